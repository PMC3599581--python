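"""Partial least squares decompositions by NIPALS and SIMPLS.

Both algorithms fit the bilinear model

    X = t_1 p_1' + ... + t_s p_s' + E,      y = t_1 q_1 + ... + t_s q_s + f

on a column-centered matrix ``X``.  Each weight vector maximizes the
squared sample covariance cov^2(Xw, y) subject to unit norm, with
successive components orthogonal (w_i' X'X w_j = 0 for i != j, hence
mutually orthogonal score vectors t_i).

NIPALS deflates X (and the response) each round, so its weights ``w_i``
apply to the *deflated* matrices; SIMPLS enforces the orthogonality
constraint directly and returns weights ``r_i`` that apply to the original
centered matrix.  For a univariate response the two algorithms produce the
same sequence of score directions (De Jong); the weight vectors differ
from the second component on.  Gene ranking downstream uses the squared
entries of the weight columns.

Conventions: weight columns have unit Euclidean norm for both algorithms
(so squared weights are comparable across components), and each weight
column's sign is fixed so its largest-magnitude entry is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "PLSModel",
    "center_columns",
    "fit_nipals",
    "fit_simpls",
    "nipals_r_weights",
]

# NIPALS inner-loop convergence for a multivariate response; the
# univariate weight is closed-form and needs no iteration.
_NIPALS_TOL = 1e-10
_NIPALS_MAXITER = 500

# A component whose score norm falls below this fraction of ||Xc||
# carries no signal (numerical rank exhausted).
_SCORE_RTOL = 1e-12


@dataclass(frozen=True)
class PLSModel:
    """Weights, scores, loadings and residuals of a fitted PLS decomposition.

    ``weights`` holds NIPALS ``w_i`` or SIMPLS ``r_i`` per column (unit
    norm).  ``y_loadings`` is an ``(s,)`` vector for a univariate response
    or ``(s, K)`` for a multivariate one.
    """

    algorithm: str  # "nipals" | "simpls"
    weights: np.ndarray  # (m, s)
    scores: np.ndarray  # (l, s)
    x_loadings: np.ndarray  # (m, s)
    y_loadings: np.ndarray  # (s,) or (s, K)
    x_residual: np.ndarray  # (l, m)
    y_residual: np.ndarray  # (l,) or (l, K)

    @property
    def s(self) -> int:
        return self.weights.shape[1]

    @property
    def m(self) -> int:
        return self.weights.shape[0]


def center_columns(X: np.ndarray):
    """Subtract each column's mean; return the centered matrix and the means.

    The means are returned so held-out rows can be centered with the
    *training* means.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("cannot center an empty matrix")
    mu = X.mean(axis=0)
    return X - mu, mu


def _check_fit_inputs(Xc, Yc, s):
    Xc = np.asarray(Xc, dtype=float)
    Yc = np.asarray(Yc, dtype=float)
    if Xc.ndim != 2 or Xc.size == 0:
        raise ValueError("Xc must be a non-empty 2-D array")
    if Yc.shape[0] != Xc.shape[0]:
        raise ValueError("response length does not match sample count")
    if not np.any(np.abs(Yc) > 0):
        raise ValueError("response has zero variance after centering")
    if s < 1:
        raise ValueError("component count must be >= 1")
    rank = np.linalg.matrix_rank(Xc)
    if s > rank:
        raise ValueError(
            f"requested {s} components but the centered matrix has rank {rank}"
        )
    return Xc, Yc


def _fix_sign(w):
    """Return +1/-1 so the largest-magnitude entry of ``w`` is positive."""
    j = int(np.argmax(np.abs(w)))
    return -1.0 if w[j] < 0 else 1.0


def fit_nipals(Xc: np.ndarray, Yc: np.ndarray, s: int) -> PLSModel:
    """Fit ``s`` PLS components by NIPALS on centered data.

    ``Yc`` may be a centered vector (two-class coding) or a centered
    l x K indicator matrix (all-classes-at-once).  X and the response are
    both deflated each component; weights apply to the deflated matrix.
    """
    Xc, Yc = _check_fit_inputs(Xc, Yc, s)
    univariate = Yc.ndim == 1
    Y2 = Yc[:, None] if univariate else Yc

    l, m = Xc.shape
    Xd = Xc.copy()
    Yd = Y2.copy()
    xnorm = np.linalg.norm(Xc)

    W = np.empty((m, s))
    T = np.empty((l, s))
    P = np.empty((m, s))
    Q = np.empty((s, Y2.shape[1]))

    n_done = 0
    for i in range(s):
        if univariate:
            w = Xd.T @ Yd[:, 0]
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w = w / nw
        else:
            # classical NIPALS inner loop on deflated X, Y
            u = Yd[:, int(np.argmax(Yd.var(axis=0)))]
            w = np.zeros(m)
            for _ in range(_NIPALS_MAXITER):
                w_new = Xd.T @ u
                nw = np.linalg.norm(w_new)
                if nw == 0:
                    break
                w_new = w_new / nw
                t = Xd @ w_new
                tt = t @ t
                if tt == 0:
                    break
                q = Yd.T @ t / tt
                qq = q @ q
                if qq == 0:
                    break
                u = Yd @ q / qq
                if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                    w = w_new
                    break
                w = w_new
            if np.linalg.norm(w) == 0:
                break
        t = Xd @ w
        tt = t @ t
        if np.sqrt(tt) <= _SCORE_RTOL * xnorm:
            warnings.warn(
                f"component {i + 1}: score norm below numerical rank "
                "threshold, stopping early",
                RuntimeWarning,
            )
            break
        p = Xd.T @ t / tt
        q = Yd.T @ t / tt
        sign = _fix_sign(w)
        w, t, p, q = sign * w, sign * t, sign * p, sign * q
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, q)
        W[:, i], T[:, i], P[:, i], Q[i] = w, t, p, q
        n_done += 1

    if n_done < s:
        raise ValueError(
            f"only {n_done} informative components available, {s} requested"
        )
    E = Xc - T @ P.T
    F = Y2 - T @ Q
    return PLSModel(
        "nipals",
        W,
        T,
        P,
        Q[:, 0] if univariate else Q,
        E,
        F[:, 0] if univariate else F,
    )


def fit_simpls(Xc: np.ndarray, Yc: np.ndarray, s: int) -> PLSModel:
    """Fit ``s`` PLS components by SIMPLS on centered data.

    Weights ``r_i`` apply directly to the original centered matrix
    (scores are ``Xc @ R`` by construction); X is never deflated —
    instead the cross-product matrix is projected off the span of the
    previous x-loadings, which enforces r_i' X'X r_j = 0 directly.
    """
    Xc, Yc = _check_fit_inputs(Xc, Yc, s)
    univariate = Yc.ndim == 1
    Y2 = Yc[:, None] if univariate else Yc

    l, m = Xc.shape
    xnorm = np.linalg.norm(Xc)
    S = Xc.T @ Y2  # m x K cross-product, deflated in place

    R = np.empty((m, s))
    T = np.empty((l, s))
    P = np.empty((m, s))
    Q = np.empty((s, Y2.shape[1]))
    V = np.empty((m, s))  # orthonormal basis of x-loadings used for deflation

    n_done = 0
    for i in range(s):
        if S.shape[1] == 1:
            r = S[:, 0].copy()
        else:
            U, _, _ = np.linalg.svd(S, full_matrices=False)
            r = U[:, 0].copy()
        nr = np.linalg.norm(r)
        if nr == 0:
            break
        r = r / nr
        t = Xc @ r
        tt = t @ t
        if np.sqrt(tt) <= _SCORE_RTOL * xnorm:
            warnings.warn(
                f"component {i + 1}: score norm below numerical rank "
                "threshold, stopping early",
                RuntimeWarning,
            )
            break
        p = Xc.T @ t / tt
        q = Y2.T @ t / tt
        sign = _fix_sign(r)
        r, t, p, q = sign * r, sign * t, sign * p, sign * q
        v = p.copy()
        if i > 0:
            v = v - V[:, :i] @ (V[:, :i].T @ p)
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v = v / nv
        S = S - np.outer(v, v @ S)
        R[:, i], T[:, i], P[:, i], Q[i], V[:, i] = r, t, p, q, v
        n_done += 1

    if n_done < s:
        raise ValueError(
            f"only {n_done} informative components available, {s} requested"
        )
    E = Xc - T @ P.T
    F = Y2 - T @ Q
    return PLSModel(
        "simpls",
        R,
        T,
        P,
        Q[:, 0] if univariate else Q,
        E,
        F[:, 0] if univariate else F,
    )


def nipals_r_weights(model: PLSModel) -> np.ndarray:
    """Convert NIPALS weights to weights for the original centered matrix.

    Solves R = W (P'W)^{-1}; P'W is upper triangular, so the conversion is
    a triangular solve.  ``Xc @ R`` reproduces the NIPALS score matrix.
    Columns are *not* re-normalized (the first equals w_1 exactly).
    """
    if model.algorithm != "nipals":
        raise ValueError("r-weight conversion applies to NIPALS models only")
    PtW = model.x_loadings.T @ model.weights
    diag = np.abs(np.diag(PtW))
    if np.any(diag < 1e-12):
        bad = int(np.argmin(diag)) + 1
        raise ValueError(f"degenerate component {bad}: p_i'w_i is zero")
    return model.weights @ solve_triangular(PtW, np.eye(model.s))
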