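"""Balanced bootstrap plans and .632+ prediction-error estimation.

The balanced bootstrap concatenates B copies of the l sample indices,
permutes the combined set, and reads off successive l-element chunks as
bootstrap samples, so every observation appears exactly B times across
the collection.  Samples absent from chunk b form that iteration's
out-of-bag test set C_b.

The .632+ estimator blends resubstitution and out-of-bag error with a
weight driven by the relative overfitting rate R and the no-information
rate gamma (Efron & Tibshirani); with no overfitting it reduces to
0.368*err_resub + 0.632*err_test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BootstrapPlan",
    "ErrorEstimate",
    "balanced_bootstrap",
    "err_resub",
    "err_test",
    "no_information_rate",
    "err632plus",
    "percentile_ci",
]


@dataclass(frozen=True)
class BootstrapPlan:
    """B balanced bootstrap training multisets plus their out-of-bag sets."""

    l: int
    B: int
    seed: int
    train_multisets: tuple  # B arrays of length l (0-based indices)
    oob_sets: tuple  # B sorted arrays, each non-empty

    def to_table(self):
        """Long-form audit table: iteration, role, sample index, multiplicity."""
        import pandas as pd

        rows = []
        for b in range(self.B):
            idx, counts = np.unique(self.train_multisets[b], return_counts=True)
            for i, c in zip(idx, counts):
                rows.append((b, "train", int(i), int(c)))
            for i in self.oob_sets[b]:
                rows.append((b, "test", int(i), 1))
        return pd.DataFrame(rows, columns=["iteration", "role", "sample", "multiplicity"])


def balanced_bootstrap(l: int, B: int, seed: int) -> BootstrapPlan:
    """Build a balanced bootstrap plan: permute B copies of {0..l-1}, chunk by l.

    If any chunk covers all samples (empty out-of-bag set) the whole
    permutation is redrawn, up to 100 attempts.
    """
    if l < 2:
        raise ValueError("balanced bootstrap needs at least 2 samples")
    if B < 1:
        raise ValueError("need at least one bootstrap iteration")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(l)
    for _ in range(100):
        perm = rng.permutation(np.repeat(all_idx, B))
        trains = tuple(perm[b * l : (b + 1) * l].copy() for b in range(B))
        oobs = tuple(np.setdiff1d(all_idx, t) for t in trains)
        if all(o.size > 0 for o in oobs):
            return BootstrapPlan(l, B, seed, trains, oobs)
    raise RuntimeError(
        f"could not build a balanced bootstrap plan with non-empty "
        f"out-of-bag sets for l={l}, B={B} after 100 attempts"
    )


def err_resub(true_labels, predicted_labels) -> float:
    """Mean 0/1 loss of a model evaluated on its own training data."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError("label vectors differ in length")
    return float(np.mean(y != p))


def err_test(plan: BootstrapPlan, per_iteration_losses: Sequence[np.ndarray]) -> float:
    """Iteration-weighted out-of-bag error: mean over b of the mean loss on C_b."""
    if len(per_iteration_losses) != plan.B:
        raise ValueError("need one loss vector per bootstrap iteration")
    means = []
    for b, losses in enumerate(per_iteration_losses):
        losses = np.asarray(losses, dtype=float)
        if losses.size != plan.oob_sets[b].size:
            raise ValueError(
                f"iteration {b}: {losses.size} losses for "
                f"{plan.oob_sets[b].size} out-of-bag samples"
            )
        means.append(losses.mean())
    return float(np.mean(means))


def no_information_rate(true_labels, predicted_labels) -> float:
    """Expected error if inputs and labels were independent: sum_k p_k (1 - q_k)."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    classes = np.union1d(np.unique(y), np.unique(p))
    phat = np.array([np.mean(y == k) for k in classes])
    qhat = np.array([np.mean(p == k) for k in classes])
    return float(np.sum(phat * (1.0 - qhat)))


@dataclass(frozen=True)
class ErrorEstimate:
    """Components of a .632+ error estimate."""

    err_resub: float
    err_test: float
    err632plus: float
    gamma_hat: float
    overfit_rate: float  # R, clamped to [0, 1]
    weight: float  # w in [0.632, 1]
    class_props: tuple = ()
    pred_props: tuple = ()


def err632plus(resub: float, test: float, gamma: float) -> ErrorEstimate:
    """Combine resubstitution error, out-of-bag error and gamma into .632+.

    The overfitting rate R = (err_test' − err_resub) / (gamma − err_resub)
    with err_test' = min(err_test, gamma); R is set to 0 whenever
    err_test' <= err_resub or gamma <= err_resub, and clamped to [0, 1].
    The blend weight is w = 0.632 / (1 − 0.368 R), and the estimate is the
    .632 blend plus the overfitting correction evaluated at err_test':

        0.368*resub + 0.632*test + (test' − resub) (0.368*0.632*R)/(1 − 0.368*R)

    so with R = 0 it is exactly the .632 estimator and with resub = test it
    returns that common value for any gamma.
    """
    for name, v in (("err_resub", resub), ("err_test", test), ("gamma", gamma)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    test_prime = min(test, gamma)
    if test_prime <= resub or gamma <= resub:
        r = 0.0
    else:
        r = (test_prime - resub) / (gamma - resub)
    r = float(np.clip(r, 0.0, 1.0))
    w = 0.632 / (1.0 - 0.368 * r)
    est = (
        0.368 * resub
        + 0.632 * test
        + (test_prime - resub) * (0.368 * 0.632 * r) / (1.0 - 0.368 * r)
    )
    return ErrorEstimate(
        err_resub=float(resub),
        err_test=float(test),
        err632plus=float(est),
        gamma_hat=float(gamma),
        overfit_rate=r,
        weight=float(w),
    )


def percentile_ci(values, level: float = 95.0) -> tuple[float, float]:
    """Percentile confidence interval of a bootstrap distribution."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(values, [alpha, 100.0 - alpha])
    return float(lo), float(hi)
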