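"""Ranked gene lists from PLS weights and baseline statistics.

A K-class selection problem is handled three ways:

* ``mclass`` — one PLS fit against the centered l x K ±1 class-indicator
  matrix ("all classes at once");
* ``ovr`` — K two-class problems, class k (+1) against the rest (−1);
* ``ovo`` — K(K−1)/2 two-class problems over each class pair's samples.

Each two-class problem yields a full ranking of all genes; the per-problem
rankings are merged round-robin: the top gene of every sublist first, then
each sublist's next not-yet-emitted gene, and so on until ``g`` unique
genes are collected.

Baseline rankers: absolute pooled-variance two-sample t statistic, and
recursive feature elimination (RFE) driven by a linear soft-margin SVM.
Any external two-class scoring function can be plugged into the same
decompose/merge machinery via :func:`rank_custom`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataset import ExpressionDataset
from .pls import center_columns, fit_nipals, fit_simpls, nipals_r_weights

__all__ = [
    "TwoClassProblem",
    "RankedGeneList",
    "gene_importance",
    "decompose_ovr",
    "decompose_ovo",
    "encode_mclass",
    "merge_ranked_lists",
    "rank_pls",
    "rank_ttest",
    "rank_rfe",
    "rank_custom",
]


@dataclass(frozen=True)
class TwoClassProblem:
    """One binary sub-problem of a multiclass decomposition.

    ``sample_index`` are 0-based row positions into the parent dataset;
    ``coded_labels`` are +1/−1 per included sample.
    """

    name: str
    sample_index: np.ndarray
    coded_labels: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.sample_index, dtype=int)
        y = np.asarray(self.coded_labels, dtype=float)
        if idx.shape != y.shape:
            raise ValueError("sample_index and coded_labels length mismatch")
        if not (np.any(y > 0) and np.any(y < 0)):
            raise ValueError(f"problem {self.name}: both codes must be present")
        object.__setattr__(self, "sample_index", idx)
        object.__setattr__(self, "coded_labels", y)


@dataclass(frozen=True)
class RankedGeneList:
    """Ordered gene identifiers with importance scores."""

    gene_ids: tuple
    scores: tuple
    g: int
    method: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = tuple(self.gene_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("ranked list contains duplicate genes")
        object.__setattr__(self, "gene_ids", ids)
        object.__setattr__(self, "scores", tuple(float(x) for x in self.scores))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, g: int) -> tuple:
        return self.gene_ids[:g]


def _check_labels(labels) -> tuple[np.ndarray, int]:
    y = np.asarray(labels, dtype=int)
    K = int(y.max())
    present = set(np.unique(y))
    missing = sorted(set(range(1, K + 1)) - present)
    if missing:
        raise ValueError(f"classes {missing} absent from labels")
    if K < 2:
        raise ValueError("need at least two classes")
    return y, K


def decompose_ovr(labels) -> list[TwoClassProblem]:
    """One problem per class k: class k coded +1, all others −1, all samples."""
    y, K = _check_labels(labels)
    idx = np.arange(y.size)
    return [
        TwoClassProblem(f"{k}vR", idx, np.where(y == k, 1.0, -1.0))
        for k in range(1, K + 1)
    ]


def decompose_ovo(labels) -> list[TwoClassProblem]:
    """One problem per class pair (a < b), restricted to those samples.

    Class a is coded +1, class b −1; problems in lexicographic pair order.
    """
    y, K = _check_labels(labels)
    problems = []
    for a in range(1, K + 1):
        for b in range(a + 1, K + 1):
            mask = (y == a) | (y == b)
            idx = np.flatnonzero(mask)
            problems.append(
                TwoClassProblem(f"{a}v{b}", idx, np.where(y[idx] == a, 1.0, -1.0))
            )
    return problems


def encode_mclass(labels) -> np.ndarray:
    """l x K ±1 indicator matrix: +1 in the label's column, −1 elsewhere."""
    y, K = _check_labels(labels)
    Y = -np.ones((y.size, K))
    Y[np.arange(y.size), y - 1] = 1.0
    return Y


def gene_importance(model, s: int) -> np.ndarray:
    """Per-gene importance: sum of squared weights over the first ``s`` components."""
    if s < 1 or s > model.s:
        raise ValueError(f"s must be in 1..{model.s}")
    return np.sum(model.weights[:, :s] ** 2, axis=1)


def _order_desc(scores: np.ndarray) -> np.ndarray:
    """Indices sorting scores descending; ties broken by ascending gene index."""
    return np.argsort(-np.asarray(scores), kind="stable")


def _scores_to_list(gene_ids, scores, method) -> RankedGeneList:
    order = _order_desc(scores)
    return RankedGeneList(
        tuple(gene_ids[j] for j in order),
        tuple(np.asarray(scores, dtype=float)[order]),
        g=len(order),
        method=method,
    )


def merge_ranked_lists(sublists: Sequence[RankedGeneList], g: int) -> RankedGeneList:
    """Round-robin merge of per-problem rankings.

    Each round visits the sublists in their fixed order and emits every
    sublist's next not-yet-emitted gene, so the top genes of all problems
    head the merged list, then the second-best of each, and so on.  Stops
    once ``g`` unique genes are emitted.
    """
    if not sublists:
        raise ValueError("no sublists to merge")
    universe: set = set()
    for sl in sublists:
        universe.update(sl.gene_ids)
    if g > len(universe):
        raise ValueError(f"g={g} exceeds the {len(universe)} distinct genes available")

    pointers = [0] * len(sublists)
    emitted: set = set()
    out_ids: list = []
    out_scores: list = []
    while len(out_ids) < g:
        progressed = False
        for i, sl in enumerate(sublists):
            ptr = pointers[i]
            ids = sl.gene_ids
            while ptr < len(ids) and ids[ptr] in emitted:
                ptr += 1
            if ptr < len(ids):
                out_ids.append(ids[ptr])
                out_scores.append(sl.scores[ptr])
                emitted.add(ids[ptr])
                pointers[i] = ptr + 1
                progressed = True
                if len(out_ids) == g:
                    break
            else:
                pointers[i] = ptr
        if not progressed:
            break
    method = dict(sublists[0].method)
    method["merged_from"] = len(sublists)
    return RankedGeneList(tuple(out_ids), tuple(out_scores), g=g, method=method)


def _problems_for_mode(labels, mode: str) -> list[TwoClassProblem]:
    if mode == "ovo":
        return decompose_ovo(labels)
    if mode == "ovr":
        return decompose_ovr(labels)
    raise ValueError(f"unknown decomposition mode {mode!r}")


def _rank_by_problem_scores(
    dataset: ExpressionDataset,
    mode: str,
    score_fn: Callable[[TwoClassProblem, np.ndarray], np.ndarray],
    g: int,
    method: dict,
) -> RankedGeneList:
    """Decompose, score each problem, merge — shared by all two-class rankers."""
    sublists = []
    for prob in _problems_for_mode(dataset.labels, mode):
        scores = np.asarray(score_fn(prob, dataset.matrix[prob.sample_index]))
        if scores.shape != (dataset.m,):
            raise ValueError(
                f"problem {prob.name}: scorer returned shape {scores.shape}, "
                f"expected ({dataset.m},)"
            )
        sublists.append(
            _scores_to_list(dataset.gene_ids, scores, {**method, "problem": prob.name})
        )
    return merge_ranked_lists(sublists, g)


def _pls_problem_scorer(algo: str, s: int, use_r_weights: bool):
    def scorer(prob: TwoClassProblem, X: np.ndarray) -> np.ndarray:
        Xc, _ = center_columns(X)
        yc = prob.coded_labels - prob.coded_labels.mean()
        if algo == "nipals":
            model = fit_nipals(Xc, yc, s)
            W = nipals_r_weights(model) if use_r_weights else model.weights
        elif algo == "simpls":
            model = fit_simpls(Xc, yc, s)
            W = model.weights
        else:
            raise ValueError(f"unknown PLS algorithm {algo!r}")
        return np.sum(W[:, :s] ** 2, axis=1)

    return scorer


def rank_pls(
    dataset: ExpressionDataset,
    mode: str = "ovo",
    algo: str = "simpls",
    s: int = 1,
    g: int = 30,
    use_r_weights: bool = False,
) -> RankedGeneList:
    """PLS squared-weight gene ranking under a multiclass formulation.

    ``mclass`` fits one model against the ±1 indicator matrix and sorts
    the summed squared weights; ``ovo``/``ovr`` fit one univariate model
    per two-class problem and merge the per-problem rankings.  NIPALS
    ranks on ``w`` (or, when ``use_r_weights``, on the converted ``r``);
    SIMPLS ranks on ``r``.
    """
    method = {
        "selector": "pls",
        "mode": mode,
        "algo": algo,
        "components": s,
        "use_r_weights": bool(use_r_weights),
    }
    if mode == "mclass":
        Xc, _ = center_columns(dataset.matrix)
        Y = encode_mclass(dataset.labels)
        Yc = Y - Y.mean(axis=0)
        if algo == "nipals":
            model = fit_nipals(Xc, Yc, s)
            W = nipals_r_weights(model) if use_r_weights else model.weights
        elif algo == "simpls":
            model = fit_simpls(Xc, Yc, s)
            W = model.weights
        else:
            raise ValueError(f"unknown PLS algorithm {algo!r}")
        imp = np.sum(W[:, :s] ** 2, axis=1)
        full = _scores_to_list(dataset.gene_ids, imp, method)
        if g > dataset.m:
            raise ValueError(f"g={g} exceeds the {dataset.m} genes available")
        return RankedGeneList(full.gene_ids[:g], full.scores[:g], g=g, method=method)
    scorer = _pls_problem_scorer(algo, s, use_r_weights)
    return _rank_by_problem_scores(dataset, mode, scorer, g, method)


def pooled_t_statistic(X: np.ndarray, coded: np.ndarray) -> np.ndarray:
    """Equal-variance two-sample t per column; zero pooled variance gives 0."""
    pos = X[coded > 0]
    neg = X[coded < 0]
    n1, n2 = pos.shape[0], neg.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples for the t statistic")
    v1 = pos.var(axis=0, ddof=1)
    v2 = neg.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = pos.mean(axis=0) - neg.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def rank_ttest(dataset: ExpressionDataset, mode: str = "ovo", g: int = 30) -> RankedGeneList:
    """Rank genes by |pooled-variance t| per two-class problem, then merge."""

    def scorer(prob, X):
        return np.abs(pooled_t_statistic(X, prob.coded_labels))

    return _rank_by_problem_scores(
        dataset, mode, scorer, g, {"selector": "ttest", "mode": mode}
    )


def _rfe_order(X: np.ndarray, coded: np.ndarray, keep: int, step_fraction: float, name: str) -> np.ndarray:
    """Total gene order from SVM-RFE on one two-class problem.

    Eliminates the lowest-|coef|^2 ``step_fraction`` of remaining genes
    per refit until ``keep`` remain; survivors are ordered by the final
    fit's squared coefficients, eliminated genes by reverse elimination
    order (within a batch, larger coefficient first).
    """
    from sklearn.svm import SVC

    m = X.shape[1]
    remaining = np.arange(m)
    eliminated: list = []  # appended least-important-first
    y = (coded > 0).astype(int)
    coef2 = None
    while True:
        Xc = X[:, remaining] - X[:, remaining].mean(axis=0)
        clf = SVC(kernel="linear", C=1.0)
        try:
            clf.fit(Xc, y)
        except Exception as exc:  # pragma: no cover - solver failure surface
            raise RuntimeError(f"RFE classifier failed on problem {name}: {exc}") from exc
        coef2 = np.asarray(clf.coef_).ravel() ** 2
        if remaining.size <= keep:
            break
        n_elim = max(1, int(np.floor(step_fraction * remaining.size)))
        n_elim = min(n_elim, remaining.size - keep)
        order = np.argsort(coef2, kind="stable")  # ascending importance
        drop = order[:n_elim]
        # within a batch: least important eliminated "first"
        eliminated.extend(remaining[drop].tolist())
        mask = np.ones(remaining.size, dtype=bool)
        mask[drop] = False
        remaining = remaining[mask]
    survivors = remaining[np.argsort(-coef2, kind="stable")]
    return np.concatenate([survivors, np.asarray(eliminated[::-1], dtype=int)])


def rank_rfe(
    dataset: ExpressionDataset,
    mode: str = "ovo",
    g: int = 30,
    step_fraction: float = 0.1,
) -> RankedGeneList:
    """SVM recursive-feature-elimination ranking per two-class problem, merged.

    Per problem, a linear soft-margin SVM is refit while the lowest-scoring
    ``step_fraction`` of remaining genes (at least one) is dropped each
    round, down to ``g`` genes; rank follows elimination order with the
    survivors first.
    """
    if not 0 < step_fraction < 1:
        raise ValueError("step_fraction must be in (0, 1)")
    method = {"selector": "rfe", "mode": mode, "step_fraction": step_fraction}
    sublists = []
    for prob in _problems_for_mode(dataset.labels, mode):
        X = dataset.matrix[prob.sample_index]
        order = _rfe_order(X, prob.coded_labels, min(g, dataset.m), step_fraction, prob.name)
        # score = descending position credit so merged sublists stay ordered
        scores = np.empty(dataset.m)
        scores[np.arange(order.size)] = dataset.m - np.arange(order.size)
        sublists.append(
            RankedGeneList(
                tuple(dataset.gene_ids[j] for j in order),
                tuple(float(dataset.m - i) for i in range(order.size)),
                g=order.size,
                method={**method, "problem": prob.name},
            )
        )
    return merge_ranked_lists(sublists, g)


def rank_custom(
    dataset: ExpressionDataset,
    score_fn: Callable[[TwoClassProblem, np.ndarray], np.ndarray],
    mode: str = "ovo",
    g: int = 30,
    name: str = "custom",
) -> RankedGeneList:
    """Plug-in slot: decompose/merge any external two-class gene scorer.

    ``score_fn(problem, X_sub)`` must return one non-negative importance
    per gene, computed from the problem's samples only.
    """
    return _rank_by_problem_scores(
        dataset, mode, score_fn, g, {"selector": name, "mode": mode}
    )
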