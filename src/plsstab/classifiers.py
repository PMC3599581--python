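"""Uniform fit/predict contract over the four comparator classifiers.

All four are linear: soft-margin SVMs in one-vs-one, one-vs-rest and
single-objective multiclass (Crammer–Singer) formulations (C = 1), and
linear discriminant analysis with a shrinkage covariance estimator (the
gene count can approach the training count).  Solvers come from
scikit-learn; this module pins the training-mean centering, the gene
subset bookkeeping and determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC, LinearSVC

__all__ = ["CLASSIFIER_KINDS", "FittedClassifier", "fit_classifier", "predict"]

CLASSIFIER_KINDS = ("svm_ovo", "svm_ovr", "msvm", "lda")


@dataclass(frozen=True)
class FittedClassifier:
    kind: str
    gene_subset: tuple  # ordered gene ids the model was trained on
    center: np.ndarray  # training column means
    model: object  # fitted sklearn estimator, or None when degenerate
    degenerate: bool = False  # constant-feature fallback to majority class
    majority: int = 0


def _make_estimator(kind: str):
    if kind == "svm_ovo":
        return SVC(kernel="linear", C=1.0)
    if kind == "svm_ovr":
        return OneVsRestClassifier(SVC(kernel="linear", C=1.0))
    if kind == "msvm":
        return LinearSVC(C=1.0, multi_class="crammer_singer", random_state=0, max_iter=100_000)
    if kind == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


def fit_classifier(kind: str, X: np.ndarray, y: np.ndarray, gene_ids) -> FittedClassifier:
    """Train one classifier on (training rows x selected genes).

    Columns are centered by the training means, which are stored and
    re-applied at prediction.  An all-constant feature matrix cannot
    separate anything; the fit falls back to the majority class and is
    flagged ``degenerate``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    gene_ids = tuple(gene_ids)
    if X.ndim != 2 or X.shape[1] != len(gene_ids):
        raise ValueError("feature matrix does not match the gene subset")
    if X.shape[0] != y.size:
        raise ValueError("row/label count mismatch")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    center = X.mean(axis=0)
    Xc = X - center
    if not np.any(np.abs(Xc) > 0):
        vals, counts = np.unique(y, return_counts=True)
        return FittedClassifier(
            kind, gene_ids, center, None, degenerate=True, majority=int(vals[np.argmax(counts)])
        )
    est = _make_estimator(kind)
    est.fit(Xc, y)
    return FittedClassifier(kind, gene_ids, center, est)


def predict(fitted: FittedClassifier, X: np.ndarray, gene_ids=None) -> np.ndarray:
    """Predict class labels for rows carrying the model's gene subset.

    If ``gene_ids`` is given the needed columns are looked up by id;
    missing genes raise an error naming them.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if gene_ids is not None:
        pos = {gid: j for j, gid in enumerate(gene_ids)}
        missing = [gid for gid in fitted.gene_subset if gid not in pos]
        if missing:
            raise KeyError(f"rows are missing genes {missing}")
        X = X[:, [pos[gid] for gid in fitted.gene_subset]]
    if X.shape[1] != len(fitted.gene_subset):
        raise ValueError(
            f"{X.shape[1]} columns supplied for {len(fitted.gene_subset)} model genes"
        )
    if fitted.degenerate:
        return np.full(X.shape[0], fitted.majority, dtype=int)
    return np.asarray(fitted.model.predict(X - fitted.center), dtype=int)
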