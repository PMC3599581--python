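"""Synthetic multiclass expression data with planted marker genes.

Emulates the structure of a K-class microarray study on a log-intensity
scale: most genes are pure Gaussian noise around a common baseline, a
small set of *pairwise* markers separates one specific class pair (+delta
in one class of the pair, −delta in the other), and a set of *one-vs-rest*
markers is shifted +delta in a single class.  Marker positions are drawn
at random so rankers cannot benefit from gene order, and the ground-truth
map names every planted gene.

Defaults mirror the desk-scale study conditions used throughout the test
suite: 3 classes, 20 samples per class, 1000 genes, effect size
delta = 2*sigma.  Real microarray features the generator does not emulate:
probe-level effects, inter-gene correlation, batch structure, and
intensity-dependent variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .dataset import ExpressionDataset

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study design for one synthetic dataset.

    ``delta`` is the additive mean shift of a marker (expression units on
    the baseline scale); ``sigma`` the per-gene noise standard deviation.
    ``pairwise_markers`` counts markers per class pair, ``ovr_markers``
    per class.
    """

    K: int = 3
    n_per_class: int = 20
    m: int = 1000
    pairwise_markers: int = 5
    ovr_markers: int = 5
    delta: float = 2.0
    sigma: float = 1.0
    baseline: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("need at least 2 classes")
        if self.n_per_class < 2:
            raise ValueError("need at least 2 samples per class")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.total_markers > self.m:
            raise ValueError(
                f"{self.total_markers} markers exceed {self.m} genes"
            )

    @property
    def n_pairs(self) -> int:
        return self.K * (self.K - 1) // 2

    @property
    def total_markers(self) -> int:
        return self.n_pairs * self.pairwise_markers + self.K * self.ovr_markers


def generate(spec: SyntheticSpec):
    """Draw one dataset; returns (ExpressionDataset, marker map).

    The marker map is ``{gene_id: {"type": "pairwise", "classes": (a, b)}}``
    or ``{"type": "ovr", "class": k}`` for every planted gene.
    """
    rng = np.random.default_rng(spec.seed)
    l = spec.K * spec.n_per_class
    labels = np.repeat(np.arange(1, spec.K + 1), spec.n_per_class)
    X = rng.normal(spec.baseline, spec.sigma, size=(l, spec.m))

    marker_cols = rng.choice(spec.m, size=spec.total_markers, replace=False)
    gene_ids = tuple(f"G{j + 1:05d}" for j in range(spec.m))
    marker_map: dict = {}
    pos = 0
    for a, b in combinations(range(1, spec.K + 1), 2):
        for _ in range(spec.pairwise_markers):
            j = int(marker_cols[pos])
            pos += 1
            X[labels == a, j] += spec.delta
            X[labels == b, j] -= spec.delta
            marker_map[gene_ids[j]] = {"type": "pairwise", "classes": (a, b)}
    for k in range(1, spec.K + 1):
        for _ in range(spec.ovr_markers):
            j = int(marker_cols[pos])
            pos += 1
            X[labels == k, j] += spec.delta
            marker_map[gene_ids[j]] = {"type": "ovr", "class": k}

    sample_ids = tuple(f"S{i + 1:03d}" for i in range(l))
    return ExpressionDataset(X, labels, gene_ids, sample_ids), marker_map
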