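"""In-memory container for a labelled expression matrix.

Samples are rows, genes are columns; class labels are integers 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ExpressionDataset"]


@dataclass(frozen=True)
class ExpressionDataset:
    """A samples x genes expression matrix with per-sample class labels.

    Parameters
    ----------
    matrix : (l, m) float array
        Expression values, one row per sample, one column per gene.
    labels : (l,) int array
        Class label of each sample, in ``{1..K}``.
    gene_ids : sequence of str
        Unique identifier per column.
    sample_ids : sequence of str
        Unique identifier per row.
    min_class_size : int
        Smallest admissible class; a full dataset needs at least 2
        samples per class, bootstrap-restricted views allow 1.
    """

    matrix: np.ndarray
    labels: np.ndarray
    gene_ids: tuple = field(default=None)
    sample_ids: tuple = field(default=None)
    min_class_size: int = 2

    def __post_init__(self):
        X = np.asarray(self.matrix, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("expression matrix must be a non-empty 2-D array")
        if not np.all(np.isfinite(X)):
            raise ValueError("expression matrix contains missing or non-finite values")
        l, m = X.shape
        if y.shape != (l,):
            raise ValueError(
                f"label count {y.size} does not match sample count {l}"
            )
        gid = self.gene_ids
        sid = self.sample_ids
        if gid is None:
            gid = tuple(f"G{j + 1}" for j in range(m))
        else:
            gid = tuple(str(g) for g in gid)
        if sid is None:
            sid = tuple(f"S{i + 1}" for i in range(l))
        else:
            sid = tuple(str(s) for s in sid)
        if len(gid) != m:
            raise ValueError(f"{len(gid)} gene ids for {m} columns")
        if len(sid) != l:
            raise ValueError(f"{len(sid)} sample ids for {l} rows")
        if len(set(gid)) != m:
            raise ValueError("duplicate gene ids")
        if len(set(sid)) != l:
            raise ValueError("duplicate sample ids")
        K = int(y.max()) if y.size else 0
        if y.min() < 1:
            raise ValueError("labels must be integers in {1..K}")
        counts = np.bincount(y, minlength=K + 1)[1:]
        if np.any(counts < self.min_class_size):
            bad = [k + 1 for k in range(K) if counts[k] < self.min_class_size]
            raise ValueError(
                f"classes {bad} have fewer than {self.min_class_size} samples"
            )
        object.__setattr__(self, "matrix", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "gene_ids", gid)
        object.__setattr__(self, "sample_ids", sid)

    @property
    def l(self) -> int:
        """Number of samples."""
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        """Number of genes."""
        return self.matrix.shape[1]

    @property
    def K(self) -> int:
        """Number of classes."""
        return int(self.labels.max())

    def take_rows(self, rows: Sequence[int]) -> "ExpressionDataset":
        """Row-restricted view; ``rows`` may be a multiset (bootstrap sample).

        Repeated rows get suffixed sample ids to keep ids unique.
        """
        rows = np.asarray(rows, dtype=int)
        seen: dict = {}
        sids = []
        for r in rows:
            n = seen.get(r, 0)
            seen[r] = n + 1
            base = self.sample_ids[r]
            sids.append(base if n == 0 else f"{base}.rep{n}")
        return ExpressionDataset(
            self.matrix[rows],
            self.labels[rows],
            self.gene_ids,
            tuple(sids),
            min_class_size=1,
        )

    def take_genes(self, cols: Sequence[int]) -> "ExpressionDataset":
        """Column-restricted view (gene subset, order preserved)."""
        cols = np.asarray(cols, dtype=int)
        return ExpressionDataset(
            self.matrix[:, cols],
            self.labels,
            tuple(self.gene_ids[j] for j in cols),
            self.sample_ids,
            min_class_size=self.min_class_size,
        )
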