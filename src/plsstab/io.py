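"""Reading and writing expression matrices, label files and ranked lists.

Internal orientation is samples x genes.  Matrix files are delimited text
with gene identifiers as column headers and sample identifiers as row
labels; transposed (genes x samples) files — the common microarray export
— are accepted via an orientation flag.  Class labels are arbitrary
strings mapped to integers 1..K in first-appearance order.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .ranking import RankedGeneList

logger = logging.getLogger(__name__)

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_ranked_list",
    "write_ranked_list",
    "write_stability_summary",
]

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless round trip for our data


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_dataset(
    matrix_path,
    labels_path,
    orientation: str = "samples_by_genes",
) -> ExpressionDataset:
    """Load a matrix file plus a label file into a validated dataset.

    The label file has one sample per line: either ``sample_id<TAB>label``
    or a bare label per line in matrix row order.
    """
    matrix_path = Path(matrix_path)
    labels_path = Path(labels_path)
    for p in (matrix_path, labels_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    df = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.isna().any().any():
        raise ValueError(f"{matrix_path}: matrix contains missing values")

    lab = pd.read_csv(labels_path, sep=_sep_for(labels_path), header=None, dtype=str)
    if lab.shape[1] >= 2:
        mapping_series = pd.Series(
            lab.iloc[:, 1].values, index=lab.iloc[:, 0].astype(str).values
        )
        missing = [s for s in df.index.astype(str) if s not in mapping_series.index]
        if missing:
            raise ValueError(f"{labels_path}: no label for samples {missing}")
        raw = [str(mapping_series[s]) for s in df.index.astype(str)]
    else:
        if lab.shape[0] != df.shape[0]:
            raise ValueError(
                f"{labels_path}: {lab.shape[0]} labels for {df.shape[0]} samples"
            )
        raw = [str(v) for v in lab.iloc[:, 0].values]

    order: dict = {}
    for v in raw:
        if v not in order:
            order[v] = len(order) + 1
    labels = np.array([order[v] for v in raw], dtype=int)
    logger.info("label mapping: %s", order)
    return ExpressionDataset(
        df.to_numpy(dtype=float),
        labels,
        tuple(df.columns.astype(str)),
        tuple(df.index.astype(str)),
    )


def write_dataset(dataset: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write the matrix (samples x genes TSV/CSV) and a two-column label file."""
    matrix_path = Path(matrix_path)
    labels_path = Path(labels_path)
    df = pd.DataFrame(
        dataset.matrix, index=list(dataset.sample_ids), columns=list(dataset.gene_ids)
    )
    df.to_csv(matrix_path, sep=_sep_for(matrix_path), float_format=_FLOAT_FMT)
    with open(labels_path, "w") as fh:
        for sid, lab in zip(dataset.sample_ids, dataset.labels):
            fh.write(f"{sid}\t{lab}\n")


def write_ranked_list(path, ranked: RankedGeneList, with_scores: bool = True) -> None:
    """Tab-separated ranked list: rank, gene id, optional score."""
    with open(path, "w") as fh:
        for r, gid in enumerate(ranked.gene_ids, start=1):
            if with_scores:
                fh.write(f"{r}\t{gid}\t{ranked.scores[r - 1]:.12g}\n")
            else:
                fh.write(f"{r}\t{gid}\n")


def read_ranked_list(path) -> RankedGeneList:
    """Read a ranked-list TSV written by :func:`write_ranked_list`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    ids: list = []
    scores: list = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            ids.append(parts[1])
            scores.append(float(parts[2]) if len(parts) > 2 else 0.0)
    return RankedGeneList(tuple(ids), tuple(scores), g=len(ids))


def write_stability_summary(path, rows) -> None:
    """TSV summary: method, g, s1, s2, reselected."""
    pd.DataFrame(rows, columns=["method", "g", "s1", "s2", "reselected"]).to_csv(
        path, sep="\t", index=False
    )
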