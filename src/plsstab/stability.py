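"""Gene-list stability indices and stability-plot data.

All indices compare a reference top-g list L (from the whole dataset)
with B bootstrap lists L_b:

* ``s1`` (percentage of overlapping genes, POG): mean fraction of L's
  top-g genes recovered in each bootstrap top-g list — order-insensitive.
* ``s2``: rank-displacement index; a gene absent from a bootstrap list is
  placed at g+1, and the summed displacement is normalized by the maximal
  value B*g*(g+1)/2, so 1 means identically ordered lists and 0 disjoint.
* Bootstrap-based feature ranking: per-gene scores Q (mean normalized
  rank credit r_bj = g − u_bj + 1, zero when absent) and Q' (fraction of
  bootstrap lists whose top g contain the gene).
* Reselected genes: number of distinct genes over all bootstrap top-g
  lists; equals the count of genes with Q' > 0, ideal value g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StabilityResult",
    "pog_s1",
    "s2_score",
    "bbfr_q",
    "bbfr_qprime",
    "reselected_genes",
    "rank_scatter_data",
    "compute_stability",
]


def _ids(lst) -> tuple:
    """Accept RankedGeneList or any sequence of gene ids."""
    ids = tuple(getattr(lst, "gene_ids", lst))
    if len(set(ids)) != len(ids):
        raise ValueError("gene list contains duplicates")
    return ids


def _check_g(lists, g: int):
    for lst in lists:
        if len(lst) < g:
            raise ValueError(f"g={g} exceeds a list of length {len(lst)}")


def _placements(ids: tuple, g: int) -> dict:
    """gene -> 1-based rank within the top g (absent genes omitted)."""
    return {gene: r + 1 for r, gene in enumerate(ids[:g])}


def pog_s1(reference, boot_lists, g: int) -> float:
    """Percentage of overlapping genes between L and the bootstrap lists."""
    ref = _ids(reference)
    boots = [_ids(b) for b in boot_lists]
    _check_g([ref] + boots, g)
    top_ref = set(ref[:g])
    hits = sum(len(top_ref & set(b[:g])) for b in boots)
    return hits / (len(boots) * g)


def s2_score(reference, boot_lists, g: int) -> float:
    """Rank-aware stability: 1 − normalized rank displacement, absences at g+1.

    The summed displacement is normalized by B·g(g+1)/2 (its value for
    fully disjoint lists).  A pathological ordering — a late reference
    gene top-ranked in a bootstrap list while earlier ones are absent —
    can push the raw sum slightly past that, so the result is clamped at
    0 to keep the index on its stated [0, 1] scale.
    """
    ref = _ids(reference)
    boots = [_ids(b) for b in boot_lists]
    _check_g([ref] + boots, g)
    total = 0.0
    for b in boots:
        place = _placements(b, g)
        for u_j, gene in enumerate(ref[:g], start=1):
            u_bj = place.get(gene, g + 1)
            total += abs(u_j - u_bj)
    return max(0.0, 1.0 - total / (len(boots) * g * (g + 1) / 2.0))


def bbfr_q(boot_lists, g: int) -> pd.Series:
    """Per-gene Q: mean rank credit r_bj = g − u_bj + 1 over iterations, /g.

    Genes outside a bootstrap top-g list contribute rank credit 0 for that
    iteration.  Returns a Series over all genes seen in any top-g list,
    sorted descending.
    """
    boots = [_ids(b) for b in boot_lists]
    _check_g(boots, g)
    B = len(boots)
    credit: dict = {}
    for b in boots:
        for u_bj, gene in enumerate(b[:g], start=1):
            credit[gene] = credit.get(gene, 0.0) + (g - u_bj + 1)
    q = pd.Series({gene: c / (B * g) for gene, c in credit.items()}, dtype=float)
    return q.sort_values(ascending=False)


def bbfr_qprime(boot_lists, g: int) -> pd.Series:
    """Per-gene Q': fraction of bootstrap top-g lists containing the gene."""
    boots = [_ids(b) for b in boot_lists]
    _check_g(boots, g)
    B = len(boots)
    count: dict = {}
    for b in boots:
        for gene in b[:g]:
            count[gene] = count.get(gene, 0) + 1
    qp = pd.Series({gene: c / B for gene, c in count.items()}, dtype=float)
    return qp.sort_values(ascending=False)


def reselected_genes(boot_lists, g: int) -> int:
    """Distinct genes over all bootstrap top-g lists (ideal value g)."""
    boots = [_ids(b) for b in boot_lists]
    _check_g(boots, g)
    union: set = set()
    for b in boots:
        union.update(b[:g])
    return len(union)


def rank_scatter_data(reference, boot_lists, g: int) -> pd.DataFrame:
    """Bootstrap-rank distribution of each reference top-g gene.

    One row per reference gene with its reference rank, the quartiles and
    extremes of its B bootstrap ranks (g+1 when absent), and the count of
    iterations that dropped it — the data behind rank boxplots, where the
    diagonal rank == reference rank is the ideal.
    """
    ref = _ids(reference)
    boots = [_ids(b) for b in boot_lists]
    _check_g([ref] + boots, g)
    places = [_placements(b, g) for b in boots]
    rows = []
    for u_j, gene in enumerate(ref[:g], start=1):
        ranks = np.array([pl.get(gene, g + 1) for pl in places], dtype=float)
        q1, med, q3 = np.percentile(ranks, [25, 50, 75])
        rows.append(
            {
                "gene": gene,
                "reference_rank": u_j,
                "min": ranks.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": ranks.max(),
                "absent_count": int(np.sum(ranks == g + 1)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StabilityResult:
    """All stability summaries for one selection method at list length g."""

    s1: float
    s2: float
    q_scores: pd.Series
    q_prime_scores: pd.Series
    reselected: int
    g: int
    B: int
    rank_scatter: pd.DataFrame

    def to_row(self) -> dict:
        return {
            "s1": round(self.s1, 6),
            "s2": round(self.s2, 6),
            "reselected": self.reselected,
            "g": self.g,
            "B": self.B,
        }


def compute_stability(reference, boot_lists, g: int) -> StabilityResult:
    """Bundle s1, s2, Q, Q', reselected count and boxplot data."""
    return StabilityResult(
        s1=pog_s1(reference, boot_lists, g),
        s2=s2_score(reference, boot_lists, g),
        q_scores=bbfr_q(boot_lists, g),
        q_prime_scores=bbfr_qprime(boot_lists, g),
        reselected=reselected_genes(boot_lists, g),
        g=g,
        B=len(list(boot_lists)),
        rank_scatter=rank_scatter_data(reference, boot_lists, g),
    )
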