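"""Full bootstrap experiment: selection + classification + stability.

One balanced bootstrap plan is generated once and shared across every
selection method and classifier, so methods are compared on identical
resamples.  Per iteration b, gene selection runs on the training multiset
only (never touching the out-of-bag set C_b); each classifier is then
trained on the top-g genes for every g up to ``g_max`` and scored on C_b.
The .632+ estimate combines those out-of-bag losses with whole-dataset
resubstitution fits, and the reported "best" accuracy per classifier is
the maximum .632+ accuracy over g.  Stability indices compare the
whole-dataset reference list against the per-iteration lists at
``g_stability`` genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classifiers import CLASSIFIER_KINDS, fit_classifier, predict
from .dataset import ExpressionDataset
from .ranking import RankedGeneList, rank_custom, rank_pls, rank_rfe, rank_ttest
from .resampling import (
    BootstrapPlan,
    balanced_bootstrap,
    err632plus,
    err_resub,
    no_information_rate,
    percentile_ci,
)
from .stability import StabilityResult, compute_stability

logger = logging.getLogger(__name__)

__all__ = [
    "SelectorSpec",
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "parallel_map",
    "spawn_seeds",
]


@dataclass(frozen=True)
class SelectorSpec:
    """One gene-selection method to evaluate.

    ``selector`` is one of ``pls``, ``ttest``, ``rfe`` or ``custom`` (the
    plug-in slot for an external two-class scorer, supplied in
    ``score_fn``).
    """

    selector: str = "pls"
    mode: str = "ovo"
    algo: str = "simpls"
    components: int = 1
    step_fraction: float = 0.1
    score_fn: Callable | None = None
    label: str = ""

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.selector == "pls":
            return f"{self.algo.upper()}+{self.mode.upper()} {self.components} comp."
        return f"{self.selector.upper()}+{self.mode.upper()}"

    def rank(self, dataset: ExpressionDataset, g: int) -> RankedGeneList:
        if self.selector == "pls":
            return rank_pls(dataset, self.mode, self.algo, self.components, g)
        if self.selector == "ttest":
            return rank_ttest(dataset, self.mode, g)
        if self.selector == "rfe":
            return rank_rfe(dataset, self.mode, g, self.step_fraction)
        if self.selector == "custom":
            if self.score_fn is None:
                raise ValueError("custom selector needs a score_fn")
            return rank_custom(dataset, self.score_fn, self.mode, g, self.name)
        raise ValueError(f"unknown selector {self.selector!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Experiment layout: methods, classifiers, bootstrap size, list lengths."""

    selectors: tuple = (SelectorSpec(),)
    classifiers: tuple = CLASSIFIER_KINDS
    B: int = 500
    g_max: int = 30
    g_stability: int = 30
    seed: int = 0
    preselect: int | None = None  # variance-rank filter size, off by default
    workers: int = 1

    def __post_init__(self):
        if self.B < 2:
            raise ValueError("B must be at least 2")
        if self.g_max < 1:
            raise ValueError("g_max must be >= 1")
        if not 1 <= self.g_stability <= self.g_max:
            raise ValueError("need 1 <= g_stability <= g_max")
        sels = tuple(
            SelectorSpec(**s) if isinstance(s, dict) else s for s in self.selectors
        )
        object.__setattr__(self, "selectors", sels)
        object.__setattr__(self, "classifiers", tuple(self.classifiers))


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def parallel_map(fn, items: Sequence, workers: int = 1) -> list:
    """Order-preserving map; identical results for any worker count.

    Any per-task randomness must be seeded inside the task arguments
    (see :func:`spawn_seeds`) so dispatch order cannot matter.
    """
    items = list(items)
    if not items:
        return []
    if workers == 1:
        return [fn(it) for it in items]
    from joblib import Parallel, delayed

    return list(Parallel(n_jobs=workers)(delayed(fn)(it) for it in items))


def _variance_preselect(dataset: ExpressionDataset, n: int) -> np.ndarray:
    """Indices of the n highest-variance genes (the optional preselection stage)."""
    v = dataset.matrix.var(axis=0, ddof=1)
    order = np.argsort(-v, kind="stable")[:n]
    return np.sort(order)


def _rank_with_preselect(dataset, spec, g, preselect):
    if preselect is None or preselect >= dataset.m:
        return spec.rank(dataset, g)
    cols = _variance_preselect(dataset, preselect)
    return spec.rank(dataset.take_genes(cols), g)


def _iteration_losses(dataset, spec, plan, b, g_max, g_need, classifiers, preselect):
    """Selection + classification for bootstrap iteration b.

    Returns the iteration's ranked list and a (kind, g) -> loss-vector map
    over the out-of-bag samples.  Uses only the training multiset for
    every fitted quantity.
    """
    train_rows = plan.train_multisets[b]
    oob_rows = plan.oob_sets[b]
    sub = dataset.take_rows(train_rows)
    lst = _rank_with_preselect(sub, spec, g_need, preselect)
    gene_pos = {gid: j for j, gid in enumerate(dataset.gene_ids)}
    top_cols = np.array([gene_pos[gid] for gid in lst.gene_ids[:g_max]])
    X_tr = dataset.matrix[train_rows]
    y_tr = dataset.labels[train_rows]
    X_te = dataset.matrix[oob_rows]
    y_te = dataset.labels[oob_rows]
    losses: dict = {}
    for g in range(1, g_max + 1):
        cols = top_cols[:g]
        ids = lst.gene_ids[:g]
        for kind in classifiers:
            fc = fit_classifier(kind, X_tr[:, cols], y_tr, ids)
            pred = predict(fc, X_te[:, cols])
            losses[(kind, g)] = (pred != y_te).astype(float)
    return lst, losses


@dataclass(frozen=True)
class ExperimentResult:
    """Everything the experiment computed, plus table/plot-data writers."""

    config: ExperimentConfig
    plan: BootstrapPlan
    table: pd.DataFrame  # one row per method, Table-style columns
    acc_curves: pd.DataFrame  # method, classifier, g, err components, acc632
    per_iter_acc: dict  # (method, kind, g) -> per-iteration OOB accuracy array
    stability: dict  # method name -> StabilityResult
    reference_lists: dict  # method name -> RankedGeneList
    boot_lists: dict  # method name -> list[RankedGeneList]

    def qprime_curve(self, method: str) -> pd.DataFrame:
        qp = self.stability[method].q_prime_scores
        return pd.DataFrame(
            {"rank": np.arange(1, len(qp) + 1), "gene": qp.index, "q_prime": qp.values}
        )

    def accuracy_vs_g(self) -> pd.DataFrame:
        return self.acc_curves

    def write(self, outdir) -> None:
        """Write results JSON, Table-shaped TSV and plot-data CSVs."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "table.tsv", sep="\t", index=False)
        self.acc_curves.to_csv(out / "accuracy_vs_g.csv", index=False)
        for method, st in self.stability.items():
            tag = method.replace(" ", "_").replace("+", "_").replace(".", "")
            self.qprime_curve(method).to_csv(out / f"qprime_{tag}.csv", index=False)
            st.rank_scatter.to_csv(out / f"rank_scatter_{tag}.csv", index=False)
        payload = {
            "config": {
                "B": self.config.B,
                "g_max": self.config.g_max,
                "g_stability": self.config.g_stability,
                "seed": self.config.seed,
                "classifiers": list(self.config.classifiers),
                "methods": [s.name for s in self.config.selectors],
            },
            "table": self.table.to_dict(orient="records"),
        }
        (out / "results.json").write_text(json.dumps(payload, indent=2))


def run_experiment(dataset: ExpressionDataset, config: ExperimentConfig) -> ExperimentResult:
    """Run the whole bootstrap experiment for every configured method."""
    g_max = min(config.g_max, dataset.m)
    g_stab = min(config.g_stability, dataset.m)
    g_need = max(g_max, g_stab)
    plan = balanced_bootstrap(dataset.l, config.B, config.seed)

    table_rows = []
    curve_rows = []
    per_iter_acc: dict = {}
    stability: dict = {}
    reference_lists: dict = {}
    boot_lists: dict = {}

    for spec in config.selectors:
        name = spec.name
        logger.info("method %s: reference selection on the full dataset", name)
        ref = _rank_with_preselect(dataset, spec, g_need, config.preselect)
        reference_lists[name] = ref

        def task(b, _spec=spec):
            try:
                return _iteration_losses(
                    dataset, _spec, plan, b, g_max, g_need,
                    config.classifiers, config.preselect,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"method {name}: bootstrap iteration {b} failed: {exc}"
                ) from exc

        results = parallel_map(task, range(config.B), config.workers)
        lists_b = [r[0] for r in results]
        boot_lists[name] = lists_b

        # resubstitution fits on the whole dataset, reference gene list
        gene_pos = {gid: j for j, gid in enumerate(dataset.gene_ids)}
        ref_cols = np.array([gene_pos[gid] for gid in ref.gene_ids[:g_max]])
        resub: dict = {}
        gamma: dict = {}
        for g in range(1, g_max + 1):
            cols = ref_cols[:g]
            ids = ref.gene_ids[:g]
            for kind in config.classifiers:
                fc = fit_classifier(kind, dataset.matrix[:, cols], dataset.labels, ids)
                pred = predict(fc, dataset.matrix[:, cols])
                resub[(kind, g)] = err_resub(dataset.labels, pred)
                gamma[(kind, g)] = no_information_rate(dataset.labels, pred)

        best_acc = {}
        best_g = {}
        for kind in config.classifiers:
            accs = np.empty(g_max)
            for g in range(1, g_max + 1):
                iter_means = np.array(
                    [r[1][(kind, g)].mean() for r in results]
                )
                e_test = float(iter_means.mean())
                est = err632plus(resub[(kind, g)], e_test, gamma[(kind, g)])
                accs[g - 1] = 1.0 - est.err632plus
                per_iter_acc[(name, kind, g)] = 1.0 - iter_means
                curve_rows.append(
                    {
                        "method": name,
                        "classifier": kind,
                        "g": g,
                        "err_resub": est.err_resub,
                        "err_test": est.err_test,
                        "gamma_hat": est.gamma_hat,
                        "overfit_rate": est.overfit_rate,
                        "acc632plus": accs[g - 1],
                    }
                )
            best_g[kind] = int(np.argmax(accs)) + 1
            best_acc[kind] = float(accs.max())

        best_kind = max(config.classifiers, key=lambda k: best_acc[k])
        ci_lo, ci_hi = percentile_ci(per_iter_acc[(name, best_kind, best_g[best_kind])])

        st = compute_stability(ref, lists_b, g_stab)
        stability[name] = st
        row = {
            "method": name,
            "selector": spec.selector,
            "mode": spec.mode,
            "algo": spec.algo if spec.selector == "pls" else "",
            "components": spec.components if spec.selector == "pls" else "",
            "s1": round(st.s1, 3),
            "s2": round(st.s2, 3),
            "reselected": st.reselected,
        }
        for kind in config.classifiers:
            row[f"acc_{kind}"] = round(best_acc[kind], 4)
        row["best_classifier"] = best_kind
        row["best_g"] = best_g[best_kind]
        row["acc"] = round(best_acc[best_kind], 4)
        row["accL"] = round(min(ci_lo, best_acc[best_kind]), 4)
        row["accH"] = round(max(ci_hi, best_acc[best_kind]), 4)
        table_rows.append(row)

    return ExperimentResult(
        config=config,
        plan=plan,
        table=pd.DataFrame(table_rows),
        acc_curves=pd.DataFrame(curve_rows),
        per_iter_acc=per_iter_acc,
        stability=stability,
        reference_lists=reference_lists,
        boot_lists=boot_lists,
    )
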