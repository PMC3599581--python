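"""Figures from experiment plot data (accuracy-vs-g, Q' curves, rank
boxplots, stability bars).  Rendering only; all numbers come from the
pipeline's plot-data frames."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["save_figures"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def save_figures(result, outdir) -> list:
    """Write one PNG per figure family; returns the written paths."""
    plt = _mpl()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    # accuracy vs number of genes, per method (best classifier per method)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for method, df in result.acc_curves.groupby("method"):
        best_kind = result.table.set_index("method").loc[method, "best_classifier"]
        sub = df[df["classifier"] == best_kind]
        ax.plot(sub["g"], sub["acc632plus"], marker=".", label=f"{method} ({best_kind})")
    ax.set_xlabel("number of selected genes g")
    ax.set_ylabel(".632+ accuracy")
    ax.legend(fontsize=7)
    p = out / "accuracy_vs_g.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    # sorted Q' curves with the ideal step curve
    fig, ax = plt.subplots(figsize=(7, 4.5))
    g = None
    for method in result.stability:
        curve = result.qprime_curve(method)
        g = result.stability[method].g
        ax.step(curve["rank"], curve["q_prime"], where="post", label=method)
    if g is not None:
        xs = np.arange(1, int(ax.get_xlim()[1]) + 2)
        ax.step(xs, np.where(xs <= g, 1.0, 0.0), where="post", color="black", label="ideal")
    ax.set_xlabel("gene rank (sorted)")
    ax.set_ylabel("Q' score")
    ax.legend(fontsize=7)
    p = out / "qprime_curve.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    # rank boxplots per method
    for method, st in result.stability.items():
        sc = st.rank_scatter
        fig, ax = plt.subplots(figsize=(7, 4.5))
        stats = [
            {
                "med": r["median"],
                "q1": r["q1"],
                "q3": r["q3"],
                "whislo": r["min"],
                "whishi": r["max"],
                "fliers": [],
            }
            for _, r in sc.iterrows()
        ]
        ax.bxp(stats, positions=sc["reference_rank"], showfliers=False)
        lim = st.g + 1
        ax.plot([1, st.g], [1, st.g], color="red", lw=1, label="ideal")
        ax.set_ylim(0, lim + 1)
        ax.set_xlabel("rank in whole-dataset list")
        ax.set_ylabel("rank in bootstrap lists")
        ax.set_title(method, fontsize=9)
        ax.legend(fontsize=7)
        tag = method.replace(" ", "_").replace("+", "_").replace(".", "")
        p = out / f"rank_boxplot_{tag}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    # stability bars (s2) with best accuracy dots
    fig, ax = plt.subplots(figsize=(7, 4.5))
    tbl = result.table
    x = np.arange(len(tbl))
    ax.bar(x, tbl["s2"], color="lightsteelblue", label="s2")
    ax2 = ax.twinx()
    ax2.errorbar(
        x,
        tbl["acc"],
        yerr=[tbl["acc"] - tbl["accL"], tbl["accH"] - tbl["acc"]],
        fmt="o",
        color="darkred",
        label="best .632+ accuracy",
    )
    ax.set_xticks(x)
    ax.set_xticklabels(tbl["method"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("stability index s2")
    ax2.set_ylabel("accuracy")
    p = out / "stability_bars.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written
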