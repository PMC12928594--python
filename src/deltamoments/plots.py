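"""Minimal plotting helpers: simulation performance panels and forest plots."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .meta_model import MetaResult
from .effect_sizes import EffectSize

__all__ = ["plot_performance_panels", "plot_forest"]


def plot_performance_panels(table: pd.DataFrame, out_path: str | Path) -> None:
    """Bias / relative variance bias / coverage vs n, one line per pairing."""
    metrics = [("bias", 0.0), ("rel_var_bias", 0.0), ("coverage", 0.95)]
    families = sorted(table["family"].unique())
    fig, axes = plt.subplots(
        len(families), 3, figsize=(12, 3.2 * len(families)), squeeze=False
    )
    for i, fam in enumerate(families):
        sub = table[table["family"] == fam]
        for j, (metric, ref) in enumerate(metrics):
            ax = axes[i][j]
            for pairing, grp in sub.groupby("estimator_pairing"):
                agg = grp.groupby("n_per_group")[metric].mean()
                ax.plot(agg.index, agg.values, marker="o", ms=3, label=pairing)
            ax.axhline(ref, color="grey", lw=0.8, ls="--")
            ax.set_xscale("log")
            ax.set_xlabel("n per group")
            ax.set_title(f"{fam}: {metric}")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_forest(
    effects: Sequence[EffectSize],
    result: Optional[MetaResult],
    out_path: str | Path,
    labels: Optional[Sequence[str]] = None,
) -> None:
    """Per-effect Wald intervals with the pooled estimate at the bottom."""
    from .effect_sizes import confidence_interval

    k = len(effects)
    fig, ax = plt.subplots(figsize=(6, 0.4 * (k + 2) + 1.2))
    for i, e in enumerate(effects):
        lo, hi = confidence_interval(e)
        y = k - i
        ax.plot([lo, hi], [y, y], color="black", lw=1)
        ax.plot(e.estimate, y, "s", color="black", ms=4)
    if result is not None:
        ax.plot(result.ci, [0, 0], color="teal", lw=2)
        ax.plot(result.pooled_estimate, 0, "D", color="teal", ms=7)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    names = list(labels) if labels is not None else [str(i + 1) for i in range(k)]
    ax.set_yticks(list(range(k, 0, -1)) + [0])
    ax.set_yticklabels(names + ["pooled"])
    ax.set_xlabel(effects[0].effect_kind if effects else "effect")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
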