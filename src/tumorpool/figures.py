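"""Static summary figures for an experiment result."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classification import CLASSES

__all__ = ["write_figures"]


def write_figures(result, outdir: str | Path) -> list[Path]:
    """Write the four summary figures; returns the paths written."""
    outdir = Path(outdir)
    written = []
    pv = result.summary.per_variant

    # VAF distribution per class
    fig, ax = plt.subplots(figsize=(4, 3))
    data = [pv.loc[pv["label"] == c, "max_regional_vaf"] for c in CLASSES]
    ax.boxplot([d if len(d) else [np.nan] for d in data], tick_labels=CLASSES)
    ax.set_ylabel("max regional VAF")
    p = outdir / "fig_vaf_by_class.png"
    fig.tight_layout(); fig.savefig(p, dpi=120); plt.close(fig)
    written.append(p)

    # pooled vs mean regional VAF
    fig, ax = plt.subplots(figsize=(4, 4))
    reg = pv[pv["label"] != "absent"]
    ax.scatter(reg["mean_regional_vaf"], reg["pooled_vaf"], s=8, alpha=0.6)
    lim = max(0.01, reg["mean_regional_vaf"].max(), reg["pooled_vaf"].max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("mean regional VAF"); ax.set_ylabel("pooled VAF")
    p = outdir / "fig_pooled_vs_mean_vaf.png"
    fig.tight_layout(); fig.savefig(p, dpi=120); plt.close(fig)
    written.append(p)

    # expression correlation heatmap
    corr = result.expression.correlations
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(corr.to_numpy(), vmin=0.8, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(corr)), corr.index)
    fig.colorbar(im, ax=ax, label="Pearson r (log2)")
    p = outdir / "fig_expression_correlation.png"
    fig.tight_layout(); fig.savefig(p, dpi=120); plt.close(fig)
    written.append(p)

    # fold-change fractions per threshold and group
    fc = result.expression.foldchanges
    fig, ax = plt.subplots(figsize=(5, 3))
    width = 0.35
    thresholds = sorted(fc["threshold"].unique())
    for k, group in enumerate(("region_vs_region", "region_vs_pooled")):
        sub = fc[fc["group"] == group]
        means = [sub.loc[sub["threshold"] == t, "fraction"].mean() for t in thresholds]
        ax.bar(np.arange(len(thresholds)) + k * width, means, width, label=group)
    ax.set_xticks(np.arange(len(thresholds)) + width / 2,
                  [f">{int(t)}-fold" for t in thresholds])
    ax.set_ylabel("mean fraction of genes"); ax.legend(fontsize=7)
    p = outdir / "fig_foldchange_fractions.png"
    fig.tight_layout(); fig.savefig(p, dpi=120); plt.close(fig)
    written.append(p)
    return written
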