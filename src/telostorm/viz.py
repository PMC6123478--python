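"""Plotting helpers for shape-table results."""

from __future__ import annotations

import numpy as np

from telostorm.shape import GroupShapeTable


def violin_rg_by_group(table: GroupShapeTable, cutoff: float | None = None, ax=None):
    """Violin plot of the per-telomere Rg distribution per group.

    Shows the density, the median (white dot), the interquartile range (thick
    bar) and the 95% confidence interval of the mean (thin line); an optional
    horizontal dashed line marks the reference cutoff.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * len(table.groups) + 1.5, 4.0))
    by_group = table.rg_by_group()
    labels = list(by_group)
    data = [by_group[g] for g in labels]
    ax.violinplot(data, showextrema=False)
    from telostorm.shape import summarize_shape_distribution

    summary, _ = summarize_shape_distribution(table)
    summary = summary.set_index("group")
    for i, g in enumerate(labels, start=1):
        row = summary.loc[g]
        ax.vlines(i, row["iqr_low_nm"], row["iqr_high_nm"], lw=5, color="k")
        ax.vlines(i, row["ci_low_nm"], row["ci_high_nm"], lw=1.2, color="k")
        ax.plot(i, row["median_rg_nm"], "o", color="white", ms=5, zorder=3)
    if cutoff is not None:
        ax.axhline(cutoff, ls="--", color="0.4", lw=1)
    ax.set_xticks(np.arange(1, len(labels) + 1), labels)
    ax.set_ylabel("Rg (nm)")
    return ax


def scatter_rg_by_nucleus(table: GroupShapeTable, group: str, ax=None):
    """Per-nucleus dot plot of Rg for one group (one dot per telomere)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.0, 4.0))
    sub = table.records[table.records["group"] == group]
    nuclei = list(dict.fromkeys(sub["nucleus"]))
    rng = np.random.default_rng(0)
    for i, nuc in enumerate(nuclei):
        vals = sub[sub["nucleus"] == nuc]["rg_nm"]
        x = i + rng.uniform(-0.15, 0.15, len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.7)
    ax.set_xlabel("nucleus index")
    ax.set_ylabel("Rg (nm)")
    ax.set_title(group)
    return ax
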