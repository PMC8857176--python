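"""Minimal matplotlib views of the pipeline outputs.

Styling is intentionally plain; these are diagnostic plots, not figure
reproductions.
"""

from __future__ import annotations

import numpy as np

from .profiles import FP_OFFSETS, TP_OFFSETS


def plot_positional_profile(profile_row, ax=None):
    """Bar view of one positional-profile row (5'/3' offsets + A/U tails)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    labels = (
        [f"5' {k:+d}" for k in FP_OFFSETS]
        + [f"3' {k:+d}" for k in TP_OFFSETS]
        + ["+A", "+U"]
    )
    values = profile_row.to_numpy(dtype=float)
    colors = ["tab:blue"] * 7 + ["tab:green"] * 7 + ["tab:red"] * 2
    ax.bar(np.arange(len(values)), values, color=colors)
    ax.set_xticks(np.arange(len(values)), labels, rotation=90, fontsize=7)
    ax.set_ylabel("proportion of reads")
    return ax


def plot_ecdf(ecdf_df, mirna, category="TOTAL", ax=None):
    """Target vs non-target correlation ECDFs for one miRNA x category."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    sub = ecdf_df[(ecdf_df["mirna"] == mirna) & (ecdf_df["category"] == category)]
    for group, color in (("target", "tab:red"), ("nontarget", "tab:gray")):
        g = sub[sub["group"] == group].sort_values("r")
        ax.step(g["r"], g["ecdf"], where="post", color=color, label=group)
    ax.set_xlabel("Pearson r (miRNA vs gene)")
    ax.set_ylabel("ECDF")
    ax.set_title(f"{mirna} / {category}", fontsize=9)
    ax.legend(fontsize=7)
    return ax


def plot_cell_correlation(clustering, ax=None):
    """Cell-cell Spearman heatmap ordered by the dendrogram leaves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    order = clustering.leaf_order
    mat = clustering.correlation.loc[order, order]
    im = ax.imshow(mat.to_numpy(), cmap="viridis", vmin=-1, vmax=1)
    ax.set_xticks([])
    ax.set_yticks([])
    plt.colorbar(im, ax=ax, label="Spearman rho")
    return ax
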