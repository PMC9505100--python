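"""Figure helpers: per-slice AUC boxplots with slab shading."""

from __future__ import annotations

import numpy as np

from .volume import SLAB_RANGES

_SLAB_COLORS = ("#d62728", "#ffbf00", "#9467bd", "#2ca02c")  # slabs 1-4


def plot_auc_distributions(results, projection: str, ax=None):
    """Boxplot of the replica AUC distribution at every slice.

    Real models only; slabs are shaded in the conventional four colours
    and 1.5 x IQR outliers appear as open circles (matplotlib default).
    """
    import matplotlib.pyplot as plt

    sub = results.auc_slices.query(
        "projection == @projection and model_kind == 'real'"
    )
    if sub.empty:
        raise ValueError(f"no real-model AUCs for projection {projection!r}")
    coords = np.sort(sub["coordinate"].unique())
    data = [sub.loc[sub["coordinate"] == c, "auc"].to_numpy() for c in coords]
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    for (lo, hi), color in zip(SLAB_RANGES[projection], _SLAB_COLORS):
        ax.axvspan(lo - 0.5, hi + 0.5, color=color, alpha=0.12, lw=0)
    ax.boxplot(data, positions=coords, widths=0.7, whis=1.5, manage_ticks=False)
    ax.axhline(0.5, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(f"{projection} slice coordinate")
    ax.set_ylabel("AUC")
    ax.set_ylim(0, 1)
    ax.set_title(f"{projection} replica AUC distributions")
    return ax
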