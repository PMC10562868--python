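"""Minimal plotting helpers hanging off the result objects."""

from __future__ import annotations

import numpy as np


def plot_profile_heatmap(model, ax=None):
    """LFC heatmap of genes (rows, grouped by cluster) x factors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    order = model.labels.sort_values().index
    data = model.profile.loc[order].to_numpy()
    lim = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(model.profile.shape[1]))
    ax.set_xticklabels(model.profile.columns, rotation=90, fontsize=7)
    ax.set_ylabel("genes (grouped by cluster)")
    ax.figure.colorbar(im, ax=ax, label="LFC (log2 IP/total)")
    return ax


def plot_property_boxes(values, labels, property_name="property", ax=None):
    """Notched boxplots of one property per cluster plus the all-gene box."""
    import matplotlib.pyplot as plt
    import pandas as pd

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    vals = pd.Series(values).reindex(labels.index)
    groups = [vals.dropna().to_numpy()]
    names = ["all"]
    for c in sorted(pd.unique(labels)):
        groups.append(vals[labels == c].dropna().to_numpy())
        names.append(str(c))
    ax.boxplot(groups, notch=True, tick_labels=names, showfliers=False)
    ax.set_xlabel("cluster")
    ax.set_ylabel(property_name)
    return ax
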