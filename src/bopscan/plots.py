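"""Figure helpers for signature results: MDS scatter and signature heatmap.

Thin matplotlib wrappers; all statistics are computed by the library
functions, these only render.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

GROUP_COLORS = {"DSP": "#d62728", "DSS": "#1f77b4", "DSM": "#2ca02c"}


def plot_mds(coords: pd.DataFrame, groups: pd.Series, path) -> None:
    """Scatter the 2-D embedding, coloured by sample group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, sub in coords.groupby(groups.reindex(coords.index)):
        ax.scatter(
            sub["dim1"], sub["dim2"], s=18,
            color=GROUP_COLORS.get(str(group), "grey"), label=str(group),
        )
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_signature_heatmap(
    matrix: pd.DataFrame,
    groups: pd.Series | None,
    row_linkage: np.ndarray,
    col_linkage: np.ndarray,
    path,
) -> None:
    """Heatmap of the signature matrix with dendrogram-ordered rows/columns.

    ``matrix`` is probes x samples; linkages must come from
    :func:`bopscan.signature.hierarchical_cluster` on label-sorted axes.
    """
    row_order = hierarchy.leaves_list(row_linkage)
    col_order = hierarchy.leaves_list(col_linkage)
    rows = sorted(matrix.index.astype(str))
    cols = sorted(matrix.columns.astype(str))
    ordered = matrix.loc[[rows[i] for i in row_order], [cols[i] for i in col_order]]

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(ordered.to_numpy(dtype=float), aspect="auto", cmap="RdYlBu_r", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="beta")
    ax.set_yticks(range(len(ordered.index)))
    ax.set_yticklabels(ordered.index, fontsize=5)
    ax.set_xticks(range(len(ordered.columns)))
    ax.set_xticklabels(ordered.columns, fontsize=5, rotation=90)
    if groups is not None:
        for tick in ax.get_xticklabels():
            tick.set_color(GROUP_COLORS.get(str(groups.get(tick.get_text(), "")), "black"))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
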