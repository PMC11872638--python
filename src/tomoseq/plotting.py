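"""Optional figures: correlation heatmap with cluster bar, and Z-score traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def correlation_heatmap(cm, assignment=None, path=None):
    """Section x section Pearson correlation heatmap in physical order,
    with a cluster-identity bar when an assignment is given."""
    fig, ax = plt.subplots(figsize=(6, 5.5))
    im = ax.imshow(cm.r.to_numpy(), cmap="viridis", origin="lower", aspect="auto")
    ax.set_xlabel("section (epi → endo)")
    ax.set_ylabel("section (epi → endo)")
    fig.colorbar(im, ax=ax, label="Pearson r")
    if assignment is not None:
        labels = assignment.labels.to_numpy()
        ax2 = ax.inset_axes([0, 1.01, 1, 0.04])
        ax2.imshow(labels[None, :], cmap="tab10", aspect="auto")
        ax2.set_xticks([])
        ax2.set_yticks([])
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def zscore_traces(profile_df, path=None):
    """Fig-style spatial Z-score traces from a long-format profile table."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    for gene, grp in profile_df.groupby("gene"):
        ax.plot(grp["position"], grp["z"], label=gene, lw=1.2)
    ax.set_xlabel("section position (epi → endo)")
    ax.set_ylabel("expression Z-score")
    ax.axhline(0, color="grey", lw=0.6)
    ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
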