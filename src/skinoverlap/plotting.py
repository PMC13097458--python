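"""Plain figure exports: overlap heatmaps and CIELAB scatter previews."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .dataset import SkinDataset  # noqa: E402
from .matrices import OverlapMatrix  # noqa: E402

__all__ = ["plot_overlap_heatmap", "plot_lab_scatter"]


def plot_overlap_heatmap(matrix: OverlapMatrix, path) -> None:
    """White-to-blue heatmap of an overlap matrix (rows = reference)."""
    k = matrix.n_groups
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * k, 1.0 + 0.6 * k))
    im = ax.imshow(matrix.values, cmap="Blues", vmin=0, vmax=100)
    ax.set_xticks(range(k), matrix.groups)
    ax.set_yticks(range(k), matrix.groups)
    ax.set_xlabel("comparison group")
    ax.set_ylabel("reference group")
    ax.set_title(f"{matrix.method} overlap (%)")
    for i in range(k):
        for j in range(k):
            v = matrix.values[i, j]
            ax.text(j, i, f"{v:.1f}", ha="center", va="center",
                    color="white" if v > 60 else "black", fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lab_scatter(dataset: SkinDataset, path) -> None:
    """a*b* and L*C* scatter of the dataset, one colour per group."""
    from .colorimetry import chroma

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for g in dataset.groups:
        lab = dataset.lab(g)
        axes[0].scatter(lab[:, 1], lab[:, 2], s=2, alpha=0.4, label=g)
        axes[1].scatter(chroma(lab), lab[:, 0], s=2, alpha=0.4, label=g)
    axes[0].set_xlabel("a*"), axes[0].set_ylabel("b*")
    axes[1].set_xlabel("C*"), axes[1].set_ylabel("L*")
    axes[0].legend(markerscale=4, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
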