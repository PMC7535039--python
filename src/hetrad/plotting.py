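"""Optional matplotlib output: histogram pairs, correlation heatmap, PCA scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .quantize import HistogramPair
from .stats import HabitatComparisonResults


def plot_histogram_pair(hist: HistogramPair, path: str, title: str = "") -> None:
    """Shared-scale intensity histograms of the two habitats."""
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    width = np.diff(hist.bin_edges)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(centers, hist.density_rec, width=width, alpha=0.55, label="recurrent")
    ax.bar(centers, hist.density_nonrec, width=width, alpha=0.55, label="non-recurrent")
    ax.set_xlabel("intensity")
    ax.set_ylabel("relative frequency")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation_heatmap(results: HabitatComparisonResults, path: str) -> None:
    """Pearson r of paired differences; insignificant cells are blanked."""
    if results.corr is None:
        raise ValueError("no correlation matrix in results")
    r = results.corr.to_numpy().copy()
    masked = np.where(results.corr_mask.to_numpy(), r, np.nan)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.imshow(masked, vmin=-1, vmax=1, cmap="coolwarm")
    names = list(results.corr.columns)
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(names)), names, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r (p < 0.05)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca_scatter(results: HabitatComparisonResults, path: str) -> None:
    """PC1/PC2 scatter of the pooled region vectors."""
    if results.pca is None:
        raise ValueError("no PCA in results")
    sc = results.pca.scores
    evf = results.pca.explained_variance_fraction
    fig, ax = plt.subplots(figsize=(5, 4))
    for region, marker in (("recurrent", "o"), ("nonrecurrent", "s")):
        sel = sc["region"] == region
        ax.scatter(sc.loc[sel, "PC1"], sc.loc[sel, "PC2"], marker=marker, label=region, alpha=0.8)
    ax.set_xlabel(f"PC1 ({100 * evf[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * evf[1]:.0f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
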