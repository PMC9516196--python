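"""Figure output: SNP-index genome scans and clustered log2FC heat maps."""

from __future__ import annotations

import os
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .deg import ClusterResult
from .mapping import PeakRegion, ScanResult


def plot_snp_index(
    scan: ScanResult,
    peaks: Sequence[PeakRegion] = (),
    path: str | os.PathLike | None = None,
    chrom: str | None = None,
):
    """Per-site SNP-index dots with the windowed mean and shaded peak regions.

    One panel per chromosome (or a single panel when ``chrom`` is given),
    the style of a bulked-segregant mapping plot: dots near 1 mark the
    selected causal region, dots near 0.5 the unlinked background.
    """
    chroms = [chrom] if chrom else sorted(scan.sites["chrom"].unique())
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(9, 2.2 * len(chroms)), squeeze=False, sharey=True
    )
    for ax, name in zip(axes.ravel(), chroms):
        sites = scan.sites[scan.sites["chrom"] == name]
        wins = scan.windows[scan.windows["chrom"] == name]
        ax.scatter(sites["pos"] / 1e6, sites["snp_index"], s=8, alpha=0.6, label="SNP index")
        mid = (wins["start"] + wins["end"]) / 2 / 1e6
        ax.plot(mid, wins["mean_index"], color="firebrick", lw=1.5, label="window mean")
        for p in peaks:
            if p.chrom == name:
                ax.axvspan(p.start / 1e6, p.end / 1e6, color="grey", alpha=0.3)
        ax.set_ylim(-0.05, 1.05)
        ax.set_ylabel("SNP index")
        ax.set_title(name, fontsize=9)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    axes.ravel()[0].legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(str(path), dpi=120)
        plt.close(fig)
    return fig


def plot_log2fc_heatmap(result: ClusterResult, path: str | os.PathLike | None = None):
    """Leaf-ordered log2FC heat map from a clustering result."""
    data = result.ordered.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4, 6))
    vmax = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(result.col_order)))
    ax.set_xticklabels(result.col_order, rotation=90, fontsize=8)
    ax.set_yticks([])
    ax.set_ylabel(f"{data.shape[0]} genes (complete linkage, Euclidean)")
    fig.colorbar(im, ax=ax, label="log2FC")
    fig.tight_layout()
    if path is not None:
        fig.savefig(str(path), dpi=120)
        plt.close(fig)
    return fig
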