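"""Manhattan plots of genome-wide tracks with called regions shaded."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .genotype_io import chrom_sort_key
from .regions import Region
from .stats import AssocTrack

__all__ = ["manhattan_plot"]


def manhattan_plot(track: AssocTrack, regions: Optional[Sequence[Region]] = None,
                   out_path=None, threshold: Optional[float] = None):
    """Alternating-color per-chromosome scatter of the track.

    P-value tracks are drawn as -log10(p) with a horizontal line at
    -log10(threshold) (e.g. the Bonferroni threshold); other tracks (Fst)
    are drawn on their own scale.  ``regions`` are shaded spans in genome
    coordinates.  Returns the Matplotlib figure (also written to
    ``out_path`` when given).
    """
    if len(track) == 0:
        raise ValueError("cannot plot an empty track")
    is_p = track.statistic.endswith("_p")
    vals = np.asarray(track.values, dtype=float)
    y = -np.log10(vals) if is_p else vals

    chrom_list = sorted(set(track.chroms), key=chrom_sort_key)
    offsets: dict[str, int] = {}
    cum = 0
    for c in chrom_list:
        offsets[c] = cum
        cum += int(np.asarray(track.positions)[np.asarray(track.chroms) == c].max()) + 1

    x = np.array([offsets[c] for c in track.chroms], dtype=float) + track.positions

    fig, ax = plt.subplots(figsize=(10, 3.5))
    colors = ("#30508c", "#8ca0c8")
    for i, c in enumerate(chrom_list):
        mask = np.asarray(track.chroms) == c
        ax.scatter(x[mask], y[mask], s=4, color=colors[i % 2], rasterized=True)

    if regions:
        for r in regions:
            ax.axvspan(offsets[r.chrom] + r.start_bp, offsets[r.chrom] + r.end_bp,
                       color="#d9822b", alpha=0.3, zorder=0)

    if is_p and threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", linestyle="--", linewidth=1)

    centers = [offsets[c] + np.asarray(track.positions)[np.asarray(track.chroms) == c].mean()
               for c in chrom_list]
    ax.set_xticks(centers)
    ax.set_xticklabels(chrom_list, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(f"-log10({track.statistic})" if is_p else track.statistic)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
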