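"""Candidate-gene annotation of called regions.

Gene intervals come from BED (0-based half-open) or TSV (1-based closed)
files and are matched to VGRs as *inside* (gene contained in the region),
*overlapping* (partial intersection) or *proximal* (gap up to ``flank_bp``).
The gap between closed intervals [a, b] and [c, d] with b < c is c - b.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .genotype_io import chrom_sort_key
from .regions import VGR

__all__ = ["GeneInterval", "AnnotationHit", "read_gene_intervals", "annotate_regions",
           "hits_to_dataframe"]

DEFAULT_FLANK_BP = 3_000_000


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start_bp: int  # 1-based closed
    end_bp: int
    name: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.name}: start > end")


@dataclass(frozen=True)
class AnnotationHit:
    vgr_index: int
    gene: str
    relation: str  # inside | overlapping | proximal
    distance_bp: int
    source_tag: str = ""


def read_gene_intervals(source: Union[str, Path], fmt: str = "bed") -> list[GeneInterval]:
    """Parse gene intervals; BED is converted to internal 1-based closed."""
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"format must be 'bed' or 'tsv', got {fmt!r}")
    genes: list[GeneInterval] = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{fmt.upper()} line {lineno}: expected >= 4 columns")
            try:
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            except ValueError as e:
                raise ValueError(f"{fmt.upper()} line {lineno}: {e}") from None
            tag = parts[4] if len(parts) > 4 else ""
            if fmt == "bed":
                start, end = start + 1, end
            if end < start:
                raise ValueError(f"{fmt.upper()} line {lineno}: end < start")
            genes.append(GeneInterval(chrom, start, end, name, tag))
    genes.sort(key=lambda g: (chrom_sort_key(g.chrom), g.start_bp, g.end_bp))
    return genes


def annotate_regions(vgrs: Sequence[VGR], genes: Sequence[GeneInterval],
                     flank_bp: int = DEFAULT_FLANK_BP) -> list[AnnotationHit]:
    """Match genes to VGRs on the same chromosome.

    A gene fully contained in the region is *inside*; any other intersection
    is *overlapping* (both distance 0); otherwise a gap of at most
    ``flank_bp`` yields a *proximal* hit carrying the gap size.
    """
    hits: list[AnnotationHit] = []
    for v in vgrs:
        for g in genes:
            if g.chrom != v.chrom:
                continue
            if g.start_bp <= v.end_bp and v.start_bp <= g.end_bp:
                rel = ("inside" if v.start_bp <= g.start_bp and g.end_bp <= v.end_bp
                       else "overlapping")
                hits.append(AnnotationHit(v.index, g.name, rel, 0, g.source_tag))
            else:
                gap = (v.start_bp - g.end_bp if g.end_bp < v.start_bp
                       else g.start_bp - v.end_bp)
                if gap <= flank_bp:
                    hits.append(AnnotationHit(v.index, g.name, "proximal", gap,
                                              g.source_tag))
    return hits


def hits_to_dataframe(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"vgr": h.vgr_index, "gene": h.gene, "relation": h.relation,
          "distance_bp": h.distance_bp, "source_tag": h.source_tag} for h in hits],
        columns=["vgr", "gene", "relation", "distance_bp", "source_tag"])
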