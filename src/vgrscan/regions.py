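"""Variable-genomic-region (VGR) calling.

A scan track is ranked (rank 1 = most extreme), the top ``n_top`` markers
seed regions, each seed is extended to secondary markers (top
``secondary_fraction`` of ranked markers) within ``window_bp`` up- or
downstream on the same chromosome, overlapping or book-ended regions are
merged, and finally regions supported by both scan types (interval
intersection) are reported as VGR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import chrom_sort_key
from .stats import AssocTrack

__all__ = [
    "RegionParams",
    "Region",
    "VGR",
    "rank_scores",
    "call_regions",
    "merge_regions",
    "intersect_region_sets",
    "recovery_score",
    "regions_to_bed",
    "vgrs_to_dataframe",
]


@dataclass(frozen=True)
class RegionParams:
    n_top: int = 50
    secondary_fraction: float = 0.005
    window_bp: int = 1_500_000

    def __post_init__(self) -> None:
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")
        if not 0.0 < self.secondary_fraction <= 1.0:
            raise ValueError("secondary_fraction must be in (0, 1]")
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")


@dataclass
class Region:
    """A called region: closed 1-based interval with its peak marker."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_marker_id: str
    peak_pos_bp: int
    peak_value: float
    member_marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("region start must be <= end")
        if not self.start_bp <= self.peak_pos_bp <= self.end_bp:
            raise ValueError("peak must lie within the region")


@dataclass
class VGR:
    """A region supported by both scans, with per-method peaks."""

    index: int
    chrom: str
    start_bp: int
    end_bp: int
    fst_peak: Optional[tuple[int, float]] = None    # (pos_bp, theta)
    emmax_peak: Optional[tuple[int, float]] = None  # (pos_bp, p)

    def __post_init__(self) -> None:
        if self.fst_peak is None and self.emmax_peak is None:
            raise ValueError("a VGR needs at least one source peak")


def rank_scores(values: np.ndarray, direction: str) -> np.ndarray:
    """Ranks with 1 = most extreme; NaN entries are excluded (rank NaN).

    ``direction`` is "desc" (largest value best, e.g. Fst) or "asc"
    (smallest best, e.g. p-values).  Ties go to the earlier genome position,
    i.e. the lower index in a (chrom, pos)-sorted track.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("cannot rank an all-NaN track")
    if direction == "desc":
        key = -v[finite]
    elif direction == "asc":
        key = v[finite]
    else:
        raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")
    idx = np.flatnonzero(finite)
    order = np.lexsort((idx, key))  # primary: key, secondary: genome order
    ranks = np.full(v.size, np.nan)
    ranks[idx[order]] = np.arange(1, idx.size + 1)
    return ranks


def call_regions(track: AssocTrack, params: RegionParams = RegionParams(),
                 direction: Optional[str] = None) -> list[Region]:
    """Peak-extension region calling on one track.

    T1 = markers ranked <= n_top; T2 = markers ranked <= ceil(
    secondary_fraction * N_ranked).  Each T1 seed spans itself plus all T2
    markers within window_bp on the same chromosome; overlapping or
    book-ended spans are merged transitively, the merged peak being the
    best-ranked member.
    """
    if direction is None:
        direction = "asc" if track.statistic.endswith("_p") else "desc"
    ranks = rank_scores(track.values, direction)
    n_ranked = int(np.isfinite(ranks).sum())
    n_top = params.n_top
    if n_ranked < n_top:
        warnings.warn(f"only {n_ranked} ranked markers < n_top={n_top}; using all",
                      stacklevel=2)
        n_top = n_ranked
    n_t2 = math.ceil(params.secondary_fraction * n_ranked)

    with np.errstate(invalid="ignore"):
        t1 = np.flatnonzero(ranks <= n_top)
        t2 = np.flatnonzero(ranks <= n_t2)
    pos = np.asarray(track.positions, dtype=np.int64)
    chroms = np.asarray(track.chroms, dtype=object)

    raw: list[Region] = []
    for s in t1:
        near = t2[(chroms[t2] == chroms[s])
                  & (np.abs(pos[t2] - pos[s]) <= params.window_bp)]
        members = np.union1d(near, [s])
        best = members[np.nanargmin(ranks[members])]
        raw.append(Region(
            chrom=str(chroms[s]),
            start_bp=int(pos[members].min()),
            end_bp=int(pos[members].max()),
            peak_marker_id=str(track.marker_ids[best]),
            peak_pos_bp=int(pos[best]),
            peak_value=float(track.values[best]),
            member_marker_ids=[str(track.marker_ids[j]) for j in members],
        ))
    return merge_regions(raw, ranks, track)


def merge_regions(raw: Sequence[Region], ranks: np.ndarray,
                  track: AssocTrack) -> list[Region]:
    """Transitively merge overlapping or book-ended regions per chromosome."""
    id_to_idx = {str(m): j for j, m in enumerate(track.marker_ids)}
    out: list[Region] = []
    for chrom in sorted({r.chrom for r in raw}, key=chrom_sort_key):
        rs = sorted((r for r in raw if r.chrom == chrom), key=lambda r: (r.start_bp, r.end_bp))
        cur: Optional[Region] = None
        members: set[str] = set()
        for r in rs:
            if cur is None or r.start_bp > cur.end_bp:
                if cur is not None:
                    out.append(_finalize(cur, members, id_to_idx, ranks, track))
                cur = Region(r.chrom, r.start_bp, r.end_bp, r.peak_marker_id,
                             r.peak_pos_bp, r.peak_value, list(r.member_marker_ids))
                members = set(r.member_marker_ids)
            else:
                cur.end_bp = max(cur.end_bp, r.end_bp)
                members |= set(r.member_marker_ids)
        if cur is not None:
            out.append(_finalize(cur, members, id_to_idx, ranks, track))
    return out


def _finalize(region: Region, members: set[str], id_to_idx, ranks, track) -> Region:
    idx = sorted((id_to_idx[m] for m in members))
    best = min(idx, key=lambda j: ranks[j])
    pos = np.asarray(track.positions)
    return Region(
        chrom=region.chrom,
        start_bp=int(min(pos[j] for j in idx)),
        end_bp=int(max(pos[j] for j in idx)),
        peak_marker_id=str(track.marker_ids[best]),
        peak_pos_bp=int(pos[best]),
        peak_value=float(track.values[best]),
        member_marker_ids=[str(track.marker_ids[j]) for j in idx],
    )


def _overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def intersect_region_sets(fst_regions: Sequence[Region],
                          emmax_regions: Sequence[Region],
                          require_both: bool = True) -> list[VGR]:
    """VGRs from connected components of the cross-method overlap graph.

    Closed intervals; zero-length regions act as points.  With
    ``require_both`` (default) only components containing a region from each
    method are reported; the VGR interval is the union span of its component.
    The Fst peak is the component's largest-theta Fst-side peak, the EMMAX
    peak its smallest-p EMMAX-side peak.
    """
    tagged = ([("fst", r) for r in fst_regions] + [("emmax", r) for r in emmax_regions])
    vgrs: list[VGR] = []
    for chrom in sorted({r.chrom for _, r in tagged}, key=chrom_sort_key):
        rs = sorted(((t, r) for t, r in tagged if r.chrom == chrom),
                    key=lambda tr: (tr[1].start_bp, tr[1].end_bp))
        comp: list[tuple[str, Region]] = []
        max_end = None
        for t, r in rs:
            if max_end is not None and r.start_bp > max_end:
                vgrs.extend(_component_vgr(comp, require_both))
                comp, max_end = [], None
            comp.append((t, r))
            max_end = r.end_bp if max_end is None else max(max_end, r.end_bp)
        if comp:
            vgrs.extend(_component_vgr(comp, require_both))
    vgrs.sort(key=lambda v: (chrom_sort_key(v.chrom), v.start_bp))
    for i, v in enumerate(vgrs, start=1):
        v.index = i
    return vgrs


def _component_vgr(comp, require_both) -> list[VGR]:
    sides = {t for t, _ in comp}
    if require_both and sides != {"fst", "emmax"}:
        return []
    fst_rs = [r for t, r in comp if t == "fst"]
    emx_rs = [r for t, r in comp if t == "emmax"]
    fst_peak = None
    if fst_rs:
        best = max(fst_rs, key=lambda r: r.peak_value)
        fst_peak = (best.peak_pos_bp, best.peak_value)
    emmax_peak = None
    if emx_rs:
        best = min(emx_rs, key=lambda r: r.peak_value)
        emmax_peak = (best.peak_pos_bp, best.peak_value)
    return [VGR(index=0, chrom=comp[0][1].chrom,
                start_bp=min(r.start_bp for _, r in comp),
                end_bp=max(r.end_bp for _, r in comp),
                fst_peak=fst_peak, emmax_peak=emmax_peak)]


# ---------------------------------------------------------------------------
# Recovery scoring against simulated truth


def recovery_score(vgrs: Sequence[VGR],
                   truth_intervals: Sequence[tuple[str, int, int]],
                   slack_bp: int = 0) -> tuple[float, int]:
    """(sensitivity, false-positive count) of called VGRs against planted
    intervals; overlap is tested on the planted interval widened by
    ``slack_bp`` on each side."""
    recovered = 0
    hit_any = [False] * len(vgrs)
    for chrom, start, end in truth_intervals:
        lo, hi = start - slack_bp, end + slack_bp
        found = False
        for i, v in enumerate(vgrs):
            if v.chrom == str(chrom) and _overlap(v.start_bp, v.end_bp, lo, hi):
                found = True
                hit_any[i] = True
        recovered += found
    sensitivity = recovered / len(truth_intervals) if truth_intervals else float("nan")
    false_pos = sum(1 for h in hit_any if not h)
    return sensitivity, false_pos


# ---------------------------------------------------------------------------
# Serialization


def regions_to_bed(regions: Sequence[Region], path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.peak_marker_id}\n")


def vgrs_to_dataframe(vgrs: Sequence[VGR]) -> pd.DataFrame:
    rows = []
    for v in vgrs:
        rows.append({
            "vgr": v.index, "chrom": v.chrom,
            "start_bp": v.start_bp, "end_bp": v.end_bp,
            "fst_peak_pos": v.fst_peak[0] if v.fst_peak else np.nan,
            "fst_peak_value": v.fst_peak[1] if v.fst_peak else np.nan,
            "emmax_peak_pos": v.emmax_peak[0] if v.emmax_peak else np.nan,
            "emmax_peak_p": v.emmax_peak[1] if v.emmax_peak else np.nan,
        })
    cols = ["vgr", "chrom", "start_bp", "end_bp", "fst_peak_pos",
            "fst_peak_value", "emmax_peak_pos", "emmax_peak_p"]
    return pd.DataFrame(rows, columns=cols)
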