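"""Two-population genotype simulation under the Balding-Nichols model.

Each marker draws an ancestral allele frequency p0 ~ Uniform(0.05, 0.95);
each population then draws its own frequency from
Beta(p0 (1 - F) / F, (1 - p0)(1 - F) / F), so that loci have expected
differentiation F.  Neutral loci use ``f_background``; loci inside a planted
region use that region's ``f_selected``, giving strongly divergent intervals
with known ground truth.  Genotypes are Binomial(2, p_pop) per individual
(Hardy-Weinberg within population); optional full-sib pairs are produced by
gene-dropping from two simulated parents; missingness is i.i.d.  Everything
is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, Marker, Sample, MISSING, chrom_sort_key

__all__ = ["PlantedRegion", "SimConfig", "SimTruth", "simulate_dataset",
           "default_array_scale_config"]


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start_bp: int
    end_bp: int
    f_selected: float = 0.5

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("planted region start > end")
        if not 0.0 <= self.f_selected < 1.0:
            raise ValueError("f_selected must be in [0, 1)")


@dataclass
class SimConfig:
    """Study-condition defaults: two cohorts of 41 and 141 diploids, ~1%
    missingness, background divergence F = 0.05."""

    n_pop_a: int = 41
    n_pop_b: int = 141
    n_chrom: int = 5
    markers_per_chrom: int = 1000
    chrom_length_bp: int = 100_000_000
    f_background: float = 0.05
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    missing_rate: float = 0.01
    n_sib_pairs: int = 0  # full-sib pairs per population
    seed: int = 0
    chrom_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.f_background < 1.0:
            raise ValueError("f_background must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        names = self.chromosomes()
        if len(names) != self.n_chrom:
            raise ValueError("chrom_names length must equal n_chrom")
        for r in self.planted_regions:
            if r.chrom not in names:
                raise ValueError(f"planted region on unknown chromosome {r.chrom!r}")
            if r.end_bp > self.chrom_length_bp:
                raise ValueError("planted region exceeds chromosome length")
        for n_pop in (self.n_pop_a, self.n_pop_b):
            if 2 * self.n_sib_pairs > n_pop:
                raise ValueError("2 * n_sib_pairs cannot exceed the population size")

    def chromosomes(self) -> list[str]:
        return list(self.chrom_names) if self.chrom_names else [
            str(i + 1) for i in range(self.n_chrom)]


@dataclass
class SimTruth:
    """Planted intervals plus per-locus simulation parameters."""

    planted: list[PlantedRegion]
    marker_ids: np.ndarray
    p0: np.ndarray
    p_a: np.ndarray
    p_b: np.ndarray
    f: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def planted_intervals(self) -> list[tuple[str, int, int]]:
        return [(r.chrom, r.start_bp, r.end_bp) for r in self.planted]

    def loci_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"marker_id": self.marker_ids, "p0": self.p0,
                             "p_a": self.p_a, "p_b": self.p_b, "f": self.f})

    def planted_to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.planted:
                fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                         f"f={r.f_selected:g}\n")


def _unique_positions(rng: np.random.Generator, m: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=m))
    while pos.size < m:
        extra = rng.integers(1, length + 1, size=m - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:m])


def _balding_nichols(rng: np.random.Generator, p0: np.ndarray, f: np.ndarray) -> np.ndarray:
    p = p0.copy()
    drift = f > 0
    if drift.any():
        ratio = (1.0 - f[drift]) / f[drift]
        p[drift] = rng.beta(p0[drift] * ratio, (1.0 - p0[drift]) * ratio)
    return p


def _population_genotypes(rng: np.random.Generator, n: int, n_sib_pairs: int,
                          p: np.ndarray) -> np.ndarray:
    """n x m dosages: unrelated individuals first, then full-sib pairs
    gene-dropped from two simulated (unobserved) parents per pair."""
    m = p.size
    n_unrel = n - 2 * n_sib_pairs
    blocks = [rng.binomial(2, p[None, :], size=(n_unrel, m)).astype(np.int8)]
    if n_sib_pairs:
        parents = rng.binomial(2, p[None, None, :], size=(n_sib_pairs, 2, m))
        for _ in range(2):  # two sibs per pair, independent transmissions
            child = (rng.binomial(1, parents[:, 0, :] / 2.0)
                     + rng.binomial(1, parents[:, 1, :] / 2.0))
            blocks.append(child.astype(np.int8))
        # interleave so each pair's sibs are adjacent
        sibs = np.stack(blocks[1:], axis=1).reshape(2 * n_sib_pairs, m)
        blocks = [blocks[0], sibs]
    return np.concatenate(blocks, axis=0)


def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate a labeled two-population dataset and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = sorted(config.chromosomes(), key=chrom_sort_key)

    all_chrom, all_pos = [], []
    for c in chroms:
        pos = _unique_positions(rng, config.markers_per_chrom, config.chrom_length_bp)
        all_chrom.extend([c] * pos.size)
        all_pos.append(pos)
    pos = np.concatenate(all_pos)
    chrom_arr = np.array(all_chrom, dtype=object)
    m = pos.size

    f = np.full(m, config.f_background)
    truth_warnings = []
    for r in config.planted_regions:
        inside = (chrom_arr == r.chrom) & (pos >= r.start_bp) & (pos <= r.end_bp)
        if not inside.any():
            msg = f"planted region {r.chrom}:{r.start_bp}-{r.end_bp} contains no marker"
            warnings.warn(msg, stacklevel=2)
            truth_warnings.append(msg)
        f[inside] = r.f_selected

    p0 = rng.uniform(0.05, 0.95, size=m)
    p_a = _balding_nichols(rng, p0, f)
    p_b = _balding_nichols(rng, p0, f)

    ga = _population_genotypes(rng, config.n_pop_a, config.n_sib_pairs, p_a)
    gb = _population_genotypes(rng, config.n_pop_b, config.n_sib_pairs, p_b)
    geno = np.concatenate([ga, gb], axis=0)
    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = MISSING

    marker_ids = np.array([f"snp_{c}_{p}" for c, p in zip(chrom_arr, pos)], dtype=object)
    markers = [Marker(str(mid), str(c), int(p), "A", "G")
               for mid, c, p in zip(marker_ids, chrom_arr, pos)]
    samples = ([Sample(f"A{i + 1:04d}", "A") for i in range(config.n_pop_a)]
               + [Sample(f"B{i + 1:04d}", "B") for i in range(config.n_pop_b)])

    dataset = GenotypeDataset(markers=markers, samples=samples, genotypes=geno)
    truth = SimTruth(planted=list(config.planted_regions), marker_ids=marker_ids,
                     p0=p0, p_a=p_a, p_b=p_b, f=f, warnings=truth_warnings)
    return dataset, truth


def default_array_scale_config(seed: int = 0) -> SimConfig:
    """Array-scale study conditions: 41 + 141 diploids, 26 autosomes + X with
    ~46.5k markers total, ten 2-Mb planted regions at F = 0.5 over a
    background of F = 0.05, 1% missingness."""
    chrom_names = [str(i) for i in range(1, 27)] + ["X"]
    planted = [PlantedRegion(c, 40_000_000, 42_000_000, 0.5)
               for c in ("1", "3", "5", "7", "9", "11", "13", "15", "17", "20")]
    return SimConfig(
        n_pop_a=41, n_pop_b=141,
        n_chrom=27, markers_per_chrom=1724, chrom_length_bp=100_000_000,
        f_background=0.05, planted_regions=planted,
        missing_rate=0.01, n_sib_pairs=0, seed=seed, chrom_names=chrom_names,
    )
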