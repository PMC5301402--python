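"""PLINK text-format genotype I/O and marker-level quality control.

The in-memory model is a :class:`GenotypeDataset`: an ordered marker map,
a sample table with population labels, and an ``n_samples x n_markers``
dosage matrix counting copies of ``allele_b`` (0, 1, 2, or :data:`MISSING`).

Quality control mirrors the PLINK marker filters ``--geno`` (per-marker
missingness), ``--maf`` (minor-allele frequency) and ``--hwe`` (exact
Hardy-Weinberg test), applied in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "MISSING",
    "Marker",
    "Sample",
    "GenotypeDataset",
    "QCParams",
    "QCReport",
    "read_ped_map",
    "write_ped_map",
    "apply_qc",
    "chrom_sort_key",
]

#: Sentinel dosage for a missing genotype.
MISSING = -1

_SPECIAL_CHROMS = {"X": 100, "Y": 101, "XY": 102, "MT": 103, "M": 103}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Deterministic chromosome ordering: autosome numbers, then X/Y/XY/MT,
    then any other label lexicographically."""
    c = str(chrom).upper()
    if c.isdigit():
        return (int(c), "")
    if c in _SPECIAL_CHROMS:
        return (_SPECIAL_CHROMS[c], "")
    return (1000, c)


def is_autosome(chrom: str) -> bool:
    return str(chrom).upper().isdigit()


@dataclass(frozen=True)
class Marker:
    """A biallelic marker; ``allele_b`` is the counted (dosage) allele."""

    id: str
    chrom: str
    pos_bp: int
    allele_a: str = "0"
    allele_b: str = "0"

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.id}: pos_bp must be >= 1, got {self.pos_bp}")


@dataclass(frozen=True)
class Sample:
    id: str
    population: Optional[str] = None  # "A" or "B" once labeled
    sex: Optional[str] = None


@dataclass
class GenotypeDataset:
    """Markers sorted by (chrom, pos_bp), samples, and a dosage matrix.

    ``genotypes[i, j]`` is the number of copies of ``markers[j].allele_b``
    carried by ``samples[i]``, or :data:`MISSING`.
    """

    markers: list[Marker]
    samples: list[Sample]
    genotypes: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.markers):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        vals = np.unique(self.genotypes)
        bad = [v for v in vals if v not in (MISSING, 0, 1, 2)]
        if bad:
            raise ValueError(f"invalid genotype codes {bad}; expected 0/1/2/{MISSING}")
        ids = [mk.id for mk in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids are not unique")
        keys = [(chrom_sort_key(mk.chrom), mk.pos_bp) for mk in self.markers]
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("markers must be strictly sorted by (chrom, pos_bp)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> np.ndarray:
        return np.array([mk.id for mk in self.markers], dtype=object)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([mk.chrom for mk in self.markers], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.array([mk.pos_bp for mk in self.markers], dtype=np.int64)

    @property
    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.samples], dtype=object)

    def population_mask(self, label: str) -> np.ndarray:
        return np.array([s.population == label for s in self.samples])

    def autosome_mask(self) -> np.ndarray:
        return np.array([is_autosome(mk.chrom) for mk in self.markers])

    def subset_markers(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeDataset(
            markers=[self.markers[j] for j in idx],
            samples=list(self.samples),
            genotypes=self.genotypes[:, idx].copy(),
        )


@dataclass(frozen=True)
class QCParams:
    """Marker QC thresholds (PLINK ``--geno`` / ``--maf`` / ``--hwe``).

    ``hwe_population`` selects the sample for the exact Hardy-Weinberg test.
    The default tests population A only, mirroring PLINK's ``--hwe`` with a
    case/control phenotype (controls only).  Testing the pooled sample of
    two diverged cohorts rejects HWE at exactly the most differentiated
    markers (Wahlund effect) and would filter away the strongest signals.
    """

    max_missing_rate: float = 0.1
    min_maf: float = 0.05
    hwe_alpha: float = 0.001
    hwe_population: str = "population_A_only"  # pooled | per_population | population_A_only

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hwe_population not in ("pooled", "per_population", "population_A_only"):
            raise ValueError(f"unknown hwe_population {self.hwe_population!r}")


@dataclass
class QCReport:
    n_input: int
    n_pass: int
    removals: dict[str, int] = field(default_factory=dict)
    removed_markers: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_pass + sum(self.removals.values()) == self.n_input


# ---------------------------------------------------------------------------
# PED/MAP parsing


def _open(source: Union[str, Path, TextIO], mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def _read_map(map_source) -> list[Marker]:
    fh, close = _open(map_source)
    markers = []
    try:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"MAP line {lineno}: expected 4 columns, got {len(parts)}")
            chrom, mid, _cm, bp = parts
            markers.append(Marker(id=mid, chrom=chrom, pos_bp=int(bp)))
    finally:
        if close:
            fh.close()
    return markers


def read_ped_map(ped_source, map_source) -> GenotypeDataset:
    """Read PLINK text PED/MAP into a :class:`GenotypeDataset`.

    The counted allele at each marker is the lexicographically larger of the
    alleles observed there (a deterministic, dataset-independent choice; the
    differentiation statistics are invariant to it).  The PED phenotype
    column carries the population label: ``1`` -> "A", ``2`` -> "B",
    anything else -> unlabeled.
    """
    markers = _read_map(map_source)
    m = len(markers)

    samples: list[Sample] = []
    rows: list[list[str]] = []
    fh, close = _open(ped_source)
    try:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED line {lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2 x {m} markers), got {len(parts)}"
                )
            _fid, iid, _fa, _mo, sex, pheno = parts[:6]
            pop = {"1": "A", "2": "B"}.get(pheno)
            samples.append(Sample(id=iid, population=pop, sex=sex if sex in ("1", "2") else None))
            rows.append(parts[6:])
    finally:
        if close:
            fh.close()

    n = len(samples)
    allele_arr = np.array(rows, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2), object)

    geno = np.full((n, m), MISSING, dtype=np.int8)
    final_markers: list[Marker] = []
    for j, mk in enumerate(markers):
        a1 = allele_arr[:, j, 0]
        a2 = allele_arr[:, j, 1]
        observed = sorted(set(a1[a1 != "0"]) | set(a2[a2 != "0"]))
        if len(observed) > 2:
            raise ValueError(f"marker {mk.id}: more than two alleles observed: {observed}")
        if len(observed) == 2:
            allele_a, allele_b = observed[0], observed[1]
        elif len(observed) == 1:
            allele_a, allele_b = "0", observed[0]
        else:
            allele_a, allele_b = "0", "0"
        ok = (a1 != "0") & (a2 != "0")
        geno[ok, j] = (a1[ok] == allele_b).astype(np.int8) + (a2[ok] == allele_b).astype(np.int8)
        final_markers.append(Marker(mk.id, mk.chrom, mk.pos_bp, allele_a, allele_b))

    order = sorted(range(m), key=lambda j: (chrom_sort_key(final_markers[j].chrom),
                                            final_markers[j].pos_bp))
    return GenotypeDataset(
        markers=[final_markers[j] for j in order],
        samples=samples,
        genotypes=geno[:, order] if m else geno,
    )


def write_ped_map(dataset: GenotypeDataset, ped_sink, map_sink) -> None:
    """Write PLINK text PED/MAP; missing genotypes become ``0 0``."""
    fh, close = _open(map_sink, "w")
    try:
        for mk in dataset.markers:
            fh.write(f"{mk.chrom}\t{mk.id}\t0\t{mk.pos_bp}\n")
    finally:
        if close:
            fh.close()

    pheno_of = {"A": "1", "B": "2", None: "0"}
    geno = dataset.genotypes
    a_pairs = []
    for mk in dataset.markers:
        a, b = mk.allele_a, mk.allele_b
        a_pairs.append({0: f"{a} {a}", 1: f"{a} {b}", 2: f"{b} {b}", MISSING: "0 0"})
    fh, close = _open(ped_sink, "w")
    try:
        for i, s in enumerate(dataset.samples):
            pheno = pheno_of.get(s.population, "0")
            fid = s.population or "0"
            sex = s.sex or "0"
            cols = [fid, s.id, "0", "0", sex, pheno]
            cols.extend(a_pairs[j][int(geno[i, j])] for j in range(dataset.n_markers))
            fh.write(" ".join(cols) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# QC


def apply_qc(dataset: GenotypeDataset, params: QCParams = QCParams()) -> tuple[GenotypeDataset, QCReport]:
    """Sequential marker filters: missingness, then MAF, then exact HWE.

    Samples are never removed; marker order is preserved.  MAF is computed on
    the pooled non-missing genotypes (PLINK ``--maf``); the HWE test sample
    is controlled by ``params.hwe_population``.
    """
    from .stats import hwe_exact_test_vec  # deferred: stats imports this module

    geno = dataset.genotypes
    n, m = geno.shape
    if m == 0:
        raise ValueError("apply_qc requires a non-empty dataset")

    reason = np.full(m, "", dtype=object)
    miss_rate = (geno == MISSING).mean(axis=0)
    reason[miss_rate > params.max_missing_rate] = "missingness"

    alive = reason == ""
    nonmiss = geno != MISSING
    with np.errstate(invalid="ignore"):
        alt = np.where(nonmiss, geno, 0).sum(axis=0).astype(float)
        tot = 2.0 * nonmiss.sum(axis=0)
        freq = np.divide(alt, tot, out=np.full(m, np.nan), where=tot > 0)
    maf = np.fmin(freq, 1.0 - freq)
    fail_maf = alive & (np.isnan(maf) | (maf < params.min_maf))
    reason[fail_maf] = "maf"

    alive = reason == ""
    if alive.any():
        hwe_p = _hwe_pvalues(dataset, alive, params, hwe_exact_test_vec)
        fail_hwe = alive.copy()
        fail_hwe[alive] = hwe_p < params.hwe_alpha
        reason[fail_hwe] = "hwe"

    keep = reason == ""
    if not keep.any():
        warnings.warn("all markers removed by QC", stacklevel=2)
    removals: dict[str, int] = {}
    removed = []
    for r in ("missingness", "maf", "hwe"):
        ids = [dataset.markers[j].id for j in np.flatnonzero(reason == r)]
        removals[r] = len(ids)
        removed.extend((i, r) for i in ids)
    report = QCReport(n_input=m, n_pass=int(keep.sum()), removals=removals,
                      removed_markers=removed)
    return dataset.subset_markers(keep), report


def _genotype_counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return ((geno == 0).sum(axis=0), (geno == 1).sum(axis=0), (geno == 2).sum(axis=0))


def _hwe_pvalues(dataset, alive, params, hwe_vec) -> np.ndarray:
    sub = dataset.genotypes[:, alive]
    if params.hwe_population == "pooled":
        c0, c1, c2 = _genotype_counts(sub)
        return hwe_vec(c0, c1, c2)
    pops = [p for p in ("A", "B") if dataset.population_mask(p).any()]
    if params.hwe_population == "population_A_only":
        pops = ["A"]
    p = np.ones(sub.shape[1])
    for lab in pops:
        mask = dataset.population_mask(lab)
        if not mask.any():
            raise ValueError(f"hwe_population={params.hwe_population!r} but no samples "
                             f"labeled {lab!r}")
        c0, c1, c2 = _genotype_counts(sub[mask])
        p = np.minimum(p, hwe_vec(c0, c1, c2))
    return p
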