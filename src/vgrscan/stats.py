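"""Per-SNP population-differentiation statistics.

Implements the Weir & Cockerham (1984) two-population Fst estimator from its
variance components, the two-sided Fisher exact test on the 2x2 allele-count
table (PLINK tie convention: sum tables whose hypergeometric probability is
at most that of the observed table, with a small relative slack), the exact
conditional Hardy-Weinberg test, a generic Pearson chi-square, the genomic
inflation factor lambda, and the Bonferroni threshold.  Genome-wide "tracks"
apply a statistic to every marker of a :class:`~vgrscan.genotype_io.GenotypeDataset`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

from .genotype_io import MISSING, GenotypeDataset, is_autosome

__all__ = [
    "GenotypeCounts",
    "SnpCounts",
    "FstResult",
    "AssocTrack",
    "weir_cockerham_fst",
    "fisher_allelic_test",
    "hwe_exact_test",
    "hwe_exact_test_vec",
    "pearson_chi_square",
    "genomic_inflation",
    "bonferroni_threshold",
    "fst_track",
    "fisher_track",
]

# Tie slack for "probability <= observed" sums in the exact tests.
_TIE_REL = 1e-7

_CHI2_MEDIAN_1DF = sps.chi2.ppf(0.5, df=1)  # 0.4549364...


class GenotypeCounts(NamedTuple):
    """Genotype counts for one population at one biallelic SNP."""

    n_AA: int
    n_Aa: int
    n_aa: int

    @property
    def n_ind(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


class SnpCounts(NamedTuple):
    """Per-population genotype counts at one SNP."""

    pop_a: GenotypeCounts
    pop_b: GenotypeCounts


@dataclass(frozen=True)
class FstResult:
    """Weir-Cockerham variance components and theta = a / (a + b + c).

    ``a``: among-population, ``b``: among individuals within populations,
    ``c``: within-individual.  ``defined`` is False when a + b + c = 0
    (marker monomorphic across both populations) or too few individuals.
    """

    a: float
    b: float
    c: float
    theta: float
    defined: bool


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984), r = 2 populations


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Vectorized variance components from per-population sample size,
    allele-A frequency and heterozygote frequency."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / np.where(denom != 0.0, denom, 1.0), np.nan)
    usable = (nbar > 1.0) & (n1 >= 1) & (n2 >= 1) & (nc > 0)
    defined = usable & (denom != 0.0) & np.isfinite(theta)
    theta = np.where(defined, theta, np.nan)
    return a, b, c, theta, defined


def weir_cockerham_fst(counts: SnpCounts) -> FstResult:
    """Weir-Cockerham Fst estimate for one SNP in two populations."""
    res = []
    for pop in counts:
        n = pop.n_ind
        if n < 1:
            raise ValueError("weir_cockerham_fst requires n_ind >= 1 in both populations")
        res.append((n, (2 * pop.n_AA + pop.n_Aa) / (2 * n), pop.n_Aa / n))
    (n1, p1, h1), (n2, p2, h2) = res
    a, b, c, theta, defined = _wc_components(n1, p1, h1, n2, p2, h2)
    return FstResult(float(a), float(b), float(c), float(theta), bool(defined))


# ---------------------------------------------------------------------------
# Fisher exact allelic test (2x2, two-sided, PLINK tie convention)


def _fisher_p_vec(k_obs, m1, kk, nn) -> np.ndarray:
    """Two-sided Fisher p for 2x2 tables with first-cell count ``k_obs``,
    row-1 margin ``m1``, column-1 margin ``kk`` and total ``nn`` (arrays)."""
    k_obs = np.atleast_1d(np.asarray(k_obs, dtype=np.int64))
    m1 = np.atleast_1d(np.asarray(m1, dtype=np.int64))
    kk = np.atleast_1d(np.asarray(kk, dtype=np.int64))
    nn = np.atleast_1d(np.asarray(nn, dtype=np.int64))

    lf = gammaln(np.arange(int(nn.max()) + 2, dtype=np.float64) + 1.0)  # lf[k] = log k!
    m1c, kkc, nnc = m1[:, None], kk[:, None], nn[:, None]
    m2c = nnc - m1c
    log_denom = (lf[nn] - lf[kk] - lf[nn - kk])[:, None]

    def logpmf(k):  # k: (M, W) within the hypergeometric support
        return (lf[m1c] - lf[k] - lf[m1c - k]
                + lf[m2c] - lf[kkc - k] - lf[m2c - (kkc - k)]
                - log_denom)

    lo = np.maximum(0, kk - (nn - m1))
    hi = np.minimum(kk, m1)
    width = int((hi - lo).max()) + 1
    ks = lo[:, None] + np.arange(width)[None, :]
    valid = ks <= hi[:, None]
    ks_safe = np.where(valid, ks, lo[:, None])

    lp = logpmf(ks_safe)
    lp_obs = logpmf(k_obs[:, None])[:, 0]
    take = valid & (lp <= lp_obs[:, None] + np.log1p(_TIE_REL))
    # normalize within the support for numerical safety
    lz = logsumexp(np.where(valid, lp, -np.inf), axis=1)
    p = np.exp(np.where(take, lp, -np.inf) - lz[:, None]).sum(axis=1)
    return np.minimum(p, 1.0)


def allele_table(counts: SnpCounts) -> np.ndarray:
    """2x2 allele-count table: rows = populations, columns = alleles (A, a)."""
    rows = [(2 * p.n_AA + p.n_Aa, 2 * p.n_aa + p.n_Aa) for p in counts]
    return np.array(rows, dtype=np.int64)


def fisher_allelic_test(counts: SnpCounts) -> float:
    """Two-sided Fisher exact p-value for the 2x2 allele-count table."""
    if counts.pop_a.n_ind < 1 or counts.pop_b.n_ind < 1:
        raise ValueError("fisher_allelic_test requires both populations non-empty")
    t = allele_table(counts)
    return float(_fisher_p_vec(t[0, 0], t[0].sum(), t[:, 0].sum(), t.sum())[0])


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test


def hwe_exact_test_vec(n_AA, n_Aa, n_aa) -> np.ndarray:
    """Vectorized exact HWE p-values; monomorphic (or empty) markers get 1.0.

    Conditional on the diploid count n and the minor-allele count, sums the
    probabilities of all heterozygote counts whose conditional probability is
    at most that of the observed count.
    """
    n_AA = np.atleast_1d(np.asarray(n_AA, dtype=np.int64))
    n_Aa = np.atleast_1d(np.asarray(n_Aa, dtype=np.int64))
    n_aa = np.atleast_1d(np.asarray(n_aa, dtype=np.int64))
    if (n_AA < 0).any() or (n_Aa < 0).any() or (n_aa < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    na = 2 * n_AA + n_Aa
    minor = np.minimum(na, 2 * n - na)

    lf = gammaln(np.arange(int(2 * n.max()) + 2, dtype=np.float64) + 1.0)  # lf[k] = log k!
    ln2 = np.log(2.0)

    par = minor % 2
    n_support = minor // 2 + 1
    width = int(n_support.max())
    ks = par[:, None] + 2 * np.arange(width)[None, :]
    valid = ks <= minor[:, None]
    ks = np.where(valid, ks, par[:, None])

    nA = np.where(na <= n, na, 2 * n - na)  # relabel so nA is the minor allele
    hom_minor = (nA[:, None] - ks) // 2
    hom_major = (2 * n[:, None] - nA[:, None] - ks) // 2
    lp = (lf[n][:, None] - lf[hom_minor] - lf[ks] - lf[hom_major]
          + ks * ln2 + lf[nA][:, None] + lf[2 * n - nA][:, None] - lf[2 * n][:, None])
    lp_obs = np.take_along_axis(lp, ((n_Aa - par) // 2)[:, None], axis=1)[:, 0]

    take = valid & (lp <= lp_obs[:, None] + np.log1p(_TIE_REL))
    lz = logsumexp(np.where(valid, lp, -np.inf), axis=1)
    p = np.exp(np.where(take, lp, -np.inf) - lz[:, None]).sum(axis=1)
    p = np.where(n == 0, 1.0, np.minimum(p, 1.0))
    return p


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one marker."""
    if n_AA + n_Aa + n_aa < 1:
        raise ValueError("hwe_exact_test requires at least one genotyped individual")
    return float(hwe_exact_test_vec(n_AA, n_Aa, n_aa)[0])


# ---------------------------------------------------------------------------
# Pearson chi-square on an R x C table


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Classic Pearson chi-square test of independence on an R x C table.

    Rows/columns with a zero margin are dropped (with a warning) before the
    degrees of freedom are computed.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    rows = t.sum(axis=1) > 0
    cols = t.sum(axis=0) > 0
    if (~rows).any() or (~cols).any():
        warnings.warn("dropping zero-margin rows/columns before chi-square", stacklevel=2)
        t = t[rows][:, cols]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least 2 non-zero rows and columns")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


# ---------------------------------------------------------------------------
# Genomic inflation and Bonferroni


def genomic_inflation(values, kind: str = "p") -> float:
    """Genomic inflation factor lambda = median(chi2) / median(chi2_1df).

    ``kind="p"`` converts p-values to 1-df chi-square quantiles first;
    ``kind="chi2"`` takes the values as chi-square statistics.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("genomic_inflation requires at least one finite value")
    if kind == "p":
        chi2 = sps.chi2.isf(np.clip(v, 0.0, 1.0), df=1)
    elif kind == "chi2":
        chi2 = v
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Genome-wide tracks


@dataclass
class AssocTrack:
    """Per-marker scores for one statistic, aligned to a marker map."""

    marker_ids: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    statistic: str  # "fst" | "fisher_p" | "emmax_p"
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.marker_ids)
        if not (len(self.chroms) == len(self.positions) == len(self.values) == n):
            raise ValueError("track columns must have equal length")
        if self.statistic.endswith("_p"):
            v = self.values[np.isfinite(self.values)]
            if v.size and ((v <= 0).any() or (v > 1).any()):
                raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "chrom": self.chroms,
            "pos_bp": self.positions,
            self.statistic: self.values,
        })

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, statistic: Optional[str] = None) -> "AssocTrack":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        stat = statistic or [c for c in df.columns
                             if c not in ("marker_id", "chrom", "pos_bp")][0]
        return cls(df["marker_id"].to_numpy(object), df["chrom"].to_numpy(object),
                   df["pos_bp"].to_numpy(np.int64), stat, df[stat].to_numpy(float))


def population_counts(dataset: GenotypeDataset):
    """Per-marker genotype counts (c0, c1, c2) for populations A and B."""
    out = []
    for lab in ("A", "B"):
        mask = dataset.population_mask(lab)
        if not mask.any():
            raise ValueError(f"population {lab!r} is empty")
        g = dataset.genotypes[mask]
        out.append(((g == 0).sum(axis=0), (g == 1).sum(axis=0), (g == 2).sum(axis=0)))
    return out


def fst_track(dataset: GenotypeDataset) -> AssocTrack:
    """Per-marker Weir-Cockerham theta; autosomes only (X markers get NaN)."""
    (a0, a1, a2), (b0, b1, b2) = population_counts(dataset)
    n1 = a0 + a1 + a2
    n2 = b0 + b1 + b2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = (2 * a2 + a1) / (2 * n1)
        h1 = a1 / n1
        p2 = (2 * b2 + b1) / (2 * n2)
        h2 = b1 / n2
    *_, theta, defined = _wc_components(n1, p1, h1, n2, p2, h2)
    theta = np.where(defined, theta, np.nan)
    auto = dataset.autosome_mask()
    theta = np.where(auto, theta, np.nan)
    if ((n1 == 0) | (n2 == 0)).any():
        warnings.warn("markers with all genotypes missing in one population get NaN",
                      stacklevel=2)
    return AssocTrack(dataset.marker_ids, dataset.chroms, dataset.positions,
                      "fst", theta)


def fisher_track(dataset: GenotypeDataset) -> AssocTrack:
    """Per-marker two-sided Fisher exact allelic p-values (all chromosomes)."""
    (a0, a1, a2), (b0, b1, b2) = population_counts(dataset)
    alt1 = 2 * a2 + a1
    alt2 = 2 * b2 + b1
    m1 = 2 * (a0 + a1 + a2)
    m2 = 2 * (b0 + b1 + b2)
    ok = (m1 > 0) & (m2 > 0)
    p = np.full(dataset.n_markers, np.nan)
    if ok.any():
        p[ok] = _fisher_p_vec(alt1[ok], m1[ok], alt1[ok] + alt2[ok], m1[ok] + m2[ok])
    if (~ok).any():
        warnings.warn("markers with all genotypes missing in one population get NaN",
                      stacklevel=2)
    return AssocTrack(dataset.marker_ids, dataset.chroms, dataset.positions,
                      "fisher_p", p)
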