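"""EMMAX-style mixed-model association.

The model is y = X beta + u + e with Var(u) = sigma_g^2 K (K an IBS kinship
matrix) and Var(e) = sigma_e^2 I.  Variance components are estimated once on
the null model by restricted maximum likelihood, profiled over the single
ratio delta = sigma_e^2 / sigma_g^2 via the eigendecomposition of the
projected kinship (the EMMA algorithm: grid search on log10(delta) followed
by root polishing of the REML derivative).  Each marker is then tested by
generalized least squares with the variance components held fixed, i.e. an
ordinary regression after whitening by V^(-1/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "EmmaxScanResult",
    "ibs_kinship",
    "emma_reml",
    "emmax_scan",
    "population_phenotype",
]


@dataclass
class KinshipMatrix:
    """Symmetric IBS relationship matrix with unit diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, columns=self.sample_ids).to_csv(
            path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(float), list(df.columns))


@dataclass
class VarianceComponents:
    """REML estimates: delta = sigma_e^2 / sigma_g^2, the two components,
    and the restricted log-likelihood at the optimum."""

    delta: float
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    boundary: bool = False  # optimum on (or likelihood flat across) the grid edge


@dataclass
class EmmaxScanResult:
    marker_ids: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    statistic: np.ndarray
    p_values: np.ndarray
    phenotype: np.ndarray
    vc: VarianceComponents

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids, "chrom": self.chroms,
            "pos_bp": self.positions, "beta": self.beta, "se": self.se,
            "stat": self.statistic, "emmax_p": self.p_values,
        })

    def to_track(self):
        from .stats import AssocTrack
        return AssocTrack(self.marker_ids, self.chroms, self.positions,
                          "emmax_p", self.p_values)


def population_phenotype(dataset: GenotypeDataset) -> np.ndarray:
    """Population indicator used as the quantitative trait: A -> 0, B -> 1."""
    pops = dataset.populations
    if not (np.any(pops == "A") and np.any(pops == "B")):
        raise ValueError("both populations must be non-empty")
    return (pops == "B").astype(float)


# ---------------------------------------------------------------------------
# IBS kinship


def ibs_kinship(dataset: GenotypeDataset, chroms: str = "autosomes") -> KinshipMatrix:
    """Pairwise identity-by-state: K_ij = mean over markers non-missing in
    both i and j of (2 - |g_i - g_j|) / 2.

    ``chroms`` selects the marker set ("autosomes" by default, or "all").
    """
    if chroms == "autosomes":
        g = dataset.genotypes[:, dataset.autosome_mask()]
    elif chroms == "all":
        g = dataset.genotypes
    else:
        raise ValueError(f"unknown chromosome set {chroms!r}")
    if g.shape[1] == 0:
        raise ValueError("no markers available for kinship")

    ind = [np.asarray(g == d, dtype=np.float32) for d in (0, 1, 2)]
    i0, i1, i2 = ind
    shared = (2.0 * (i0 @ i0.T + i1 @ i1.T + i2 @ i2.T)
              + (i0 @ i1.T + i1 @ i0.T + i1 @ i2.T + i2 @ i1.T))
    nonmiss = i0 + i1 + i2
    overlap = nonmiss @ nonmiss.T
    if (overlap == 0).any():
        i, j = np.argwhere(overlap == 0)[0]
        raise ValueError(
            f"samples {dataset.samples[i].id!r} and {dataset.samples[j].id!r} "
            "share no genotyped marker")
    k = np.asarray(shared, dtype=float) / (2.0 * np.asarray(overlap, dtype=float))
    k = (k + k.T) / 2.0
    np.fill_diagonal(k, 1.0)
    return KinshipMatrix(k, [s.id for s in dataset.samples])


# ---------------------------------------------------------------------------
# EMMA REML in delta


def _reml_pieces(lam: np.ndarray, eta2: np.ndarray, m: int):
    """Restricted log-likelihood and its delta-derivative, profiled in
    sigma_g^2, as closures over the projected eigenvalues and squared
    rotated phenotype."""

    const = 0.5 * m * (np.log(m / (2.0 * np.pi)) - 1.0)

    def loglik(delta: float) -> float:
        d = lam + delta
        return float(const - 0.5 * m * np.log(np.sum(eta2 / d)) - 0.5 * np.sum(np.log(d)))

    def dloglik(delta: float) -> float:
        d = lam + delta
        s1 = np.sum(eta2 / d)
        s2 = np.sum(eta2 / d**2)
        return float(0.5 * (m * s2 / s1 - np.sum(1.0 / d)))

    return loglik, dloglik


def emma_reml(y: np.ndarray, X: Optional[np.ndarray], K,
              ngrids: int = 100, llim: float = -10.0, ulim: float = 10.0
              ) -> VarianceComponents:
    """REML variance components for y = X beta + u + e, Var = sigma_g^2 K +
    sigma_e^2 I, maximized over log10(delta) in [llim, ulim].

    ``X`` defaults to an intercept.  Returns the optimum over the grid plus
    all interior stationary points of the restricted likelihood.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("emma_reml requires at least 3 samples")
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    q = X.shape[1]
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("fixed-effect design X must have full column rank")
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    if Kv.shape != (n, n):
        raise ValueError("K must be n x n")

    scale = max(1.0, float(np.abs(Kv).max()))
    kmin = float(np.linalg.eigvalsh(Kv)[0])
    if kmin < -1e-8 * scale:
        raise ValueError(f"K is not positive semidefinite (min eigenvalue {kmin:.3g})")

    # project out the fixed effects, then eigendecompose S K S
    XtX_inv = np.linalg.inv(X.T @ X)
    S = np.eye(n) - X @ XtX_inv @ X.T
    SKS = S @ Kv @ S
    SKS = (SKS + SKS.T) / 2.0
    w, U = np.linalg.eigh(SKS)
    lam = np.clip(w[q:], 0.0, None)      # n - q informative eigenvalues
    Us = U[:, q:]
    eta = Us.T @ y
    eta2 = eta**2
    if np.sum(eta2) <= 0:
        raise ValueError("phenotype lies in the span of the fixed effects")
    m = n - q

    loglik, dloglik = _reml_pieces(lam, eta2, m)

    grid_log10 = np.linspace(llim, ulim, ngrids + 1)
    grid = 10.0 ** grid_log10
    ll = np.array([loglik(d) for d in grid])
    dl = np.array([dloglik(d) for d in grid])

    flat = (ll.max() - ll.min()) < 1e-8 * max(1.0, abs(ll.max()))
    candidates = [grid[0], grid[-1]]
    for i in range(ngrids):
        if np.sign(dl[i]) > 0 and np.sign(dl[i + 1]) < 0:
            root = optimize.brentq(dloglik, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-12)
            candidates.append(root)
    lls = [loglik(d) for d in candidates]
    best = int(np.argmax(lls))
    if flat:
        delta, best_ll, boundary = grid[-1], float(ll[-1]), True
    else:
        delta, best_ll = float(candidates[best]), float(lls[best])
        boundary = best < 2  # optimum stuck at a grid edge

    sigma_g2 = float(np.sum(eta2 / (lam + delta)) / m)
    sigma_e2 = float(delta * sigma_g2)
    return VarianceComponents(delta=float(delta), sigma_g2=sigma_g2,
                              sigma_e2=sigma_e2, reml_loglik=best_ll,
                              boundary=boundary)


# ---------------------------------------------------------------------------
# EMMAX per-marker scan


def emmax_scan(dataset: GenotypeDataset, phenotype: np.ndarray,
               kinship: KinshipMatrix, vc: VarianceComponents,
               test: str = "chi2") -> EmmaxScanResult:
    """Per-marker GLS association with fixed variance components.

    Genotypes are mean-imputed per marker, the phenotype/design/genotypes are
    whitened by V^(-1/2) with V = sigma_g2 K + sigma_e2 I, and each marker is
    tested in a whitened simple regression (intercept + dosage).  ``test`` is
    "chi2" (Wald against chi-square 1 df, the default) or "f" (F with n-2
    denominator df).  Both autosomes and X are scanned.
    """
    if test not in ("chi2", "f"):
        raise ValueError(f"unknown test {test!r}")
    y = np.asarray(phenotype, dtype=float).ravel()
    n = dataset.n_samples
    if y.size != n:
        raise ValueError("phenotype length must equal the number of samples")

    w, U = np.linalg.eigh(kinship.values)
    d = vc.sigma_g2 * np.clip(w, 0.0, None) + vc.sigma_e2
    if (d <= 0).any():
        raise ValueError("V = sigma_g2 K + sigma_e2 I is singular")
    T = (U / np.sqrt(d)).T  # rows of V^(-1/2) in the eigenbasis

    g = dataset.genotypes.astype(float)
    miss = dataset.genotypes == MISSING
    with np.errstate(invalid="ignore"):
        colmean = np.where(miss, 0.0, g).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1)
    g = np.where(miss, colmean[None, :], g)

    y1 = T @ y
    x1 = T @ np.ones(n)
    g1 = T @ g

    a11 = float(x1 @ x1)
    b1 = float(x1 @ y1)
    yy = float(y1 @ y1)
    a12 = x1 @ g1
    a22 = np.einsum("ij,ij->j", g1, g1)
    b2 = g1.T @ y1

    det = a11 * a22 - a12**2
    ok = det > 1e-12 * np.maximum(a11 * a22, 1e-300)
    det_safe = np.where(ok, det, 1.0)
    beta = (a11 * b2 - a12 * b1) / det_safe
    beta0 = (a22 * b1 - a12 * b2) / det_safe
    rss = np.maximum(yy - beta0 * b1 - beta * b2, 0.0)
    sigma2 = rss / max(n - 2, 1)
    var_beta = sigma2 * a11 / det_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(ok, beta**2 / var_beta, np.nan)
        # a perfect fit (zero residual) is infinitely significant, not undefined
        stat = np.where(ok & (var_beta <= 0), np.inf, stat)
    if test == "chi2":
        p = sps.chi2.sf(stat, df=1)
    else:
        p = sps.f.sf(stat, 1, n - 2)
    p = np.where(~np.isnan(stat), np.maximum(p, np.finfo(float).tiny), np.nan)
    beta = np.where(ok, beta, np.nan)
    se = np.where(ok & (var_beta > 0), np.sqrt(var_beta), np.nan)

    return EmmaxScanResult(dataset.marker_ids, dataset.chroms, dataset.positions,
                           beta, se, stat, p, y, vc)
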