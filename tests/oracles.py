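"""Independent reference implementations used only by the tests.

Each oracle is written from the defining formula or by exhaustive
enumeration, deliberately sharing no code with the package.
"""

from fractions import Fraction
from math import comb, ceil

import numpy as np


def wc_theta_reference(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham (1984) components for r populations, transcribed
    directly from the published ANOVA formulas (here r = 2)."""
    ns = [n1, n2]
    ps = [p1, p2]
    hs = [h1, h2]
    r = len(ns)
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    denom = a + b + c
    return a, b, c, (a / denom if denom != 0 else float("nan"))


def fisher_exact_enumeration(table):
    """Two-sided Fisher p by exact rational enumeration over all tables
    with the observed margins (sum of probabilities <= observed)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        probs[k] = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def hwe_exact_enumeration(n_AA, n_Aa, n_aa):
    """Exact HWE p by rational enumeration over heterozygote counts
    conditional on n and the minor-allele count."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_AA + n_Aa
    m = min(na, 2 * n - na)
    if m == 0:
        return 1.0
    denom = comb(2 * n, m)
    probs = {}
    for k in range(m % 2, m + 1, 2):
        probs[k] = Fraction(
            comb(n, (m - k) // 2) * comb(n - (m - k) // 2, k) * 2 ** k, denom)
        # remaining individuals are homozygous major: comb(n - hom_min - k, hom_maj) = 1
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def rank_reference(values, direction):
    """O(N^2) ranks: 1 + number of strictly better entries + earlier ties."""
    v = list(values)
    ranks = [float("nan")] * len(v)
    finite = [i for i, x in enumerate(v) if np.isfinite(x)]

    def better(i, j):  # does i rank above j?
        if v[i] != v[j]:
            return v[i] > v[j] if direction == "desc" else v[i] < v[j]
        return i < j

    for j in finite:
        ranks[j] = 1 + sum(1 for i in finite if i != j and better(i, j))
    return ranks


def call_regions_reference(chroms, positions, values, n_top, secondary_fraction,
                           window_bp, direction):
    """Literal rule application: T1 = top n_top ranks, T2 = top
    ceil(secondary_fraction * N) ranks, extend each T1 seed to T2 neighbors
    within the window on the same chromosome, then transitively merge
    overlapping or end-sharing spans.  Returns a sorted list of
    (chrom, start, end, peak_index) tuples."""
    ranks = rank_reference(values, direction)
    finite = [i for i, r in enumerate(ranks) if np.isfinite(r)]
    n_ranked = len(finite)
    k_top = min(n_top, n_ranked)
    k2 = ceil(secondary_fraction * n_ranked)
    t1 = [i for i in finite if ranks[i] <= k_top]
    t2 = {i for i in finite if ranks[i] <= k2}

    spans = []
    for s in t1:
        members = {s} | {t for t in t2
                         if chroms[t] == chroms[s]
                         and abs(positions[t] - positions[s]) <= window_bp}
        spans.append((chroms[s], min(positions[m] for m in members),
                      max(positions[m] for m in members), frozenset(members)))

    # transitive merge of overlapping/book-ended closed intervals per chrom
    merged = []
    changed = True
    while changed:
        changed = False
        merged = []
        for sp in sorted(spans, key=lambda x: (str(x[0]), x[1], x[2])):
            placed = False
            for i, m in enumerate(merged):
                if m[0] == sp[0] and sp[1] <= m[2] and m[1] <= sp[2]:
                    merged[i] = (m[0], min(m[1], sp[1]), max(m[2], sp[2]),
                                 m[3] | sp[3])
                    placed = True
                    changed = True
                    break
            if not placed:
                merged.append(sp)
        spans = merged

    out = []
    for chrom, start, end, members in spans:
        peak = min(members, key=lambda i: ranks[i])
        start = min(positions[m] for m in members)
        end = max(positions[m] for m in members)
        out.append((chrom, start, end, peak, tuple(sorted(members))))
    return sorted(out, key=lambda x: (str(x[0]), x[1]))
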