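# Methods

`vgrscan` scans SNP-array genotypes from two labeled cohorts for *variable
genomic regions* (VGR): intervals where the cohorts differ strongly in
allele frequency, as happens between a parental breed and a derived strain
after introgression and selection.  This note documents the models, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## Genotype model and quality control

Genotypes are dosages 0/1/2 of a per-marker reference allele, with a missing
code.  When reading PLINK text PED/MAP, the counted allele is the
lexicographically larger of the alleles observed at the marker — a
deterministic convention with no analytic consequence, since every statistic
in the package is invariant to allele relabeling (tested).  The population
label is taken from the PED phenotype column (1 → cohort A, 2 → cohort B),
the case/control convention.

Marker QC applies, in order: per-marker missingness (`--geno`, default
maximum 0.10), pooled minor-allele frequency (`--maf`, default minimum
0.05), and the exact conditional Hardy–Weinberg test (`--hwe`, default
p < 0.001 removes the marker).  Samples are never removed.

The HWE test sample matters more than it first appears.  Testing HWE on the
pooled sample of two diverged cohorts rejects preferentially at the *most
differentiated* markers — pooling creates a heterozygote deficit
proportional to the squared frequency difference (the Wahlund effect) — so a
pooled filter silently deletes the strongest signals.  On the array-scale
simulation below, a pooled test at p < 0.001 removes about 30 % of the
markers inside planted divergent regions, exactly the high-Fst ones, capping
the observable theta around 0.6.  PLINK itself, given a case/control
phenotype, restricts `--hwe` to controls; `vgrscan` therefore defaults to
testing cohort A only (`hwe_population="population_A_only"`), with
`pooled` and `per_population` available as options.

## Differentiation statistics

**Weir–Cockerham Fst.**  For two populations with sample sizes n₁, n₂,
reference-allele frequencies p₁, p₂ and heterozygote frequencies h₁, h₂,
the 1984 ANOVA estimator decomposes variance into among-population (a),
among-individual-within-population (b) and within-individual (c) components
and reports θ = a/(a+b+c).  The implementation follows the component
formulas exactly and is verified to 1e-12 against a second, independent
transcription.  θ is undefined (NaN) for monomorphic markers and when the
mean sample size is ≤ 1.  Following the array analysis it mirrors, θ is
computed for autosomes only; X-linked markers carry NaN in the Fst track.

**Fisher exact allelic test.**  The 2×2 allele-count table (cohorts ×
alleles) is tested two-sided by summing hypergeometric probabilities of all
tables, with the same margins, whose probability does not exceed the
observed table's (relative tie slack 1e-7, the PLINK convention).  A zero
margin yields p = 1.  Verified against exhaustive rational enumeration.
Being an exact conditional test it is *conservative*: its actual size at
α = 0.05 with 100 diploids per cohort and MAF ≥ 0.05 is ≈ 0.037–0.041, and
the median null p-value exceeds 0.5, so the genomic inflation factor of a
truly null Fisher track sits near 0.66 rather than 1.0 at those counts.
This is a property of the test, not an implementation artifact.

**Exact HWE test.**  Conditional on the diploid count and the minor-allele
count, heterozygote counts whose conditional probability is at most the
observed one are summed.  Verified against enumeration.

**Genomic inflation.**  λ = median(χ²)/0.4549, converting p-values to 1-df
chi-square quantiles when needed.  λ ≈ 1 indicates calibrated tests; λ ≫ 1
indicates structure or relatedness the test ignores.

**Bonferroni.**  α/N; at α = 0.05 and N = 46,563 markers this prints as
1.07 × 10⁻⁶.

## Mixed-model association (EMMAX)

The phenotype is the cohort indicator coded 0/1 and treated as quantitative,
exactly as a two-breed mixed-model GWAS does.  The model is
y = Xβ + u + e with Var(u) = σ²_g K and Var(e) = σ²_e I.

**Kinship** is pairwise identity-by-state: K_ij = mean over markers typed in
both samples of (2 − |g_i − g_j|)/2.  Missing genotypes are handled
pairwise-complete (no imputation) for K.  K is built from autosomal markers,
including each tested marker (no leave-one-chromosome-out); the
heterozygosity re-weighting some IBS implementations offer is not applied.

**REML** maximizes the restricted likelihood over the single ratio
δ = σ²_e/σ²_g using the eigendecomposition of the projected kinship
(fixed effects removed): a grid over log₁₀ δ ∈ [−10, 10] with 100 intervals,
followed by Brent root-polishing of the derivative between sign changes.  A
flat likelihood (e.g. K = I, where the restricted likelihood is constant in
δ) returns the upper grid edge with a degeneracy flag; optima stuck at a
grid edge are flagged the same way.  On block-kinship simulations with true
δ = 1 (n = 500), the median estimate over 200 replicates is ≈ 0.98.

**Scan.**  With (σ²_g, σ²_e) fixed from the null fit, the phenotype,
intercept and mean-imputed genotype vectors are whitened by V^(−1/2)
(V = σ²_g K + σ²_e I, via the eigendecomposition of K), and each marker is
tested in the whitened simple regression with a Wald χ²₁ statistic (an
F-test with n − 2 denominator df is available as a switch; at n = 182 the
difference is negligible).  A marker with zero genotype variance after
imputation gets NaN; a marker fitting the phenotype perfectly (zero
whitened residual) is reported at the smallest representable p rather than
NaN.  With K = I the scan reduces exactly to OLS (tested to 1e-8).  Both
autosomes and X are scanned.

## Region calling

Markers are ranked per track (rank 1 = largest θ, or smallest p; ties go to
the earlier genome position).  The top `n_top` (default 50) markers seed
regions; each seed spans itself plus all markers ranked in the top
`secondary_fraction` (default 0.5 %, as ⌈0.005·N⌉) lying within `window_bp`
(default 1.5 Mb) on the same chromosome.  Overlapping or end-sharing spans
merge transitively; the merged peak is the best-ranked member.  `n_top` is
an explicit count rather than a recomputed fraction because the published
rule itself rounded "~0.1 %" of ~46.5k markers to 50.  Neighbor extension is
anchored on top-tier seeds only; chains arise solely through merging.

A VGR is a connected component of the overlap graph between the Fst-side
and EMMAX-side region sets (closed intervals; zero-length regions are
points) that contains regions from both sides; its interval is the union
span and it carries both peaks.  Since Fst is not computed on X, X-linked
regions can only arise on the EMMAX side and never gain dual support — a
faithful consequence of the rule, not a bug.

Regions are 1-based closed internally and converted to 0-based half-open on
BED output.

## Candidate-gene annotation

Gene intervals (BED or 1-based TSV) are matched to VGRs as *inside*,
*overlapping* (distance 0) or *proximal*, where the gap between closed
intervals [a,b] and [c,d] with b < c is c − b and must not exceed
`flank_bp`.  The default flank of 3 Mb is a documented choice: the
qualitative "close to" usage it models includes genes sitting ~2.5 Mb from
a region boundary.

## Synthetic data

The generator draws, per marker, an ancestral frequency p₀ ~ U(0.05, 0.95)
and per-population frequencies from the Balding–Nichols distribution
Beta(p₀(1−F)/F, (1−p₀)(1−F)/F), so a locus simulated at divergence F has
expected Fst ≈ F (the Weir–Cockerham estimator is approximately unbiased
under this model; measured mean θ at F = 0.05 is within ±0.01).
Background loci use `f_background` (default 0.05); loci inside planted
regions use that region's `f_selected` (default 0.5).  Genotypes are
Binomial(2, p) per individual — Hardy–Weinberg within populations, no
linkage disequilibrium.  Optional full-sib pairs are gene-dropped from two
unobserved parents.  Missingness is i.i.d. (default 1 %).  Everything is
deterministic given the seed.

The array-scale configuration mirrors the study conditions this package
re-creates: cohorts of 41 and 141 diploids, 26 autosomes plus X with 1,724
markers each (46,548 total, within 1 % of the 46,563 markers of the real
array), ten 2-Mb planted regions at F = 0.5, 1 % missingness.  The 2-Mb
width (~34 markers at the ~58-kb spacing) reflects the multi-megabase
divergent tracts the 1.5-Mb peak-extension rule is designed for.

Because the generator has no LD, no allele-frequency ascertainment and no
real demography, passing recovery tests demonstrates that the *rule chain*
(QC → statistics → ranking → extension → intersection) behaves as
specified — not that the pipeline would achieve the same sensitivity on
real array data, where LD widens signals and background structure is not
exchangeable.

## Calibration experiments

* **Null split** (100 diploids per cohort, 5,000 markers, F = 0): mean θ is
  within ±0.01 of 0 and the EMMAX track's λ lies in [0.9, 1.1].  The
  Fisher track's empirical size at α = 0.05 is ≈ 0.037–0.041 — below the
  nominal 0.05 for the reason given above.
* **Confounding contrast** (600 diploids per cohort, every individual in a
  full-sib pair, F = 0, 10,000 markers): the naive Fisher scan inflates to
  λ ≈ 1.3 (full pairing multiplies the allele-frequency sampling variance
  by 1.5) while the mixed model stays at λ ≈ 1.06–1.09.  The cohort size
  is larger here than in the null split because at small counts Fisher's
  conservatism masks the inflation; at 600/cohort the two effects separate
  cleanly.  With background divergence F > 0 instead of sib pairs, EMMAX
  retains honest residual inflation (λ ≈ 1.1–1.3): per-marker drift
  variance is real signal a single kinship matrix cannot fully absorb —
  the same behavior reported for mixed-model scans of genuinely diverged
  breeds.
* **Planted-region recovery** (array scale, 20 seeds): median sensitivity
  1.0 with 0 median false-positive VGRs under the default calling
  parameters (n_top = 50, 0.5 % secondary tier, 1.5-Mb window, recovery
  slack 1.5 Mb).

## Known limitations

* No LD / recombination maps, no demographic histories, no phenotype
  simulation beyond the cohort label.
* Fst is two-population only; no haplotype statistics or permutation p.
* Binary PLINK BED/BIM/FAM is not parsed (text PED/MAP only).
* The X chromosome is simulated as diploid for all samples and never gains
  dual-method region support (no Fst on X).
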