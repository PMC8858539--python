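# Methods

## The analysis model

`lodsift` targets the setting where a quantitative trait (blood pressure)
has been measured in extended families, a handful of genomic regions show
variance-component linkage evidence, and the goal is to test rare variants
in those regions with as little multiple-testing burden as possible.

### Variance-component linkage

For family *j* with trait residual vector **y**_j (centered, study-adjusted,
medication-adjusted), the trait covariance at map position *t* is modeled as

    V_j(t) = 2 Φ_j σ²_a + Π_j(t) σ²_q + I σ²_e

with Φ_j the pedigree kinship matrix, Π_j(t) the matrix of expected
proportions of alleles shared identical-by-descent at *t*, σ²_a the additive
polygenic variance, σ²_q the locus variance and σ²_e the residual variance.
Both the null (σ²_q = 0) and the positional alternative are maximized by ML
jointly over families (the likelihood is a sum of family blocks, evaluated
with batched Cholesky/LU factorizations grouped by family size).
`LOD(t) = [ℓ_alt(t) − ℓ_null]/ln 10`, floored at zero for the reported total
profile. Family-specific LOD_j are per-family log-likelihood-ratio
contributions *at the global MLEs*; this is the conventional way per-family
LODs are reported, it guarantees Σ_j LOD_j equals the unfloored peak LOD
(asserted to 1e-8 in the tests), and individual LOD_j may legitimately be
negative.

Numerical choices: variances are optimized on the log scale (bounds
e^−20…e^6 on the standardized trait) by L-BFGS-B with three starts; one
start for the alternative is the null solution with σ²_q ≈ 0, which makes
ℓ_alt ≥ ℓ_null structural rather than hoped-for. Likelihood tolerance 1e-8.
The trait is standardized internally and variances are rescaled to trait
units on output.

### Multipoint IBD

Π_j(t) comes from an exact inheritance-vector HMM (Lander–Green): the hidden
state holds two meiosis bits per non-founder; between adjacent loci each bit
flips independently with the Haldane recombination fraction
θ = (1 − e^(−2d/100))/2; emissions sum over founder-allele assignments at
the population allele frequencies (founder-sample estimates by default).
Posteriors on the marker-plus-uniform grid are converted to pairwise
sharing by averaging allele-origin matches over states. Parent–offspring
pairs give Π = 0.5 identically — a structural invariant the tests assert —
and the posterior equals exhaustive enumeration on small families (oracle
test, < 1e-10).

Exact Lander–Green is exponential in the meiosis count, so families whose
MERLIN-style bit size 2n − f exceeds the configured cap (default 16) are
skipped and reported. Markers that are Mendelian-inconsistent within a
family are treated as missing for that family and reported. Single recorded
parents are completed with phantom unrelated founders before any pedigree
computation.

### Two-step selection

Step 1 keeps families with LOD_j > 0.1 (after removing two-member
parent–offspring families, which carry no linkage information) and variants
whose minor-allele count summed over members of those families is ≥ 2.
"Segregating at least twice" is ambiguous between *total MAC ≥ 2* and
*seen in ≥ 2 families*; the former is the default, the latter is
`count_mode="families"`. Step 2 computes the Pearson correlation r_i of
MAC_ij with LOD_j across the selected families, fits a two-component
Gaussian mixture to the r values of each gene by EM (percentile
initialization, three seeded restarts, variance floor 1e-6, tolerance 1e-8,
1000-iteration cap; the log-likelihood trace is asserted non-decreasing),
and keeps variants with r_i strictly above the midpoint of the two
component means — the Fisher-discriminant boundary under equal component
variances. Genes with fewer than 10 defined r values skip step 2.

The final per-gene set defaults to the union of the two steps. Because step
2 operates on step-1 variants, the literal union equals step 1; the stricter
`step2_filter` mode (step 2 with fallback to step 1 when step 2 was
skipped) and `intersection` are provided and recorded in the output
metadata, since published descriptions of this construction are
self-contradictory about whether step 2 filters or augments.

### Phenotype transformation

Treated individuals get +15 mmHg (SBP) and +10 mmHg (DBP) before analysis;
pulse pressure is derived *after* adjustment (so a treated individual's PP
rises by 5 mmHg; the raw-PP alternative is a flag). Within each ancestry
group the adjusted trait is residualized by OLS on age, age², sex, BMI,
center indicators, PCs (and optional extra covariates), transformed by
z = Φ⁻¹((rank − 0.5)/n) with average ranks on ties (Blom offsets by flag),
and multiplied by the standard deviation of the *raw pre-adjustment*
measurement within the individual's study. The same covariates are adjusted
again in the mixed model (two-stage adjustment); the null-calibration study
below confirms this does not distort type-I error.

### Association tests

The LMM null `y = Xβ + g + e`, cov(g) = σ²_g·2K, is fitted by REML (ML by
flag), profiling the variance ratio on per-block eigendecompositions of the
sparse kinship (fourth-degree threshold 2^−5.5 ≈ 0.0221; the KING
third-degree boundary 0.0884 drives the unrelated-subset filter). With
K = 0 the fit degenerates to OLS exactly.

Gene-based tests use Beta(1, 25) density weights at the analysis-sample MAF
(missing dosages mean-imputed first, MAF from non-missing genotypes). The
burden statistic is the GLS Wald test of the weighted allele sum under the
fitted null covariance — with V fixed at the null estimates this coincides
with the score test, which is why a single-variant set reproduces the
single-variant p exactly. SKAT uses Q = rᵀGW²Gᵀr with the projected
residuals r and the eigenvalues of the projected weighted kernel; tail
probabilities come from Imhof's characteristic-function inversion
(numerical quadrature, the Davies-type exact route; a single distinct
eigenvalue short-circuits to the scaled-χ² closed form), with Liu
moment-matching as the recorded fallback.

### Meta-analysis

Fisher's method: X² = −2Σ ln p ~ χ²(2k). The even-df tail is evaluated with
the finite Poisson series exp(−x/2)·Σ_{i<k}(x/2)^i/i! and cross-checked
against the continuous survival function at every call (1e-9 relative).
Zero p-values are an error unless the caller supplies an explicit floor —
silent flooring hides pathologies. The exome-wide constant 2.5e-6 and the
per-region/per-study Bonferroni thresholds are exposed as library
functions.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes: two studies with
different trait SDs (21 and 19 mmHg) in one ancestry, nuclear and
three-generation families, a uniform common-marker cM map (1 cM/Mb
pseudo-chromosome), genes tiled under the map midpoint, rare variants
planted on founder haplotypes, and latent BP built from
baseline + covariates + QTL + polygenic + noise with configured variance
fractions (defaults: h² = 0.35, QTL 0.15). Causal rare variants ride one
founder "risk haplotype" per carrier family and are transmitted through the
same simulated meioses as the markers, so family MAC, IBD sharing at the
QTL and family LODs are coupled the way the selection procedure assumes.
The polygenic component is multivariate normal with covariance 2Φσ²_a
(matching the downstream VC model; a gene-drop polygenic score would relax
that exactness but is not needed for these tests). Medication use is
logistic in the *latent* SBP (intercept −2.2, slope 0.06 per mmHg above
140), and treated individuals' observed pressures are latent minus 15/10 —
deliberately creating the bias the +15/+10 adjustment corrects, so the
adjustment is testable. DBP shares the QTL and has correlated residual
noise (ρ = 0.6) so SBP > DBP holds except for rare outliers, which load-time
QC drops.

What the generator does **not** emulate: realistic LD and allele-frequency
spectra, sequencing/imputation error, ancestry admixture, multiple real
chromosomes, or study-design heterogeneity beyond trait SD and centers.
Passing tests therefore demonstrate the *statistical machinery* — Mendelian
transmission, calibration, recovery, enrichment — not performance on real
WGS cohorts.

## Validation studies (experiments module)

Problem sizes are chosen so the full set runs in minutes on one CPU.

* **Type-I error.** 2000 replicates of the full null pipeline (100
  families, ~470 individuals, QTL variance 0): phenotypes redrawn,
  medication-adjusted, R-INT'd, REML null refitted on the sparse kinship,
  burden + SKAT run on a fixed 18-variant rare set. Both rejection rates at
  α = 0.05 must land in the exact binomial 95% interval.
* **Null MLOD.** 150 pure-noise replicates over an 11-position grid on a
  100-family cohort; the maximum LOD rarely approaches 3 (the pointwise
  ½χ²₁ reference rate at LOD 3 is 1e-4) and the median MLOD stays below
  0.25.
* **Recovery.** REML heritability (truth 0.4, 50 replicates of 300
  sib-quad families) and the EM mixture (π = 0.3, μ = (0, 0.6),
  σ = (0.1, 0.1), n = 500, 100 replicates) recover truth within 3
  Monte-Carlo standard errors of the replicate mean.
* **Selection enrichment.** 100 replicates of a cohort designed to carry
  the planted signal at desk scale: 100 families with 4–5 offspring, two
  genes of 30 rare variants each, three causal variants per gene on carrier
  haplotypes in 30% of families, jointly explaining 50% of trait variance,
  non-causal MAF 0.005–0.03 so the candidate pool segregates too. Family
  LODs are evaluated at the QTL position, the two-step selection runs, and
  the causal fraction of the step-2 set is compared with the causal
  fraction of all candidates (the size-matched random-draw expectation).
  Mean causal r_i exceeds non-causal r_i and the mean enrichment ratio
  exceeds 2. Earlier, smaller designs (50 small families, diffuse QTL)
  select no families at LOD_j > 0.1 in most replicates — with weak linkage
  evidence the weighting procedure has nothing to weight by, which is the
  expected behaviour, not a defect.
* **SKAT oracle.** Analytic mixture-of-χ² quantiles (Imhof) agree with 1e5
  Monte-Carlo quadratic-form draws at the 95th/99th percentiles within 2%.

## Known limitations

* Exact Lander–Green limits family size (bit cap); no Elston–Stewart
  fallback, dominance variance or X chromosome.
* The VC optimizer reports boundary fits (σ² → 0) as valid; standard errors
  of variance components are not produced.
* Imhof quadrature targets absolute error ~1e-10; for p below ~1e-14 the
  Liu fallback's accuracy governs.
* KING-robust is implemented per pair on shared non-missing variants; no
  ancestry-conditional (PC-AiR/PC-Relate) adjustment.
* The CLI stages exchange data through files in a run directory; there is
  no incremental caching beyond that.
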