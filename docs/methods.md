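# Methods

## Data model and conventions

All analyses consume marginal per-SNP summary statistics: effect size
`beta` (log-odds for binary traits, trait-SD or expression units
otherwise), its standard error, effect-allele frequency, p-value and sample
size. Coordinates are 1-based with closed intervals throughout (a SNP
exactly on a window boundary is inside). Thresholds follow strict
inequalities: instruments require `p < 5e-8` and `min(eaf, 1-eaf) > 0.01`.
On reading, rows violating the per-variant invariants (non-positive SE,
frequency outside (0,1), identical alleles, or a p-value inconsistent with
|beta/se| under a two-sided normal test beyond 10% relative tolerance) are
dropped and counted by reason rather than aborting the file.

### Harmonization

Outcome effects are aligned to the exposure's effect allele: swapped
alleles negate the outcome beta and flip its frequency; strand complements
(A↔T, C↔G) are resolved before the swap rule. Palindromic SNPs cannot be
strand-resolved from alleles alone, so they are kept only when both traits'
frequencies lie outside [0.42, 0.58] (band 0.08) and on the same side of
0.5; otherwise they are dropped as `palindromic-ambiguous`. The band
mirrors common two-sample-MR practice; it is a tunable parameter because no
universally agreed value exists. No proxy-SNP lookup is attempted: a SNP
missing from the outcome is dropped with a reason rather than substituted.

### Clumping

Greedy p-value clumping visits candidates in ascending p (ties broken
deterministically by chromosome, position, then SNP id) and accepts a SNP
unless an already-accepted SNP on the same chromosome lies within the
window (default 10 000 kb) *and* exceeds the r² threshold (default 0.001).
SNPs absent from the supplied LD matrix are treated as independent and
logged — the alternative (silently discarding them) would throw away signal
whenever the LD panel is incomplete.

## Two-sample MR estimators

- **IVW** is weighted regression of outcome on exposure betas through the
  origin with weights σ_Y⁻². The default is multiplicative random effects:
  the fixed-effect SE is scaled by max(1, √(Q/(n−1))). The floor at 1 means
  the estimator never claims more precision than the fixed-effect model;
  both variants are available because the upstream protocol does not state
  which was used. With one instrument IVW reduces exactly to the Wald
  ratio (SE = |σ_Y/β_X|, first-order delta method).
- **MR-Egger** adds an intercept, whose deviation from zero estimates
  directional pleiotropy. Because the intercept is not invariant to allele
  orientation, instruments are first oriented so every β_X ≥ 0. SEs carry a
  multiplicative overdispersion factor floored at 1; inference uses t with
  n−2 df (IVW and Wald use the normal distribution — a documented
  convention choice).
- **Weighted median**: the inverse-variance-weighted 50th percentile of the
  per-SNP ratios with linear interpolation between order statistics;
  consistent while valid instruments carry more than half the weight.
- **Mode estimators**: normal-kernel density over the ratios (unweighted or
  inverse-variance weighted) with bandwidth
  `factor · 0.9 · min(sd, IQR/1.349) · n^(−1/5)`, maximized on a 512-point
  grid spanning the ratios ± 3 bandwidths. If all ratios coincide the
  common value is returned directly.
- **Bootstrap SEs** (median and modes) are parametric: β̂_X and β̂_Y are
  resampled from normals at their SEs, 1000 replicates by default, with a
  mandatory seed — results are bit-reproducible.
- **Cochran's Q** uses weights β²_X/σ²_Y around the fixed-effect IVW
  estimate, referred to χ²(n−1).
- **MR-PRESSO**: the observed statistic is the weighted residual sum of
  squares of each SNP's outcome beta around its leave-one-out IVW
  prediction; the null distribution comes from parametric simulation under
  the fitted model, giving `global_p = (1 + #{RSS* ≥ RSS}) / (n_sim + 1)`.
  Outliers are flagged by per-SNP residual exceedance with Bonferroni
  correction. The distortion test is intentionally omitted — the pipeline
  uses MR-PRESSO only for detection.

The suite runner degrades gracefully (Wald only at n = 1; Q from n = 2;
Egger/median/modes from n = 3; MR-PRESSO from n = 4) and records
`direction_concordant`, true when all computed point estimates share the
IVW sign — the qualitative criterion used for sensitivity analyses.

## SMR and HEIDI

SMR tests expression→outcome at the top cis-eQTL (which must reach
p < 5×10⁻⁸; genes without such an instrument are skipped and counted):
`T_SMR = z²_G z²_E / (z²_G + z²_E)` against χ²₁, `b_xy = β_G/β_E`,
`se_xy = |b_xy|/√T_SMR`. T_SMR is invariant to rescaling either trait's
beta and SE by a common factor and tends to the smaller z² as the other
grows.

HEIDI selects SNPs with eQTL p < 1.57×10⁻³ (χ² > 10) and r² to the top SNP
in [0.05, 0.9], capped at the 20 smallest eQTL p-values (these are the
reference SMR-tool defaults; the lower r² bound keeps ratio denominators
away from zero, the upper bound avoids near-collinear duplicates). For each
selected SNP, d_i = b_xy(i) − b_xy(top); the covariance of d uses the
first-order delta method with within-trait covariances cov(β̂_i, β̂_j) ≈
r_ij σ_i σ_j and zero cross-trait covariance (non-overlapping studies
assumed). T_HEIDI = Σ z²_d is referred to Σ λ_k χ²₁ with λ the eigenvalues
of the correlation matrix of d, evaluated by Imhof numerical integration on
a transformed finite interval (exact scaled-χ² shortcut when all
eigenvalues coincide; Satterthwaite two-moment fallback if the quadrature's
error estimate exceeds 10⁻⁴). Fewer than 3 eligible SNPs yields
`p_heidi = not computed`; in the screening gate this does not reject the
gene, matching SMR-tool practice where an unavailable HEIDI p cannot
demonstrate heterogeneity. Measured on the synthetic single-causal-variant
scenario the test holds its nominal size (~5% rejections at α = 0.05), and
rejects two-variant linkage (r ≈ 0.4 between causal variants) essentially
always at strong effects.

## Colocalization

Per-SNP Wakefield log-ABFs use prior effect SD 0.2 for binary and 0.15 for
quantitative traits — the defaults of the R `coloc` package (its
case-control prior is the larger one because log-odds effects are
typically larger than SD-scale effects). Hypothesis sums are accumulated
entirely in log space (log-sum-exp; H3's off-diagonal sum via a stable
log1p complement), so |z| = 100 causes no overflow. Priors default to
p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵. Only beta/SE input is supported since the
data model always carries both; regions default to ±100 kb, closed
intervals. Fewer than 50 SNPs triggers a power warning, not an error.

## Pipeline gates

A screened gene is a hit iff (i) `p_smr` falls below the Bonferroni
threshold α/m, (ii) HEIDI does not reject (p ≥ 0.05 or not computable), and
(iii) PP.H4 > 0.9 in the coloc window around the top SNP. The denominator m
defaults to the full selected-gene count including genes without eQTL data
(an 88-style convention), switchable to the number of genes actually
tested. Every input gene appears in the report exactly once per tissue with
an explicit status; multiplicity is over genes, not gene × tissue, by
default. The dependence test reports both the 95% CI overlap and the
focal/excluded effect ratio without hard-coding a verdict, since "similar
effect sizes" has no formal criterion; with a zero flank and a focal locus
outside the gene region the excluded estimate equals the unrestricted IVW
on the same clumped set.

## Synthetic data

Two-sample scenarios draw independent instruments: maf ~ U(0.05, 0.45),
per-instrument exposure effects ±√(h²/m / 2maf(1−maf)) with total
h² = 0.05 over m instruments, SEs (2·maf(1−maf)·n)^(−1/2) with
n = 100 000 per sample — instruments then carry mean χ² ≈ 100/m·50,
comfortably genome-wide significant, as in large smoking-behaviour GWAS.
Pleiotropy adds α ~ N(mean, sd) to a configurable fraction of instruments
*relative to the exposure-increasing allele* (otherwise Egger's
orientation convention would average directional effects away); defaults
mean 0.03, sd 0.01. Binary outcomes are simulated directly on the log-odds
scale — the estimators only consume betas and SEs, so no liability
threshold model is needed.

Region scenarios use an AR(1) LD backbone r_ij = ρ^|i−j| (one parameter,
positive definite by construction, spans tight-LD and linkage contrasts),
default ρ = 0.9 over 120 SNPs spaced 1 kb. On the standardized-genotype
scale the marginal truth is exactly R·b_joint and observed betas are
MVN(R·b_joint, R/n) with SE n^(−1/2), keeping the math auditable. The
architecture enum (null / one-trait-only / distinct variants / shared
variant) maps onto coloc's H0–H4 and HEIDI's linkage scenario. eQTL
z-targets default to 30 (top blood cis-eQTLs in consortium-scale data are
routinely this strong) and GWAS z-targets to 10, with n_eQTL = 30 000 and
n_GWAS = 80 000.

The target-study generator builds a desk-scale screen: genes split between
an interaction-database table and a connectivity-score table (|score| > 90
passing, decoys below), a Bernoulli fraction (default 0.15) of non-causal
genes carrying no eQTL panel to exercise the exclusion path, causal genes
wired as shared-variant with a protective direction (higher expression,
lower risk), and non-causal genes as eQTL-only. The mediation generator
places a strong focal variant (z = 30) with tight LD partners inside a
gene region plus 30 independent background instruments; under full
mediation the focal Wald ratio equals the causal effect θ, while a direct
locus effect of equal size doubles it without moving the locus-excluded
IVW.

What the synthetic data do **not** emulate: realistic human LD maps,
allele-frequency/effect-size coupling from selection, sample overlap
between studies, population stratification, or winner's-curse selection of
instruments discovered in the same sample. Passing calibration here
therefore validates the estimators and the pipeline logic under their
stated assumptions, not robustness to those real-data complications.

## Problem sizes and numerical choices

The shipped calibration suites use 1000 replicates for IVW coverage/size
and HEIDI size, 500 for the pleiotropy-robustness contrasts, 200 for the
colocalization and linkage-power contrasts, 20 seeded end-to-end screens,
and 100 mediation replicates — sizes chosen so each suite's Monte-Carlo
error is small relative to the acceptance band it checks while the whole
run stays around a minute on one CPU. All stochastic routines take
explicit seeds; the CLI writes floats at 10 significant digits so repeated
runs are byte-identical. LD matrices are validated as symmetric,
unit-diagonal and PSD to 10⁻⁸ after eigenvalue clipping; Cholesky draws add
a 10⁻¹⁰ jitter.

## Known limitations

- No multivariable MR, Steiger filtering, CAUSE or contamination-mixture
  estimators; no SuSiE-based multi-causal colocalization or conditional
  analysis; trans-eQTLs are out of scope.
- No proxy-SNP substitution or LD computation from genotype panels; the LD
  matrix is always an input.
- MR-PRESSO omits the distortion test.
- The HEIDI delta-method covariance degrades when eQTL z-scores at
  selected SNPs are weak; the χ² > 10 selection filter mitigates but does
  not eliminate this.
- Real drug–gene interaction and connectivity tables must be supplied by
  the user as static files; the shipped tables are synthetic.
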