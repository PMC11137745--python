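# Methods

This note documents the models implemented by `efrsnet`, the defaults they
ship with, the design choices that were genuinely open, and what the
synthetic cohort does and does not establish about real data.

## Exome functional risk score

Variants are retained when their minor allele frequency is below a
threshold (default 0.01) in **both** reference panels (an East-Asian
1000-Genomes-style panel and an ExAC-style panel); a frequency missing from
one panel is treated as 0 for filtering, since absence from a panel is
itself evidence of rarity, but is excluded from the frequency-weight mean.
Each subject's score is Σ v_all · w_s · w_f over retained variants.

**Functional weight w_s.** One annotation source feeds w_s (default CADD);
the choice is recorded in the configuration and echoed in every result.
The raw→[0, 1] maps are monotone in deleteriousness: SIFT and LRT are
inverted (w_s = 1 − raw), PolyPhen-2 is used as-is (already a probability),
CADD phred is min(raw/40, 1) so scores of 40+ saturate, and
MutationAssessor is clamped linearly over [0, 5]. Raw values outside each
source's documented range raise rather than being silently clamped.
Variants lacking the chosen source are excluded from the sum and counted in
`n_dropped` — damage is never imputed.

**Frequency weight w_f.** The default rule is w_f = 1 − mean(panel MAFs),
a monotone-decreasing-in-frequency weight that equals 1 for novel variants.
The rule is pluggable (a −log₁₀(MAF+ε) variant ships as an alternative)
because different burden-score traditions weight rarity differently; any
monotone-decreasing rule preserves the score's intent.

Consequences worth knowing: scores are non-negative, bounded by
2·n_variants_used, invariant to variant row order, and strictly increased
by any additional carried variant with positive weights. Multi-allelic VCF
records are split into bi-allelic rows on read; positions stay 1-based
end to end.

## Connectivity

**FC** is the Pearson correlation of regional BOLD series, computed on the
series as supplied — detrending, band-pass filtering and nuisance
regression are upstream concerns, not repeated here. Constant regions are
a hard error naming the region. Across-subject statistics use the Fisher
z transform (atanh), with |r| = 1 clipped to 1 − 10⁻⁶ under a warning.

**IDSCN.** The reference group (a separately supplied cohort; at least 30
subjects for the synthetic generator, at least 3 for the estimator) defines
PCC_n, the pairwise Pearson matrix of one morphometric scalar per region.
For an index subject the correlation is recomputed with the subject
appended, and the perturbation is Z-scored with denominator
(1 − PCC_n²)/(n − 1) — the first-order sampling variability of a
correlation under one added observation (the influence function of r has
variance (1 − ρ²)² for bivariate normal data, and the perturbation scale is
1/(n+1), giving a Z with approximately unit variance under the null). The
denominator rule is pluggable in the sense that the construction is a
small pure function; the null-calibration test (reference n = 200, 100 null
subjects) verifies mean Z within ±0.1 and sd within [0.8, 1.2].

The morphometric feature is deliberately a single scalar per region (a
gray-matter-volume equivalent); multi-feature structural covariance is out
of scope. Vectorized matrices always use the upper triangle, row-major,
pair (i, j) with i < j, on the canonical 90-region atlas ordering shipped
as a data file.

## SVR identification of predictive pairs

Features are connectivity pairs (FC Fisher-z transformed first),
standardized per column so weights are comparable across pairs. The model
is epsilon-insensitive linear-kernel SVR; hyperparameters default to C = 1,
ε = 0.1 (common connectome-regression practice — no values are dictated by
the analysis itself) and are echoed in every result. Quality is judged on
leave-one-out cross-validation: out-of-fold predictions are regressed
against the observed outcome (prediction line slope/intercept), and R²
(squared correlation of predicted vs observed) and MSE are reported, with a
label-permutation test for the model p-value,
p = (1 + #{permuted R² ≥ observed}) / (n_perm + 1).

Two numerical choices matter:

* the linear Gram matrix is precomputed on standardized features and reused
  across all LOOCV folds and permutations. Standardization therefore
  happens once per fit rather than per fold — a second-order leakage
  (column means/sds barely move when one subject is dropped) accepted for a
  large speedup in permutation testing;
* pair selection keeps pairs with |weight| strictly greater than
  mean(|w|) + 2·sd(|w|). The threshold is a package default, not an
  estimate: selection counts are emergent, and a flat weight profile
  selects nothing. The sign of a selected weight is reported as direction
  (positive = higher connectivity predicts a higher outcome value).

## Outcome statistics

* **Grouping**: follow-up ADOS total < 7 → optimal outcome (ASD−), ≥ 7 →
  poor outcome (ASD+); missing totals are flagged lost-to-follow-up and
  excluded from grouping.
* **OLS**: `simple_linear` is ordinary least squares with the two-sided
  slope t test; it matches the closed-form normal equations exactly.
* **Logistic**: maximum-likelihood fits (statsmodels) with per-term
  OR = exp(β), Wald 95% CI exp(β ± 1.96·SE), Bonferroni-adjusted
  p = min(1, m·p) across the m model terms, and risk/protective
  classification by OR ≷ 1. Perfect or quasi-perfect separation (detected
  by non-convergence or SE > 50) marks terms "unstable" instead of
  reporting meaningless ORs. The ordinal social-outcome grade is
  dichotomized (good vs average/poor) for logistic modelling; the cut is
  configurable.
* **Group comparisons**: pooled-variance t tests by default (matching the
  SPSS-style reporting convention for baseline tables), Welch by flag;
  Pearson chi-square without continuity correction for categoricals. Tests
  are two-sided at α = 0.05 throughout.
* **Mediation**: variables are standardized, so paths are on the
  correlation scale: a from OLS of M on X; b and c′ from OLS of Y on
  (M, X); total effect c from OLS of Y on X; indirect effect a·b. For
  linear models on complete data c = c′ + a·b holds exactly (verified to
  10⁻⁸). Inference is a seeded percentile bootstrap over complete triples
  (default 5000 resamples), re-standardizing within each resample;
  significance means the CI excludes 0. The paths are computed from the
  three pairwise correlations in closed form, which keeps dense coverage
  simulations (hundreds of simulations × hundreds of bootstraps) cheap.
  A full latent-variable SEM with fit indices is intentionally not
  implemented: the three-variable path model is the inferential core, and
  any particular indicator structure beyond it would be invented.

## Synthetic cohort

The generator's defaults are the study conditions: 90 followed subjects, a
104-subject reference cohort, 90 regions, 240 time points, an optimal-
outcome fraction of 1/3, the ADOS threshold 7, and a latent gene score
EFRS ~ Normal(150, 50) truncated at 0 — the scale chosen to be consistent
with gene-score regression functions whose slopes are per-EFRS-unit
effects of order 10⁻². 2000 candidate variants are generated by default
(a desk-scale stand-in for an exome's rare-variant count; the spectrum, not
the count, is what the filtering and scoring steps depend on).

* **Variants.** True frequencies follow a mixture: with probability 0.85 a
  rare Beta(0.5, 300) draw, else Uniform(0.01, 0.3) — so the MAF < 0.01
  filter removes a known expected fraction (`SimulationConfig.maf_mass_below`),
  and a minority of variants is deliberately common so the filter is
  exercised. Both panels observe the true frequency under multiplicative
  lognormal jitter (sd 0.05). The five damage scores share one latent
  deleteriousness per variant with independent Gaussian noise (sd 0.1) on
  each source's native scale, so sources correlate strongly but disagree.
  Allele counts are Binomial(2, mean panel MAF).
* **Time series.** Subject covariance is a single-factor background
  correlation (loadings U(−0.3, 0.3), positive definite by construction)
  with planted pairs overridden: the generating Fisher z at a planted pair
  is z₀ + β·s·e + √(1−β²)·s·η for standardized gene score e, subject noise
  η and across-subject scale s (default 0.3), then back-transformed — so
  correlations stay inside (−1, 1) by construction and the across-subject
  correlation between the gene score and the pair's measured Fisher-z FC
  targets β. Finite series (240 points) attenuate the measured coupling
  slightly (measurement sd ≈ 1/√237 against s = 0.3, plus tanh
  compression); the recovery test at n = 500 absorbs this within its ±0.08
  band. Modified matrices are repaired to the nearest correlation matrix
  by eigenvalue clipping at 10⁻⁸ followed by diagonal rescaling —
  deterministic, and a no-op on already-valid matrices.
* **Morphometry.** Volume-like regional means with a single-factor
  covariance; a configured fraction of subjects is drawn with the planted
  pairwise correlation shifts applied (default +0.4 at bilateral
  thalamus), which is the signal the IDSCN construction detects. Shifts
  leaving (−1, 1) are a parameter error.
* **Phenotypes.** S-M = 9.29 − 0.013·EFRS + N(0, 0.5), clipped to the
  instrument range [5, 13] (the clip binds for ≈0.2% of subjects at the
  default scale and does not measurably bias recovery). ADI-R
  communication follows the standardized mediation chain with paths
  a = −0.47, b = −0.36, c′ = −0.10 and residual scaled for unit variance,
  mapped onto the instrument scale. Follow-up ADOS totals are drawn as a
  mixture — optimal subjects on [0, 6], poor subjects on [7, 30], at
  cohort-typical means — so the expected optimal fraction equals the
  configured 1/3. The ordinal OSO is generated on a 0–8 scale monotone
  (decreasing) in S-M and trichotomized at configurable cut points
  (≤2 good, 3–5 average, ≥6 poor), supporting both the trichotomous grade
  and numeric group means.

**One deliberate decoupling.** The latent gene score that drives
connectivity and phenotypes is drawn directly at the configured scale; the
synthetic genotypes are generated from the same configuration but are not
constrained to reproduce that score, because allele counts are drawn
per-variant and no realistic spectrum yields a burden score with the
configured mean and spread from independent binomial draws at desk scale.
The genotype → VCF → filter → score path is therefore exercised and
verified against oracles in its own right, while parameter-recovery
experiments feed the latent score to the estimators. Passing tests show
the estimators recover what the generator planted — they do not show that
real exomes produce scores on this scale, nor that real FC carries
couplings this clean.

**Determinism.** Every generator draws from a stream derived as
(seed, stage-tag), so stages regenerate bit-identically under a fixed seed
regardless of call order; the pipeline writes a sha256 manifest and its
`results.json` is byte-identical across reruns.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to make their Monte-Carlo error
small relative to the asserted bands: parameter recovery at n = 5000;
FC-coupling recovery at n = 500 subjects × 240 time points; IDSCN null
calibration at reference n = 200 with 100 null subjects; SVR planted-pair
recovery over 50 seeds at n = 100; permutation-p uniformity over 200
simulations of 200 permutations at n = 12 subjects × 10 pairs; bootstrap
coverage over 200 simulations × 500 resamples at n = 50. The bootstrap
coverage check generates data with b = 0 and a ≠ 0, where the product
statistic a·b̂ is approximately normal and percentile coverage is close to
nominal; at the 2×2 multiplicative null (a = b = 0) the product's
distribution is non-normal and percentile CIs are known to be
conservative — that regime is not asserted.

## Known limitations

* The synthetic generator emulates distributional structure, not biology:
  no linkage disequilibrium, no gene structure, no hemodynamics or motion
  artifacts, no site effects, and no missing-data mechanisms beyond
  explicit lost-to-follow-up flags.
* IDSCN uses one morphometric scalar per region and a user-supplied
  reference cohort; which cohort should serve as reference for a given
  study is a scientific choice the package does not make.
* The SVR selection rule (mean + 2 sd of |weights|) is one defensible
  convention among several; selected-pair counts depend on it.
* FC is computed on the supplied series as-is; garbage in, garbage out.
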