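# efrsnet

Exome functional risk scores, brain connectivity and gene–brain–behavior
outcome models for longitudinal ASD cohorts.

Children diagnosed with autism spectrum disorder follow very different
trajectories: a minority lose the diagnosis at follow-up (ADOS total < 7,
the "optimal outcome" group) while the majority retain it. `efrsnet`
implements, as a tested and reusable pipeline, an analysis that links three
layers of data to that outcome:

1. **EFRS** — an exome functional risk score. Variants with minor allele
   frequency < 0.01 in *both* of two reference panels are retained, and each
   subject is scored additively:

   EFRS = Σᵢ v_all(i) · w_s(i) · w_f(i)

   where `v_all` is the alternative-allele count (0/1/2), `w_s` ∈ [0, 1] a
   functional-damage weight derived from one of five annotation sources
   (LRT, MutationAssessor, PolyPhen-2, SIFT, CADD), and `w_f` ∈ (0, 1] a
   frequency weight that up-weights rarer variants.

2. **Brain connectivity** in two modalities on a 90-region atlas:
   **FC**, the Pearson correlation matrix of regional BOLD time series, and
   **IDSCN**, the individual differential structural covariance network —
   for each subject, every reference-group inter-regional morphometric
   correlation `PCC_n` is recomputed with the subject appended
   (`PCC_{n+1}`) and Z-scored:
   `Z = (PCC_{n+1} − PCC_n) / ((1 − PCC_n²)/(n − 1))`.

3. **Outcome models** — linear-kernel SVR over vectorized connectivity
   pairs (LOOCV prediction line, R², MSE, permutation p, signed weights and
   outlier-pair selection), simple OLS of the S-M social-adaptability score
   on EFRS, multivariate logistic models with Bonferroni-corrected odds
   ratios, and a standardized three-variable mediation model
   EFRS → FC(MOG.L–PAL.L) → ADI-R communication with a bootstrap CI on the
   indirect effect a·b.

Because no raw cohort of this design is publicly deposited, the package
ships a first-class synthetic cohort generator (`efrsnet.synthetic`) with
recorded ground truth — rare-skewed MAF spectra, correlated damage
annotations, gene-score-coupled connectivity, planted covariance shifts and
phenotypes generated from stated linear/mediation models — so every stage
is exercised end to end with known answers. See `docs/methods.md` for the
models, defaults and limitations.

## Worked example

```python
import numpy as np
from efrsnet import synthetic as syn, connectivity as conn
from efrsnet.efrs import filter_rare_variants, compute_efrs, WeightConfig
from efrsnet.outcome_stats import simple_linear, mediate

cfg = syn.SimulationConfig(n_subjects=90, seed=1)   # 90 followed subjects
gt = syn.make_ground_truth(cfg)

variants = syn.generate_variants(cfg)
rare = filter_rare_variants(variants, threshold=0.01)
scores = compute_efrs(rare, WeightConfig(source="CADD"))
print(f"retained {rare.n_variants}/{variants.n_variants} rare variants; "
      f"genotype EFRS mean {scores.scores.mean():.2f}")

series = syn.generate_timeseries(cfg, gt)
labels = cfg.labels()
i, j = labels.index("MOG.L"), labels.index("PAL.L")
fc = np.array([conn.fisher_z(conn.compute_fc(t)).values[i, j] for t in series])
phen = syn.generate_phenotypes(cfg, gt, gt.efrs_true, fc)

fit = simple_linear(phen["efrs"], phen["sm"])
print(f"S-M ~ EFRS: slope {fit.slope:.4f}, intercept {fit.intercept:.2f}, "
      f"p = {fit.pvalues['x']:.2g}")
med = mediate(phen["efrs"], fc, phen["adir_comm"], n_boot=5000, seed=1)
print(f"mediation: a = {med.a:.2f}, b = {med.b:.2f}, "
      f"indirect = {med.indirect:.2f}, 95% CI [{med.ci_low:.2f}, {med.ci_high:.2f}]")
```

prints

```
retained 1661/2000 rare variants; genotype EFRS mean 2.59
S-M ~ EFRS: slope -0.0139, intercept 9.44, p = 1.5e-23
mediation: a = -0.57, b = -0.25, indirect = 0.14, 95% CI [-0.01, 0.31]
```

The cohort was generated with slope −0.013, intercept 9.29 and paths
a = −0.47, b = −0.36: at n = 90 the estimators recover them up to sampling
noise (the slope within one standard error; the mediation paths more
loosely, as expected for standardized correlations at this n), and the
bootstrap CI for the indirect effect correctly reflects that uncertainty.

## Command line

Every stage is also a subcommand of the `efrsnet` console script, driven by
one YAML config:

```sh
efrsnet run-all --seed 1 --out study_out        # simulate ... mediate
efrsnet simulate --config cfg.yaml --out study_out
efrsnet svr --out study_out                     # rerun one stage
```

Each stage writes its outputs plus a checksum manifest; rerunning with the
same config is byte-identical, and deleting an intermediate makes the
downstream stage fail with an error naming the missing file.

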