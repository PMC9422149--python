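# cortexscore

Cohort classification and continuous severity staging of Alzheimer's
disease from vertex-wise cortical thickness.

Structural MRI pipelines such as FreeSurfer measure cortical thickness
at hundreds of thousands of surface vertices per brain.  Clinically,
subjects are sorted into three coarse cohorts — cognitively normal
(CN), mild cognitive impairment (MCI) and Alzheimer's disease (AD) —
but the anatomical change behind those labels is continuous, and the
per-person variation in overall cortical thickness is larger than the
disease effect.  `cortexscore` implements an algebraic
classifier-plus-predictor for this setting, aimed at researchers who
have a vertex × image thickness matrix and per-image clinical labels:

1. **Thickness grouping.** Each image is summarised by its mean
   thickness ⟨t⟩ over all vertices and assigned to one of four
   contiguous windows A (thickest) … D (thinnest).  All further
   statistics are computed within a group, which controls the global
   thickness offset between people.
2. **ROI selection.** Per vertex *p* and cohort pair, a Welch-type
   separation statistic

   Z_p = (⟨t_p⟩₁ − ⟨t_p⟩₂) / √(σ₁²/n₁ + σ₂²/n₂)

   is computed; vertices with |Z| > 1.5 in any pair are ROI vertices,
   and a higher per-pair cutoff (default 3.5) picks the *essential* ROI
   vertices used downstream.
3. **Score-matrix classification.** Per group and cohort *k*, thickness
   values at essential vertices are histogrammed into m = 1…30 bins of
   Δ = 0.2 mm, each image depositing a discrete nine-point kernel
   (weights ∝ 56:43:21:7:1, σ_f ≈ 1.435 bin widths) instead of a point
   mass.  The score matrix is S⁽ᵏ⁾[p,m] = −ln(Q[p,m]/Q[p]) with Q the
   row- and matrix-normalised probabilities; a subject is assigned the
   cohort minimising S′ = Σ_p S[p, m′(p)] at its own bins.
4. **Severity degree.** Essential-ROI profiles are standardised per
   vertex, t′ = (t − ⟨t⟩)/σ_p, and the max-normalised Gram matrix
   C_ij = t″_ij / max{t″} between images yields
   C̄_i = ⟨C_ij⟩_{j∈AD} − ⟨C_ij⟩_{j∈CN} and the severity degree

   SD_i = (C̄_i − ⟨C̄⟩_CN) / (⟨C̄⟩_AD − ⟨C̄⟩_CN),

   a continuous scale that averages exactly 0 over CN and 1 over AD
   reference images, staging every subject (MCI included) along the
   CN→AD axis.

The package also provides SVD diagnostics of the combined score matrix,
self-recognition and stratified threefold cross-validation with
subject-level folds, a synthetic cohort generator with planted ground
truth, and a thin `cortexscore` command-line interface
(`simulate`, `group`, `roi`, `train`, `classify`, `severity`,
`crossval`, `svd`, `run`).

## Worked example

```python
import cortexscore as cs

matrix, metadata, truth = cs.simulate_cohort_study(cs.preset("separated", seed=1))
fitted = cs.fit_pipeline(matrix, metadata, cs.AnalysisConfig())
report = cs.self_recognition(fitted.model, matrix, metadata)
print(report.accuracy())
```

```
            n  correct  percent
clinical
CN        100      100    100.0
MCI       100       98     98.0
AD        100      100    100.0
```

Every cohort of the simulated study (300 vertices, 100 images per
cohort, planted effects of 0.2 mm) is recognised almost perfectly; the
two MCI misses land in CN, the clinically plausible direction.  Running
the severity predictor on a latent-severity cohort
(`examples/02_severity_staging.py`) prints

```
cohort  count  mean          min       max
AD      50.0   1.000000e+00  0.909846  1.161012
CN      50.0   1.026956e-17 -0.244485  0.392506
MCI     50.0   4.284257e-01 -0.475189  0.977593

Spearman(SD, latent severity) = 0.927
```

— the CN/AD means are exact anchors of the estimator, MCI spreads
across the whole scale, and the severity degree recovers the latent
severity ordering.  The `examples/` directory holds one short script
per capability (classification, severity, SVD diagnostics,
cross-validation, scoring new subjects).

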