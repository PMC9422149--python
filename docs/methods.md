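# Methods

This note documents the statistical model behind `cortexscore`, the
choices made where the procedure leaves room, what the synthetic data
do and do not emulate, and the known limitations.

## Data model

The unit of analysis is an *image*: one T1-weighted acquisition of one
subject, represented by a vector of cortical thickness values (mm) at a
fixed set of surface vertices.  Subjects typically contribute two twin
images (e.g. MPRAGE and MPRAGE_SENSE2) that share all biology and
differ only in measurement noise.  Thickness values must lie in
[0, 6) mm — the range the binning can represent; vertices missing a
value for any image are removed before analysis (`drop_incomplete_vertices`),
mirroring the usual reduction from a full surface to the common-vertex
subset.

## Thickness grouping

Mean thickness over all vertices varies between people by far more than
any disease effect, so all cohort comparisons are performed within
windows of mean thickness.  Default: quantile windows, four groups A
(thickest) … D (thinnest), trimming 0.4 % of images at the extremes
("out-of-bounds" images are EXCLUDED and reported, never silently
dropped).  Windows are lower-inclusive/upper-exclusive in mm; explicit
boundaries can be supplied instead for reproduction runs.  The window
count is a bias/variance trade-off: narrower windows control the global
offset better but leave fewer images per cohort for every within-group
estimate.

## ROI and essential-ROI selection

Per vertex and cohort pair, the separation statistic is a Welch-type Z
with unbiased (n−1) sample variances and image counts as n.  Sign
convention: positive when the first cohort of the pair is thicker.
Degenerate vertices (both variances zero) get a ±∞ sentinel, or 0 when
the means also agree, with a warning.

ROI vertices have |Z| > 1.5 in at least one pair.  Essential ROI
vertices use a higher per-pair cutoff, combined across the three pairs
by union (configurable to intersection).  The default essential cutoff
is **3.5**: the selection is a union of three two-sided tests per
vertex, and with twin images sharing a per-subject global offset the
null Z is mildly inflated, so 3.5 keeps the per-vertex null selection
rate near 10⁻³ where 3.0 would leave it near 1 %.  Planted effects at
the sample sizes this package targets reach Z ≈ 7–11 and are unaffected
by the difference.  Vertices are also categorised (CN/MCI/AD-thicker or
-thinner, monotone-descending CN > MCI > AD, or none) with a documented
precedence (monotone first) so every vertex gets exactly one category.

## Probability and score matrices

Binning: Δ = 0.2 mm, m = 1…30, lower-inclusive/upper-exclusive.  The
step-function definition of bin membership is ambiguous exactly on a
boundary (both bins would claim mΔ); the implementation assigns the
boundary to the upper bin and guards the floor computation with a 10⁻⁹
relative epsilon so values an ulp below a boundary are treated as on
it.

Kernel density smoothing replaces each image's point mass with a
nine-point discrete kernel.  Two constructions are provided:

* `integer-ratio` (default): weights ∝ 56:43:21:7:1 at offsets 0, ±1…±4
  bins, normalised to total mass exactly 1.  Its standard deviation is
  σ_f = 1.4353 bin widths, matching the printed value to three decimals.
* `erf-recursion`: a₀ = erf(0.25), a_l = 0.5·erf(0.25 + 0.5·l) + a₀/2 −
  Σ_{l′<l} a_{l′}.  Its coefficients come out in the ratio
  ≈ 55.3 : 43.5 : 21.2 : 6.4 : 1.2 (×200) with total mass ≈ 0.9985 and
  σ ≈ 1.431 — close to, but not exactly, the integer ratios.  The
  integer-ratio form is the default because its σ_f reproduces the
  published constant exactly; the recursion is kept for fidelity.
* `delta`: no smoothing (useful for exact-identity tests; in delta mode
  S = −ln P − ln N_p wherever P > 0).

Kernel mass falling outside bins 1–30 is truncated, not renormalised,
and recorded per vertex — the literal reading of the definition, and
the per-row probability deficit equals the recorded truncated mass.

Scores: S[p,m] = −ln(Q[p,m]/Q[p]); entries with Q[p,m] = 0 are set to a
cap (default 50 ≈ −ln e⁻⁵⁰, far below any attainable probability) so
totals stay finite.  Classification sums S at the subject's bins over
the essential vertices of its group and takes the argmin cohort; ties
break CN < MCI < AD (deterministic, documented).  Classification is
invariant under adding a constant to all three score matrices.

## Severity degree

Per group, essential-ROI profiles are standardised per vertex with the
*population* σ (⟨t²⟩ − ⟨t⟩², following the defining formula, unlike the
sample convention used in the Z statistic — each statistic follows its
own definition).  The Gram matrix of standardised profiles, divided by
its maximum element (diagonal included), is the covariance correlation
matrix C.  The severity degree rescales the AD-vs-CN contrast
C̄_i = ⟨C_ij⟩_{j∈AD} − ⟨C_ij⟩_{j∈CN} so that ⟨SD⟩_CN = 0 and
⟨SD⟩_AD = 1 exactly — an affine identity that holds on any data, any
seed (tested to 10⁻¹⁰).  Cohort averages include the j = i self term by
default (switchable; the anchors hold either way).  MCI images
participate in the profiles and in C but never in the reference
averages.  Normalisation is per group with all cohorts pooled.

New subjects are scored with frozen training state: the training
per-vertex mean/σ, the training Gram maximum and the training anchors.
A query identical to a training image reproduces that image's training
SD; an interpolated profile between the CN and AD centroids is monotone
in the interpolation weight (C̄ is linear in the query profile).

## SVD diagnostics

The combined score matrix S(All) concatenates the cohort score matrices
along the bin axis (vertices × 3·m_max, order CN | MCI | AD), so each
right singular vector carries one curve over m per cohort.  No
centering is applied before the decomposition.  Sign convention: each
right vector is flipped so its largest-magnitude component is positive
(the paired left vector flips with it), making results deterministic.
Cosine similarities between cohort segments are reported as numbers —
shared leading modes vs. discriminating later modes — not asserted.

## Validation

Self-recognition classifies the training images with their own model.
Cross-validation is stratified k-fold (default k = 3) over
(group × cohort) strata; the default unit is the *subject*, so twin
images never straddle a train/test split (image-level folds are
available to mimic per-image counts).  Group windows, ROI selection and
the score model are all re-fitted inside each fold from training images
only.  Held-out images outside the training windows, or in a group the
fold could not fit, are counted as excluded, never as correct.

## Synthetic cohorts

`simulate_cohort_study` generates thickness = baseline + subject offset
+ planted effect + noise:

* baseline per vertex ~ N(2.5, 0.2) mm, clipped to [1.8, 3.2];
* per-subject global offset ~ N(0, 0.12) mm — the across-subject spread
  of mean thickness the grouping controls, sized from the observed
  spread of group-mean windows (within-window SD 0.03–0.05 mm over a
  ≈ 0.3 mm range implies a population σ of roughly 0.12–0.15);
* i.i.d. Gaussian vertex noise, σ = 0.1 mm (per-image measurement
  error); offsets and noise are tail-truncated at 4σ/5σ so values stay
  in [0, 6) by construction;
* planted vertex sets: AD-thinner and AD-thicker (AD departs one effect
  step, default 0.2 mm, from both other cohorts) and
  monotone-descending (CN → MCI → AD in two equal steps).  The default
  "separated" layout (50/30/40 of 300 vertices) yields standardised
  within-group effects of d ≈ 1.9 per step and a net AD mean-thickness
  shift of ≈ 0.07 mm — enough to skew AD towards the thinner groups, as
  in real cohorts, without emptying the thickest group;
* severity mode: a latent s per subject (CN ~ U(0, 0.1),
  MCI ~ U(0, 1), AD ~ U(0.9, 1)) scales the planted effects linearly.
  The severity-gradient preset plants 120 thinning + 120 thickening
  vertices; the balanced directions reflect that thinner and thicker
  regions are jointly informative, and keep the severity axis
  orthogonal to the global offset;
* two twin images per subject share offset and effect and differ only
  by noise.

What the generator does **not** emulate: spatial correlation along the
cortical surface, anatomically structured effect regions, non-Gaussian
thickness distributions, scanner/site batch effects, or longitudinal
change.  Passing tests therefore demonstrate the estimators' behaviour
under the model's own assumptions — selection power, chance-level
behaviour under the null, the severity identities and ordering — not
performance on real MRI data.

## Problem sizes and measurement choices in the test suite

Desk-scale runs use 300 vertices and 100 images (50 subjects) per
cohort, with all analyses at the standard four thickness groups.
Selector operating characteristics (sensitivity/false-positive rate)
are measured on a variant with 100 *independent* images per cohort
(one image per subject): twin images inflate the pooled null Z by
≈ √(1+ρ) ≈ 1.26, so exchangeable images are the right null for the
selector itself; the twin effect is a property of the full pipeline and
is handled there by subject-level folds.  The chance-level check under
the label-shuffled null averages per-cohort accuracy over 16
subject-level permutations: a single shuffled refit carries a
correlated tilt across all its predictions (empirical per-cohort SD ≈ 8
percentage points, against 4.7 for an independent-image binomial), and
the permutation average estimates the expected chance accuracy that the
binomial band describes.  Null runs use essential cutoffs of 1.5,
since at the default 3.5 a null run selects almost nothing and
classification degenerates to the tie-break.

## Limitations

* The essential-cutoff default (3.5) and the union rule are package
  choices; the original per-group cutoffs they stand in for are not
  public, so absolute ROI counts are not comparable to published ones.
* The severity degree is a linear readout of the essential-ROI
  profiles; its resolution *within* the CN and AD reference cohorts is
  limited by profile noise and reference sampling (at 150 images the
  rank correlation with a latent severity plateaus around 0.9–0.97
  depending on the draw).
* MCI is intrinsically the hardest cohort: it has no private signature
  vertices in the generator (as in the motivating data), only its
  intermediate position on monotone vertices, and its accuracy is the
  first to degrade as effects shrink.
* Explicit group boundaries are honoured but never re-derived from real
  data; FreeSurfer ingestion is out of scope (delimited text is the
  interface).
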