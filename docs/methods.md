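# Methods

This note documents the models, conventions and defaults behind
`ihc_autoscore`, the reasoning behind the choices that were genuinely open,
and what the synthetic data can and cannot establish.

## Scoring pipeline

**Tiling.** Tiles are 800 × 800 px, axis-aligned, anchored at the image
origin, pairwise disjoint. Remainder strips at the right/bottom edges are
dropped, not padded: padding would create tiles whose statistics differ
systematically from interior tiles, and a partial tile cannot satisfy the
fixed-size contract of the detectors. The center of tile
`[x, x+800) × [y, y+800)` is `(x+400, y+400)`; containment of the center in
a tumor polygon is boundary-inclusive (shapely `covers`). Both conventions
are deterministic tie-breaks so tests can assert exact values.

**Tumor-tile classifier (reference backend).** Each tile is summarised by
stain statistics after Ruifrok–Johnston color deconvolution into
hematoxylin/eosin/DAB optical densities (per-channel mean, SD, 90th and
99th percentiles) plus nucleus-morphology summaries (stained-pixel
fraction, nucleus-core pixel fraction, object count, mean/median/max object
area). Two optical-density thresholds are fixed from the rendering palette:
a broad pair (H > 0.032, D > 0.030) that captures any stain including faint
DAB cytoplasm, and a core pair (H > 0.06, D > 0.08) that isolates
nucleus-dark signal so object sizes reflect nuclei rather than cytoplasmic
halos. Features are computed at three scales — the whole tile and central
400 × 400 and 200 × 200 windows — because the *label* is defined by the
tile center: the tight windows carry the label-defining signal, the full
tile adds context. A standardized logistic regression produces the tumor
probability; the decision threshold defaults to 0.5 and is exposed in
configuration. Training sets should include bare-glass background tiles
(real slides are mostly empty glass); without them a cell-free tile is out
of distribution and its prediction is unreliable.

**Cell detector (reference backend).** Foreground thresholds on the
hematoxylin and DAB channels are *calibrated during fit* as midpoints
between in-annotation-mask and background channel means of the training
tiles. Segmentation is: threshold → fill holes → remove objects below
`min_area` (25 px) → Euclidean distance transform → peak seeds
(`min_peak_distance` 6 px) → watershed. Each instance is classified on two
independent axes: PTEN-positive iff its mean DAB optical density clears a
cutoff learned as the midpoint between annotated positive and negative
cells; tumor vs non-tumor by a standardized logistic model on instance
morphology and context (area, eccentricity, equivalent diameter, mean
distance to the three nearest instances, count of instances within 40 px).
Confidence is the larger tumor/non-tumor posterior. Overlapping proposals
are resolved by confidence-ranked non-maximum suppression at IoU 0.5. The
background class used while training lives inside the backend and is never
emitted.

**Matching and mAP.** "Overlap" in annotation refinement and evaluation
means mask IoU ≥ 0.5, boundary-inclusive — the standard instance-
segmentation convention; the dialect is pinned explicitly because mAP
admits variants. AP is computed per class from the confidence-ranked
precision–recall curve with greedy highest-IoU matching and all-point
interpolation (area under the precision envelope); mAP is the unweighted
mean over classes present in the truth. An exhaustive pairwise
implementation in the test suite serves as the independent oracle on small
instances.

**Annotation refinement.** One round applies a trained model to annotated
tiles; detections whose IoU with every existing annotation is below 0.5 are
"unmatched" and must receive a reviewer-assigned four-class label (in
tests, supplied from ground truth). The merged set is a superset of the
original by construction; re-training on it is a second-round model. The
merged set never shrinks; the number of new unmatched detections per round
is tracked, not asserted to decrease.

**Scores.** Slide score = tumor-PTEN-positive / (tumor-positive +
tumor-negative); undefined when the denominator is zero. Patient score =
unweighted mean over defined slides — slides are weighted equally, not by
cell count, matching "average score of all slides"; slide-level dropout
(undefined scores) therefore does not lose the patient. PTEN-low is strict
`score < threshold` with threshold 0.5 (so exactly 50% is PTEN-high);
alternative thresholds are a parameter, not separate code paths.

## Endpoint and statistics

**BCR.** Event at the first post-surgery PSA ≥ 0.4 ng/mL, time in decimal
years from surgery (ISO-8601 dates accepted, 365.25-day years); censored at
the final registration. A patient with no post-surgery PSA is rejected —
such patients are excluded from cohorts upstream (missing follow-up).

**Delegated machinery.** Kaplan–Meier, log-rank and Cox fits are delegated
to lifelines. Cox uses Efron tie handling and Wald confidence intervals
(the tie method and CI flavour are conventions; profile likelihood was the
alternative). Categorical covariates are dummy-coded against an explicit
reference level, and a group Wald χ² (βᵀV⁻¹β, df = number of dummies) is
reported per categorical covariate.

**Concordance index.** A pair is comparable when the subject with the
shorter time had the event; equal times are comparable only when exactly
one subject had the event (who counts as earlier). Risk-score ties score
0.5. This matches the common Harrell convention and agrees exactly with
lifelines on tie-free data (asserted in tests, with an exhaustive
double-loop oracle as the independent check).

**BCa bootstrap.** Bias correction z₀ comes from the position of the point
estimate in the bootstrap distribution (ties counted half, clipped to
(1/2B, 1−1/2B)); acceleration from the jackknife skewness formula
a = Σd³ / (6 (Σd²)^{3/2}). Resampling is by patient: all of a patient's
values move together (paired columns are resampled with one index vector).
Default 10,000 resamples. Degenerate bootstrap distributions collapse to a
point interval and are flagged. Resamples where the statistic is undefined
(e.g. an AUC resample that lost a class) are dropped; if more than 90% drop
the interval is refused. The implementation agrees with
`scipy.stats.bootstrap(method="BCa")` to quantile resolution (asserted in
tests); a vectorized path (statistic reduces axis −1) exists for
calibration studies.

**c-index difference test.** Paired bootstrap of Δc on the same patients;
the two-sided p is 1 minus the largest confidence level whose BCa interval
excludes 0. The supremum is located by bisection on the level to 1e-4
(interval width is monotone in level), with the floor at p = 1e-4;
identical score vectors short-circuit to Δ = 0, p = 1. By construction
p < 0.05 iff the 95% interval excludes 0.

**Pearson r** uses the Fisher-z confidence interval (scipy); constant
inputs are rejected rather than returning NaN.

## Synthetic data

**Slides.** The generator emulates the *geometry and color logic* of
DAB/hematoxylin IHC at 0.227 µm/px, not its appearance: white-glass
background with Gaussian sensor noise; tumor regions as irregular
14-vertex blobs (radius 0.28–0.42 of the short image side); nuclei as
randomly-oriented perturbed ellipses. Tumor nuclei have semi-axes 6–10 px,
non-tumor 4–6 px (nucleus scale at this resolution; the size gap is what
makes the tumor/non-tumor axis learnable by the reference backend).
PTEN-positive cells get a dark DAB nucleus plus a 3-px light-brown
cytoplasmic halo; negative cells a hematoxylin-blue nucleus. Default
densities are 40 tumor and 25 non-tumor cells per tile area, with 85% of
non-tumor cells positive (stroma and benign glands retain PTEN). Tumor
cells are positive independently with the planted `positive_fraction`; the
ground truth records the exact planted classes, masks and centroids.
Failure modes: `low_antibody` renders DAB at 35% strength;
`no_antibody` renders no DAB at all, and the ground truth consequently
labels every cell negative and flags the slide. Failure slides are *not*
withheld from automatic scoring (no staining QC), mirroring the intended
workflow. Identical specs are bit-identical (`numpy` PCG64, one seed).

What this does **not** emulate: chromatin texture, stain variability,
scanner artifacts, overlapping/clumped nuclei beyond a minimum-distance
layout, tissue folds, out-of-focus regions, pyramidal multiresolution
files. Passing tests therefore demonstrate the correctness of the
pipeline's logic and the learnability contracts of the backends on
separable data — not clinical-grade segmentation performance. A residual,
irreducible error source remains even here: tiles whose center falls
within about one cell diameter of a region boundary are ambiguous under
the center-labeling rule, which caps held-out tile accuracy near 0.92 at
the synthetic geometry scale (real gigapixel slides have a far smaller
boundary-tile fraction).

**Cohorts.** Event times are exponential with proportional hazards on the
log scale: lp = β₁·[PTEN-low] + β₂·[non-diploid] + β₃·[both]. The
interaction term (default 0) exists so the three-level combined-marker
structure can be planted exactly — e.g. one-adverse HR 1.94 with
both-adverse HR 4.63 requires β₃ = log 4.63 − 2·log 1.94. The exponential
law is the simplest one satisfying the Cox model, enabling clean
parameter-recovery tests. Defaults mirror a validation-cohort-like regime:
n = 259, PTEN-low prevalence 0.17, non-diploid 0.27, PTEN-low HR 3.32,
non-diploid HR 1.98, baseline hazard 0.025/yr, 10-year administrative
censoring, quarterly PSA visits. Event detection is discretized to the
visit grid: visits before the latent event time record PSA < 0.4, the
first visit at or after it records PSA ≥ `psa_recurrence_level`
(default 0.6 ng/mL) — so deriving the endpoint from the PSA series returns
exactly the simulated outcome. Planted continuous PTEN scores are uniform
on (0.02, 0.45) for PTEN-low patients and (0.55, 0.98) otherwise (the
dichotomy is exact; scores near the 0.5 boundary are avoided so emulated
manual scores, true score + N(0, 0.04) noise, rarely flip status). CAPRA-S
base scores are Poisson(2) plus 2 per adverse marker, clipped to 0–12 —
correlated with the markers so integration is non-trivial, but not an
independent hazard driver.

## Numerical and design choices

- Problem sizes in the test and acceptance runs are chosen for a
  single-CPU workflow: training slides 2400², evaluation cohorts n = 500–
  2000, bootstrap sizes 300–2000 in tests (10,000 remains the analysis
  default).
- The empirical 95% BCa coverage for a mean at n = 50 sits near 0.94:
  BCa is second-order accurate and its small-sample coverage is known to
  fall slightly below nominal; scipy's implementation shows the same value
  under identical conditions.
- Cohort exclusion rules read boolean flag columns; a patient triggering
  several rules is excluded once and counted under each rule, so per-rule
  counts can exceed the number of excluded patients.
- The pipeline treats the per-patient slide count as data (any number of
  slides per patient); nothing is hard-coded to three blocks.
- CAPRA-S base scores are an input column; computing them from their
  clinicopathological components is out of scope.
- Serialization is text-only: TIFF rasters with JSON sidecars, GeoJSON
  polygons (pixel coordinates, x right / y down, 0-based), column-major
  RLE cell masks in JSON, CSV tables, JSON statistics.

## Known limitations

- The reference backends are contracts-first stand-ins exercised on
  synthetic data; no claim is made about their accuracy on real IHC.
- Harrell's c-index here uses the "event-first" comparability rule; other
  packages differ on tied event times.
- The BCa difference-test p-value is floored at 1e-4 by the bisection
  grid; smaller p-values are reported as 1e-4.
- Exponential event times cannot probe departures from proportional
  hazards; the Cox machinery is tested only under its own assumptions.
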