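# Methods

This note documents the models and procedures implemented in `wltb`, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions that affect results.

## Imaging biomarkers

All biomarkers are computed on the union of segmented liver metastases (the
whole liver tumor burden, WLTB) over a 3D grid with anisotropic voxel
spacing in mm; axis order is x = left–right, y = anterior–posterior,
z = cranio-caudal.  Units follow radiological convention: volumes in cm³,
distances in cm, attenuation in HU.

**Lesion inventory.** Lesions are the 26-connected components of the lesion
mask.  A lesion's diameter is the maximum pairwise Euclidean distance
between its voxel centers in physical mm, computed via the convex hull
(exact, since the diameter of a finite point set is attained on its hull)
with an exhaustive fallback for degenerate clouds.  By default the diameter
is fully 3D; an axial-only (in-plane, RECIST-style) option exists because
some tumor-burden literature measures on single slices.

**Tumor burden score.** TBS = √(N² + D²) with N the lesion count and D the
largest diameter in cm.  Undefined (NaN, with a warning) for subjects
without lesions — such subjects are expected to be excluded upstream, and
the package never fabricates zeros for them.

**Bilobar disease** is decided at voxel level: the subject is bilobar as
soon as lesion voxels lie in both lobe label regions, so a single lesion
straddling the lobe plane counts.  This follows the definition "presence of
metastases in both functional lobes" rather than any per-lesion assignment
rule.

**Geometric metastatic spread.** MSx/MSy/MSz are the per-axis extents
(max − min physical coordinate, cm) of the union of lesion voxel centers.
A centroid-based variant is available (`spread_mode="centroids"`), since
the originating literature does not state which convention it used; the
voxel-union extent is the default because it is segmentation-faithful.

**Surface area and derived features.** The lesion-union surface is
triangulated by marching cubes at the 0.5 iso-level in physical units.  The
binary mask is first anti-aliased with a Gaussian of 0.6 voxel: meshing a
raw binary volume inherits the voxel staircase and overestimates smooth
surfaces by ~8–9%, while the anti-aliased mesh is within a few percent of
the analytic area for digital spheres from ~3 voxel radius upward (masks so
small that the smoothed field never reaches the iso-level fall back to the
raw binary mesh).  A voxel-face surface counter is provided for comparison
but overestimates smooth surfaces by up to ~50% and is not the default.
SA/V is mesh area divided by voxel volume of the union (1/cm);
compactness is V/(√π·A^{3/2}) (dimensionless, maximal at 1/(6π) ≈ 0.0531
for a sphere), sharing the same mesh.

**Texture features.** Intensities inside the mask are discretized with a
fixed bin width anchored at the mask minimum; the default 25 HU follows
common CT radiomics practice (the bin width is configuration, not a
constant, because the originating pipelines do not state theirs).  The
gray-level run-length matrix accumulates maximal same-bin runs along the 13
unique 3D directions; run matrices are merged across directions before the
gray-level nonuniformity GLN = Σᵢ(ΣⱼR(i,j))²/ΣᵢⱼR(i,j) is taken
(per-direction averaging is the alternative aggregation, exposed in
config).  A region falling into a single bin degenerates to GLN = run
count; this is returned as a valid value.  First-order energy is the sum of
squared raw HU with no intensity shift — toolkits differ here and the
choice changes values by orders of magnitude, so it is documented rather
than configurable.  The wavelet feature applies a single-level undecimated
(stationary) 3D separable transform — undecimated so that sub-band voxels
stay aligned with the mask — takes the HLH sub-band of a coif1 wavelet by
default, and computes the same GLN on the filtered values.  For speed the
transform runs on the mask's bounding box padded by twice the filter
length; masked coefficients are unchanged by this crop whenever the mask
sits at least that margin from the volume boundary.  No grid resampling is
performed by default; the generator exposes spacing so both native and
resampled regimes can be studied.

## Survival modeling

Cox proportional-hazards fits use Efron tie handling via `lifelines`.  A
fit reports per-term coefficient, SE, hazard ratio with 95% CI and Wald p,
the log partial likelihood, AIC = 2k − 2ℓ, and Harrell's C-index.  Fits
refuse constant covariates and cohorts with fewer than 2 events;
non-convergence raises, and convergence warnings (hints of separation) are
attached to the result.

**Screening.** Each imaging feature is fit alone; features with Wald
p < 0.2 become candidates.  The liberal threshold deliberately admits weak
signals for the multivariable stage.  A feature whose fit fails is dropped
with a logged warning.

**Clinical baselines.** Model 1: ECOG dichotomized 0 vs ≥ 1, log CRP and
log bilirubin (mg/dl; nonpositive lab values are clipped to 0.01 and
logged).  Model 2: three indicators — ECOG ≥ 2, CA 19-9 ≥ 1000 U/ml
(inclusive threshold) and CRP at or above a threshold that defaults to
5 mg/dl; the threshold value and unit are configurable because published
sources disagree (mg/L vs mg/dl).

**Extension by backward elimination.** Starting from baseline + all
candidates, the candidate whose removal most decreases the AIC is removed,
until no removal decreases it.  Clinical terms are never removed, so the
final model is nested above its baseline by construction.  AIC ties are
broken by removing the term with the larger Wald p in the current model
(deterministic).  If the full starting model is unfittable (collinear or
separating candidates, common at small n with 10+ candidates), candidates
are shed by the same best-AIC-among-fittable rule until a model converges;
the elimination trace records every step.  Note the statistical character
of AIC elimination: a pure-noise candidate is retained exactly when its
1-d.f. likelihood-ratio gain exceeds 2, which under the null happens with
probability 1 − F(2; χ²₁) ≈ 0.157 regardless of sample size, so roughly one
in six null candidates survives elimination in the long run.

**Model comparison.** The likelihood-ratio statistic 2(ℓ_ext − ℓ_base) is
referred to χ² with d.f. equal to the term-count difference.  Non-nested
inputs or mismatched cohorts are a hard error.

**Risk stratification.** The linear predictor of the final model is split
at its median ("high" above, "low" at or below), giving equal-sized groups;
Kaplan–Meier curves, per-group median survival and the two-sided log-rank
test summarize the separation.  Because published phrasing of the split is
ambiguous, an alternative mode classifies subjects by whether their
predicted survival curve (cohort KM raised to exp of the centred linear
predictor) has fallen below 0.5 at the cohort's median survival time; this
variant yields data-driven group sizes and sits behind
`split="median_survival"`.

**Correlation report.** Pairwise Spearman correlations by default (Pearson
optional — figure captions and text of the originating literature disagree,
so both are offered); hierarchical clustering with average linkage on
1 − |ρ| orders the heatmap; constant columns are masked as undefined and
logged.

## Synthetic cohorts

The generator provides ground truth for every downstream test.  Per
subject it emulates:

* a liver as a single connected ellipsoid (default semi-axes 60×50×40 mm,
  jittered uniformly ±8% per axis per subject so liver volume varies
  between subjects as real anatomy does — without this, relative and
  absolute tumor volume are exactly collinear);
* a lobe split by an oblique plane through the liver centroid (default 20°
  in the axial plane).  Real functional-lobe anatomy (Cantlie's line) is
  out of scope: the analysis consumes lobe labels, it does not infer them;
* per-subject lobe involvement drawn as both/right-only/left-only with
  probabilities 0.71/0.18/0.11, matching published cohort frequencies of
  affected lobes;
* hypodense spherical lesions (portal-venous contrast: parenchyma
  105 ± 12 HU, lesions 65 ± 12 HU, air −1000 HU outside) with log-normal
  radii (median 5 mm) and a zero-truncated negative-binomial generative
  count (size 0.8, mean 13, capped at 113).  Overlapping spheres merge and
  are re-counted as 26-connected components, because a segmentation counts
  lesions, not generative events; the generative law is calibrated so the
  segmented count has median ≈ 7 per subject.  Lesions are wholly inside
  the liver, verified on the voxel grid (the inner parallel body of an
  ellipsoid is smaller than the naively shrunken ellipsoid, so analytic
  center sampling alone is insufficient);
* Gaussian HU noise, optionally low-pass filtered
  (`texture_smoothing_mm > 0`) to give the run-length features spatial
  structure;
* clinical covariates with marginals matched to a metastatic pancreatic
  cancer cohort: ECOG 0/1/2/3 at 44/51/4/1%, log-normal CRP (median
  1.0 mg/dl), bilirubin (median 0.6 mg/dl) and CA 19-9 (median ~460 U/ml,
  very heavy tail);
* survival from a Weibull/exponential proportional-hazards model.  The
  default rate 0.07/month makes the null median ln 2/0.07 ≈ 9.9 months,
  typical of the disease.  Covariates named in the ground-truth coefficient
  map are z-scored before the linear predictor is formed, so coefficients
  are per SD.  Censoring is administrative: one cutoff at the empirical
  (1 − censor rate) quantile of the drawn times (default 8%, ≈ 6 of 75
  subjects).

What the phantoms do **not** emulate: CT physics (beam hardening, dose
noise correlation), respiratory motion, contrast-phase dynamics, lesion
shape irregularity, intra-lesion texture beyond filtered Gaussian noise,
and anatomically correct lobar boundaries.  Passing tests therefore
demonstrate definitional and statistical correctness of the pipeline —
formulas, selection, inference, determinism — not that any particular
feature value matches what a scanner-specific pipeline would produce on
patients.  Absolute texture values in particular depend on unstated
preprocessing in the originating pipelines and are not reproducible;
only their definitions are testable.

## Determinism and orchestration

All randomness flows from one root seed through named child streams
(`phantom`, `clinical`, `survival`), so reconfiguring one stage cannot
perturb another; each phantom subject additionally derives its own stream
from (seed, subject index), making single subjects reproducible in
isolation.  CSV outputs use fixed column order and a fixed float format
(`%.10g`), so two runs with the same config and seed are byte-identical.
The run manifest records the config hash, per-stage wall time, warnings and
exclusion accounting (subjects in = analyzed + excluded-by-reason).

Problem sizes used by the shipped tests and the acceptance script — 75–200
phantom subjects on 48³-scale grids at 2–3 mm spacing, 20–60 survival seeds,
400–1000 calibration replicates — were chosen as the smallest sizes at which
the Monte-Carlo error of each check is comfortably below its assertion
margin.

## Known limitations

* Mesh-based surface area is unreliable for lesions of ~1 voxel radius
  (the anti-aliased iso-surface under-resolves them); SA/V and compactness
  on such lesions carry large voxelization error at coarse spacing.
* The Cox stage is complete-case per model and does not impute missing
  clinical values; per-model n is logged.
* Proportional-hazards diagnostics beyond convergence warnings (e.g.
  Schoenfeld residual tests) are not performed.
* The generator's lesions are spheres; shape-sensitive features
  (compactness, SA/V) consequently span a narrower range than in patients.
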