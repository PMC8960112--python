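# Methods

This note documents the models, numerical choices and limitations behind
`cardioloop`, in the order data flows through the pipeline.

## Data model and provenance

Cohorts follow the DICOM-like hierarchy patient → study → case; each case
holds one or more 3D(+t) image volumes and any number of segmentation
*sessions*.  A session is append-only: curation never mutates an existing
mask but adds a new session tagged `automatic`, `manual` or `corrected`,
with a per-contour `(phase, slice, structure)` correction flag map.
Session ids are content-addressed (SHA-1 of mask voxels + origin + a salt
from the case id and session position), so identical masks re-added as
no-op corrections still get distinct, deterministic ids, and every feature
row (`case::session`) resolves back to the exact mask that produced it.

Grids are indexed `(phase, slice, row, col)` with spacing
`(slice_mm, row_mm, col_mm)`; slice 0 is the most basal slice by file
order.  Labels use the ACDC convention (0 background, 1 RV blood pool, 2 LV
myocardium, 3 LV blood pool).  NIfTI is the interchange format (written
uncompressed so reruns are byte-identical); DICOM ingestion is out of
scope.

## Synthetic phantom

The phantom is a stacked-disc left ventricle: per slice, endocardial and
epicardial borders are concentric circles; the radius tapers linearly by
40% base→apex, which keeps per-slice analytic areas exact (π r²·thickness
sums to the programmed EDV, matching the voxel count within ~0.5% at the
default 128×128 / 1.5 mm grid).  The RV is a crescent: a disc displaced
along the −column axis minus the LV epicardial disc plus a one-pixel gap.
Contraction multiplies the endocardial radius by `1 − c·s(t)` where `s` is
a piecewise half-cosine peaking at end-systole (`round(0.4·phases)`, zero
slope at both extrema, so the volume curve is C¹ and cyclic); the
epicardial radius stays fixed, so the wall thickens at ES as real
myocardium does.  Because volume scales with radius squared at fixed slice
thickness, the programmed ejection fraction is exactly `1 − (1 − c)²`.

Class priors are (mean, sd) pairs sampled per case and clipped to ±2 sd.
They are *synthetic morphology defaults, not clinical claims*:

| class | LV endo radius (mm) | wall (mm) | RV scale | contraction c |
|-------|--------------------|-----------|----------|----------------|
| NOR   | 25 ± 1.5 | 8 ± 0.8  | 1.00 | 0.33 ± 0.03 |
| DCM   | 33 ± 1.5 | 6 ± 0.6  | 1.00 | 0.15 ± 0.03 |
| HCM   | 24 ± 1.5 | 14 ± 1.0 | 1.00 | 0.36 ± 0.03 |
| RVA   | 25 ± 1.5 | 8 ± 0.8  | 1.45 | 0.30 ± 0.03 |
| SCAR  | 25 ± 1.5 | 8.5 ± 0.8| 1.00 | 0.28 ± 0.03 |

HCM and NOR share the cavity prior deliberately: hypertrophic remodelling
preserves the cavity, so wall thickness (septum, myocardial volume) is the
*class-determining* feature, which the importance analyses rely on.  The
HCM/NOR wall priors and DCM/NOR radius priors do not overlap even at the
2-sd clip, so class separation holds for every sampled pair.  Each case
draws from its own RNG stream `default_rng([seed, case_index])`, making
cohorts stable under `n_cases` changes.

Intensities are Gaussian: blood pool 400 ± 30, myocardium 150 ± 30,
background 60, plus global noise (sd 10) — arbitrary but fixed defaults so
texture features are reproducible.  The SCAR class renders a transmural
60° wedge at the inferior wall at blood-pool intensity (pseudo-LGE) and
tags the image `lge`.

Corruptions emulate the failure modes a reviewer flags in real cohorts:
`slice_shift` translates one slice's mask by 8–14 px at *all* phases
(breathing misalignment), `mask_dilate` dilates one structure by 3 px at
*one* phase, `mask_dropout` erases one structure on one mid-ventricular
slice at one phase (single-frame segmentation failures).  Injected
corruptions are recorded in the truth table.

What the phantom does **not** emulate: papillary muscles, trabecular
texture, through-plane motion, coil bias or k-space artifacts, and any
realistic class overlap — phantom classes are separable by construction.
Passing tests therefore demonstrate that the pipeline recovers *programmed*
signal and detects *injected* corruption; they do not certify clinical
accuracy.

## Features

Definitions follow the IBSI formulations; the source names features the
IBSI way (`glcm_contrast`, `ngtdm_coarseness`, …).

* **Volume**: voxel count × voxel volume, reported in ml.  An empty
  structure has volume 0 but *missing* (not zero) surface area, texture and
  derived features; missing values stay `NaN` through the table (`NA` in
  CSV) and are imputed only inside classifier pipelines, fitted on
  training folds.
* **Surface area**: marching cubes at the 0.5 level of the zero-padded
  binary volume, physical spacing applied.  Meshing the raw binary
  overestimates smooth surfaces by ~9% (staircase), so the volume is
  pre-smoothed with a 0.6-voxel Gaussian: a digitized r = 10 mm ball then
  measures within ~1.2% of 4πr² while a 20-voxel cube stays within ~5% of
  its true area.  Degenerate structures too small to survive smoothing are
  meshed raw; an isolated voxel measures √3 mm² (the octahedron through its
  six face midpoints) — documented mesher behaviour.
* **Sphericity**: `(36π V²)^{1/3} / A` with the voxel-count volume.
* **Texture (GLCM/NGTDM)**: computed 2D per slice and pooled by merging raw
  counts over slices (and the four in-plane directions for the GLCM),
  which weights voxel pairs equally — chosen because short-axis slices are
  5–10 mm thick, making through-plane co-occurrence physically
  inhomogeneous.  Gray levels: fixed 32-bin min–max quantization within
  the structure at each phase.  A constant structure falls in a single
  bin: contrast, difference entropy and cluster tendency are 0, coarseness
  is capped at 10⁶, complexity is 0.  Implementation detail: the GLCM is
  accumulated with `skimage.feature.graycomatrix` using a sentinel gray
  level for out-of-structure pixels; the NGTDM is computed by
  convolution.  Both match independent brute-force enumerations to 1e-9
  on random toy images (test suite and acceptance script).
* **Septum thickness**: the septum axis runs from the LV blood-pool
  centroid toward the RV blood-pool centroid; rays every 2° within ±30° of
  the axis measure epicardial minus endocardial radius (0.25-voxel radial
  sampling); the sector mean is the thickness.  The relative value divides
  by the LV epicardial diameter along the axis.  The ±30° sector is a
  package definition; the measure is rotation-invariant by construction
  and recovers a 10 mm shell within 0.05 mm.
* **Tortuosity**: endocardial contour perimeter over convex-hull
  perimeter, ≥ 1.  Contours come from marching squares and are smoothed
  with a 5-point circular moving average to remove rasterization
  staircase (a digitized circle otherwise inflates ~5%).  A package
  definition, used as a contour-complexity proxy.
* **Fractal dimension**: least-squares slope of log N(ε) vs log (1/ε) for
  box sizes {1, 2, 4, 8, 16} over the structure's boundary pixels.  The
  estimator needs contours of roughly ≥ 100 px to be unbiased; on the
  phantom's small apical slices it is reported but noisy.
* **Function**: EDV/ESV are the LV-pool volume-curve extrema (first
  occurrence on ties), matching variable phase counts; EF recovers the
  programmed value within 0.002 on default phantoms.

Time-resolved features are aggregated with min/max/median/mean — all four
enter the feature table (the `fast` preset keeps volumes, intensity
statistics, septum and function features; `default` adds surface,
sphericity, tortuosity, fractal and texture features).

## Outlier triage

Thresholds below are package defaults validated on phantom cohorts.

* **Robust z brushing** (`feature_outliers`): `(x − median)/(1.4826·MAD)`
  per watched feature column, flag at |z| > 3.  MAD (not sd) keeps the
  detector stable in the presence of the very outliers sought; zero-MAD
  columns are skipped with a warning.  Flags are invariant to monotone
  affine feature transforms and monotone in the threshold.  On mixed-class
  cohorts the brushes also select genuine disease tails — by design; the
  correction step is a no-op for them.
* **Slice misalignment**: max over adjacent slice pairs of LV-pool
  centroid displacement divided by the pool's equivalent radius
  (`sqrt(area/π)`), at ED; flag at ≥ 0.5.  Normalizing by the equivalent
  radius makes the score resolution-independent.  Clean stacked-disc
  phantoms score ≈ 0 (concentric slices); a 10 px shift of a 20 px pool
  scores 0.5 by construction.
* **Curve discontinuity**: for each structure's volume curve, the relative
  residual against a circular 4-point cubic interpolation of its
  neighbours, `V̂_t = (−V_{t−2} + 4V_{t−1} + 4V_{t+1} − V_{t+2})/6`;
  flag when `max_t |V_t − V̂_t| / max(V̂_t, 0.05·V_max)` exceeds 0.08.
  The cardiac cycle is periodic, so circular indexing avoids edge effects;
  a C¹ contraction curve leaves residuals ≲ 0.03 at 14 phases while a
  single-phase dropout or dilation leaves an isolated spike of the dropped
  volume fraction (≥ 0.1).  Needs ≥ 5 phases — on shorter series a spike
  cannot be told from contraction.

The worklist merges all reports, ordered by severity (score over
threshold) descending with case-id tie-breaks, so identical inputs always
produce identical lists.

## Curation

* **Shape-based interpolation**: per structure, the signed distance
  transforms (positive inside) of the two bounding annotated slices are
  linearly interpolated; the zero super-level set is the interpolated
  region.  Symmetric in the bounding slices; concentric circles interpolate
  their radius linearly (r = 10 and 20 give r ≈ 15, Dice ≥ 0.99 against the
  analytic disc).
* **Deformable registration**: multi-resolution (3 levels, shrink 4/2/1)
  symmetric-forces demons with Gaussian displacement-field regularization
  (σ = 1.5 voxels, 40 iterations per level), run slice-wise in 2D —
  through-plane motion is negligible against 5–10 mm slice spacing.  The
  registration is a transport mechanism, so its *contract* is what is
  tested: exactly zero field on identical images, a 3 px translation
  recovered within 0.5 px, and ≤ 1.5 voxel mean endpoint error inside an
  annular band for smooth synthetic deformations of ≤ 5 voxels.
* **Contour propagation**: contour points are advected through composed
  fields (bilinear field sampling), then rasterized and re-extracted from
  the region's outer boundary, which restores the simple-polygon invariant
  if the advection self-intersects.  Propagated contours carry
  `source="propagated"`, `corrected=False`.
* **Consistency enforcement**: the epicardial region is reconstructed from
  the myocardium as a star-convex region around the LV centre — per 2°
  angular bin, the outermost myocardial radius, circularly interpolated
  across bins with no myocardium and closed with a 50° circular grey
  closing so that narrow dips (a contour locally drawn into the wall)
  are bridged while genuine wall thinning is preserved.  The region is
  intersected with the previously labelled set, so the total labelled
  volume never grows.  The LV pool is clipped to the region, RV pixels
  inside it become myocardium, and the myocardium is the remainder.  The
  repair runs to a fixed point (pool and RV shrink monotonically, so it
  converges, empirically in ≤ 3 passes), making the operator exactly
  idempotent; consistent masks pass through unchanged.  If the epicardium
  itself is wrong, the repair trusts it — reconstructing a wrong wall is
  out of scope and flagged here rather than guessed.
* **Corrections**: contour edits replace their structure's region on one
  (phase, slice); pixels an endocardial edit removes fall back to
  myocardium within the previous epicardial footprint.  Exactly the edited
  triples are flagged.  `correct_with_reference` swaps in a reference mask
  (the simulated expert) and flags every differing contour.

## Classification

Stratified outer folds (default 8; reduced with a warning when the
smallest class is smaller, rejected when any class has < 2 cases) around an
inner stratified search over classifier families × hyperparameters ×
feature-class subsets, selected by mean inner accuracy; ties keep the
earlier (simpler) candidate, with the default grid ordered logistic → SVM
→ forests → boosting.  The five families fix the model-selection space:
random forest, extra trees, gradient boosting, RBF-SVM, logistic
regression.  Feature-*class* subsets (shape, cardiac, texture, first-order,
clinical groups) rather than per-feature selection keep the search small
and interpretable.  Median imputation and standardization are fitted on
training folds only (leakage is tested by fingerprinting preprocessing
parameters).  AUC uses class probabilities where native and min–max
rescaled decision-function scores otherwise; macro AUC is the unweighted
one-vs-rest mean.

Permutation importance shuffles one feature column at a time, R = 10
repeats, importance = baseline − mean permuted score; deterministic given
the seed, exactly zero for constant columns, and split across perfectly
collinear duplicates (a documented caveat with its own test).  Scoring is
accuracy by default; for the highly redundant radiomics panels (four
aggregates per curve) accuracy barely moves when one of several collinear
columns is shuffled, so the ranking experiments use the
probability-sensitive `neg_log_loss`, which measures how much the fitted
model actually relies on each column.

The improvement loop composes the pipeline: extract → nested CV → worklist
(mask-based rules + brushing) → replace flagged sessions with reference
masks as `corrected` sessions → re-extract → re-score, with identical CV
seeds before and after so only the corrected rows change.  Corrected cases
are by construction a subset of flagged cases; false-positive flags are
no-ops (their reference equals the current mask).

## Experiment sizes

Large-scale checks run on reduced phantom settings chosen as the package's
own working sizes: 14 phases, 6 slices, 96×96 grid at 1.5 mm — enough
phases for the curve-spike detector (≥ 5) and enough resolution for ~1%
analytic-volume agreement.  The outlier experiment uses 100 cases with 5
injected corruptions; classification recovery uses a 200-case four-class
cohort with the `fast` preset; the improvement property is evaluated over
20 seeds of 32-case cohorts at 10% corruption with a single-forest CV
grid.  `PhantomConfig` defaults remain the full-size acquisition (25
phases, 10 slices, 128×128).

## Known limitations

* Phantom classes are separable by construction; observed CV accuracies of
  1.0 say nothing about overlapping clinical phenotypes.
* Texture features carry little signal in the phantom (homogeneous
  Gaussian textures); they are exercised for correctness (oracle
  equivalence, invariances), not for discriminative power.
* The box-counting dimension is biased low on contours ≲ 100 px.
* The consistency repair assumes a star-convex LV cross-section around the
  cavity centre — valid for short-axis anatomy, not for arbitrary shapes.
* Registration is 2D in-plane; genuine through-plane motion is invisible
  to it (and shows up instead in the misalignment detector).
* The robust-z brushes flag biological extremes on mixed cohorts; the
  worklist is a review queue, not a defect verdict.
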