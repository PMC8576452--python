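# Methods

`brainmorph` re-implements, as a tested pipeline, a structural-MRI
classification study design for type 2 diabetes mellitus (T2DM) and
cognitive impairment (CI): four volumetric feature representations of a
segmented, spatially normalized brain volume are compared under
leave-one-out cross-validated (LOOCV) linear-SVM classification.  Because
the clinical cohort behind such studies is not publicly available, the
package ships a fully synthetic cohort generator whose planted signal makes
every downstream stage testable end to end.  This note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Normalized space and preprocessing contract

All computation happens in an MNI-like normalized space: a 181 × 217 × 181
voxel grid at 1 mm isotropic resolution holding per-tissue probability maps
(gray matter GM, white matter WM, cerebrospinal fluid CSF).  Upstream
segmentation and spatial normalization of raw scans are outside the
package: the generator emits already-segmented, already-normalized tissue
maps, which is exactly the contract every feature extractor consumes.  The
brain mask is the conjunction GM+WM+CSF ≥ 0.5 (threshold configurable),
followed by binary closing and the filling of interior cavities, where a
"cavity" is a background component not 6-connected to the volume border.

## Synthetic cohort model

**Subject table.** Defaults reproduce the study composition: 58 T2DM and 65
NT (non-diabetic) subjects, of whom 25 and 15 respectively have CI.  CI is
defined purely by a Montreal Cognitive Assessment (MoCA) score < 26.  Age,
education and gender are drawn per diagnosis group from normal (truncated
at plausible bounds: age 18–90 y, education 0–22 y) and Bernoulli
distributions with the published group moments (age 51.17 ± 9.28 vs
48.34 ± 7.39 y; education 9.83 ± 4.32 vs 9.94 ± 3.90 y; male fraction 34/58
vs 31/65).  MoCA is drawn from a discretized normal per diagnosis group
(means 25.12 and 26.75; SDs 3.2 and 2.4, chosen as roughly a quarter of the
published min–max ranges since no SD is published for these cells), and the
exact CI/NC split is then enforced by assigning the lowest-scoring subjects
to CI and shifting any subject on the wrong side of the threshold minimally
(to 25 or 26).  Fasting plasma glucose respects the diagnostic criterion
(T2DM ≥ 7.0 mmol/L, drawn as 7.0 + |N(1.5, 1.5²)|; NT ~ N(5.3, 0.5²) capped
below 6.9); the 2-h OGTT field exists but is left unpopulated.

**Anatomy.** The template brain is a procedural phantom, not a real
template image: nested ellipsoidal shells (WM core at normalized
ellipsoidal radius ρ < 0.55, GM ribbon 0.55–0.85, CSF rind 0.85–0.95, with
logistic transitions of width 0.03) on the full grid, scaled slightly below
probability 1 so perturbations stay valid.  The 116-region atlas is by
default a seeded-Voronoi tessellation of the brain mask (uniformly drawn
seed voxels; each voxel labeled by its nearest seed, ties toward the lowest
label), preserving the dimensionality and geometry of an anatomical
parcellation without redistributing a licensed atlas.  A user-supplied
integer-label NIfTI atlas can be substituted.

**Subject variability.** Two multiplicative GM components:

* a global scale factor ~ N(1, `scale_sd`²), default `scale_sd` = 0.04,
  emulating inter-individual total-GM/brain-size variation (a few percent
  is typical of adult cohorts);
* a smooth local field: white noise smoothed with a Gaussian of FWHM
  `smooth_fwhm` = 4 mm and renormalized to field SD `noise_sd` = 0.05,
  emulating local morphometric variation.

WM and CSF stay at template values; GM is clipped to the headroom
1 − WM − CSF so the tissue-sum invariant holds voxelwise.

**Planted atrophy.** Disease signal is a multiplicative GM reduction inside
a configurable region set S (default: regions 1–10), applied to subjects of
the matching clinical class (default effects: Cohen's d 1.5 for CI, 0.75
for T2DM; a subject matching both contrasts receives both factors).  The
scale factor is calibrated analytically, not by Monte Carlo: the
across-subject SD of total GM volume over S is

    σ_S² = scale_sd² · V0_S²  +  α² · ‖G ∗ (t · 1_S)‖₂²

where t is the template GM map, V0_S its integral over S, G the smoothing
kernel and α the white-noise amplitude giving field SD `noise_sd` after
smoothing (the local term uses the adjoint identity
Σ_S t·(G∗ε) = Σ ε·(G∗(t·1_S)) for a symmetric kernel; ‖G‖₂ is measured by
smoothing a delta impulse).  Affected subjects' GM in S is scaled by
1 − d·σ_S/V0_S, so the planted standardized group difference of GM volume
over S equals d by construction.  With the defaults the global term
dominates (σ_S/V0_S ≈ 0.04), so d = 1.5 corresponds to a ≈ 6 % regional GM
reduction — a magnitude in line with reported regional atrophy in
neurodegeneration.

All randomness flows from one integer seed; each subject's stream is
derived from the cohort seed plus a stable SHA-256-based hash of the
subject id, so any subject can be regenerated independently and the whole
cohort is byte-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic MRI intensities, bias fields, motion or
scanner effects; anatomically shaped (non-Voronoi) regions; correlated
atrophy gradients across region boundaries; covariate-linked atrophy (age,
education); longitudinal change.  Tests against this generator validate the
*machinery* (feature definitions, leakage-free evaluation, statistics) and
the recoverability of a known planted effect, not clinical performance.

## Feature representations

All four extractors consume the GM probability map (the only channel with
disease signal under the segmentation-based contract) and are exposed as
scikit-learn transformers.

* **VOR** (volume of regions, 116 dims): summed GM probability per atlas
  region, divided by the subject's total GM.  Features are nonnegative, at
  most 1, and sum to the GM fraction covered by the parcellation.
* **PBM** (patch-based morphometry, 864 dims): the volume is center-cropped
  to 144 × 192 × 128 (offset ⌊(volume − crop)/2⌋ per axis, i.e. (18, 12, 26)
  on the default grid) and partitioned into 9 × 12 × 8 cubic 16³ patches;
  each feature is the patch's summed GM probability divided by the total GM
  of the full uncropped volume.  Patch enumeration is row-major over grid
  axes (axis 0 slowest, axis 2 fastest) so feature indices are stable across
  subjects.  All 864 patches are used; an optional patch mask exists at the
  classifier level but defaults to off.
* **LEP** (local energy pattern, 36 × 3 × 864 = 93,312 dims): per patch, a
  2-D histogram-of-oriented-gradients (HOG) descriptor is computed for each
  of the 16 slices along each orthogonal view, averaged per view, and the
  three views are concatenated.  HOG uses the unique standard configuration
  that yields 36 values on a 16 × 16 slice: 9 unsigned orientation bins,
  8 × 8-pixel cells, one 2 × 2-cell block with L2-Hys normalization.  View
  convention (fixed and documented): axial = slices along axis 2, coronal =
  axis 1, sagittal = axis 0; concatenation order axial, coronal, sagittal.
  All 16 slices are averaged whether or not they intersect the brain mask.
  z-score normalization is deliberately *not* part of extraction: it is
  fitted on the training fold inside the LOOCV loop (see below).
* **DTL** (deep transfer features, 5 × 6 × 4 × 64 = 7,680 dims): the GM map
  is center-cropped/padded to 160 × 192 × 128 — chosen because five
  halvings give exactly a 5 × 6 × 4 spatial grid — and passed through five
  stages of 2 × 2 × 2 stride-2 convolution + ReLU with channel widths
  (8, 16, 32, 64, 64).  The pre-trained weights of the original
  transfer-learning network are not published, so the default weight bank
  is seeded-random (He-scaled normals, zero biases), making the
  representation a deterministic random-projection feature bank with the
  exact architecture shape; a `.npz` loading hook accepts externally
  trained weights with shape validation.  Classification results obtained
  with random weights carry no transfer-learning claim.

## Evaluation harness

Leave-one-out cross-validation with a linear SVM at C = 1 (the libsvm
formulation via scikit-learn's `SVC`).  Per fold, the optional feature
normalizer is fitted on the training subjects only — z-score for LEP and
DTL, none for VOR and PBM (which are already normalized by total GM) — and
the held-out subject's signed decision value is recorded.  Fitting the
z-score inside the fold is the leakage-free reading of the design; the
alternative (fitting once on all subjects) is available by overriding
`SvmConfig.normalize` for sensitivity analysis.

The confusion matrix thresholds raw decision values at 0 (the SVM margin
sign, the default decision rule); the positive class is the clinical class
(CI or T2DM), fixing sensitivity/specificity directionality.  Calibration
is a strictly increasing (injective monotone) map of the raw scores onto
[0, 1] — affine min–max by default.  Any strictly monotone choice leaves
score ranks, hence ROC, AUC and the threshold-matched confusion matrix,
unchanged; this invariance is enforced by test rather than assumed.  The
ROC curve sweeps all distinct score thresholds; AUC is the trapezoidal
area, equal to the Mann–Whitney probability of correct pair ordering with
ties at half credit.  Degenerate cases raise informative errors: a
training fold with one class, fewer than 3 subjects, fewer than 2 subjects
per class after subgroup filtering, all-identical scores at calibration.

## Cohort statistics

Group comparisons use the pooled-variance two-sample Student's t
(df = n₁ + n₂ − 2), computable from raw columns or directly from printed
summary triples (n, mean, SD); the two forms agree to machine precision by
construction.  Pooled rather than Welch is the default because it
reproduces published two-decimal p-values computed from group moments
(e.g. 0.062 and 0.88 for the diabetes contrast, 0.23 for the cognition
contrast on age), which Welch does not (0.066 for the first).  Zero pooled
variance yields p = 1 for equal means and p = 0 with a warning for unequal
means (the limiting behavior).  Categorical 2 × 2 comparisons expose plain
chi-square, Yates-corrected chi-square and Fisher's exact test; published
categorical p-values are often not attributable to a single method, so
none is pinned.  The comparison-table builder formats mean ± SD (age,
education), M/F counts (gender) and mean (min, max) (MoCA), with a star at
p < 0.05 and raw p-values retained alongside.

## Numerical and reproducibility choices

* Exact determinism: one integer seed drives table, volumes, parcellation
  and weights; repeated runs are byte-identical (volumes in float32).
* Coordinate convention: 0-based voxel indices, half-open patch intervals;
  NIfTI output in RAS with the origin at the usual MNI anterior-commissure
  voxel.
* Nearest-seed parcellation ties break toward the lowest label (first
  argmin); distances are exact squared Euclidean computed in chunks.
* Mask monotonicity: raising the threshold never adds voxels before hole
  filling; closing is applied as dilation-erosion union-ed with the raw
  mask so it never removes thresholded voxels.
* Probability tolerance 1e-4 on the tissue-sum invariant (float32 I/O).
* Problem sizes in the test suite: full-scale checks (planted-effect
  recovery, permutation null) run once on the complete 123-subject cohort
  at the full 181 × 217 × 181 grid; distribution-level unit tests of the
  generator use a 91 × 109 × 91 grid with 40 subjects per group, and
  extractor oracles use 8³–32³ toys — sizes chosen so the default suite
  stays a few minutes on one CPU while the full-scale path is still
  exercised.

## Known limitations

* The synthetic phantom's Voronoi regions are convex and roughly
  equal-sized, unlike anatomical parcels; absolute region volumes are not
  comparable to real atlas statistics.
* With the default variability model the planted effect is recovered
  almost perfectly by VOR (LOOCV AUC near 1 at d = 1.5), because the
  generator's nuisance variation is far cleaner than real inter-subject
  anatomy; published real-data AUCs (≈ 0.58–0.64) are *not* reproducible
  targets since that cohort is private, and the package makes no attempt
  to match them.
* At very small n with unscaled VOR/PBM features, the C = 1 linear SVM can
  be dominated by the intercept under fold imbalance, producing
  chance-level or inverted LOOCV scores; this is faithful SVM behavior,
  not an artifact of the harness.
* The DTL path validates architecture and dimensionality only; without
  trained weights its features are a random projection.
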