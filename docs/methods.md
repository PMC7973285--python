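# Methods

## Problem and model

HDR cervical brachytherapy delivers dose through an applicator placed in
the vaginal cavity: a purely intracavitary (IC) tandem-and-ring or
tandem-and-ovoid device, or a hybrid interstitial (IS) device whose ring
guides needles into tissue. Which device yields the better dose
distribution depends mainly on the geometry of the high-risk clinical
target volume (HR-CTV) relative to the applicator: large, laterally
extended, or asymmetric targets are hard to cover from intracavitary
channels alone. The package casts applicator selection as binary
classification of a treatment fraction from interpretable geometric
features, with a soft-voting ensemble of tree classifiers as the model.

## Coordinate conventions and rasterization

Structures are stacks of closed planar polygons in the DICOM patient
coordinate system (LPS, mm), read either from a plain-JSON reference format
or from DICOM RT-STRUCT. The applicator frame is a tandem axis (point +
superior unit direction) and a ring/ovoid plane (point + unit normal
oriented along the tandem); when only RT-PLAN dwell positions are
available, the axis is a total-least-squares line through the tandem
dwells and the plane a least-squares fit through the ring dwells.

Contours are scan-converted to voxel masks: a voxel is occupied iff its
center is inside the polygon of the nearest contour plane (even-odd rule
across polygons sharing a plane) and within the half-open slab
[plane − g/2, plane + g/2), where g is the median inter-slice gap. The
half-open convention tiles abutting slabs without double-counting boundary
voxels. Default spacing is 1 mm isotropic — grid-convergence tests put the
induced volume error below 2 % at clinical structure sizes (and below 2 %
at 0.5 mm for 30 cm³ analytic ellipsoids) — and all masks of one fraction
share a spacing-aligned lattice so center-to-center distances are exact
where structures overlap. The voxel spacing that generated the original
clinical results is not documented anywhere we can consult, so the
convergence tests bound the uncertainty this choice introduces.

## Feature definitions

Twelve features per fraction; lengths mm, volumes cm³, all non-negative.

| feature | definition |
|---|---|
| axis offset | perpendicular distance of the occupied-voxel centroid from the tandem axis |
| lateral mean/max extent | voxels binned into axial slabs (width = spacing along the axis); each slab contributes its farthest perpendicular reach from the axis; max over slabs / mean over occupied slabs |
| vertical mean/max extent | signed height above the ring plane, clamped at 0; voxels binned into an in-plane 2-D grid; per-cell maxima, then max / mean over occupied cells |
| HR-CTV and OAR volumes | occupied-voxel count × voxel volume |
| OAR proximity | per OAR voxel, distance to the nearest HR-CTV voxel center; mean over the nearest 1.5 cm³ of OAR voxels |

Two definitional choices were genuinely open and are exposed as
configuration switches with the defaults below:

- **"Mean" extent** is the mean of per-slab (per-cell) boundary reach, not
  the mean voxel distance. This matches the picture of arrows from the
  tandem/ring to the target edge at multiple levels, and makes the lateral
  maximum agree with the clinical "> 25 mm lateral extent" rule of thumb
  (a one-sided reach from the tandem). `mean_mode="voxel"` selects the
  alternative reading.
- **Proximity direction**: the average runs over the nearest-1.5 cm³ OAR
  voxels' distances to the target (`direction="oar_side"`); the mirrored
  target-side average is available as `direction="hrctv_side"`.

Heights below the ring plane clamp to zero — extent is a non-negative
reach, and tissue inferior to the ring should not produce negative
"extent". Distances are voxel-center to voxel-center; the bias versus
surface distances is sub-voxel. Absent OARs yield explicitly flagged
missing values, never zeros.

## Plan-quality weighting

Each fraction carries eight dosimetric metrics (D90/D98 HR-CTV, D98 GTV,
D98 IR-CTV, Point A EQD2, and D2cc of bladder/rectum/sigmoid, all Gy EQD2).
Against a configurable table of planning aims and hard dose constraints,
the training weight is 0.25 if any hard constraint is violated, else 0.5 if
more than two planning aims are violated, else 1.0. Violations are counted
per metric; since any hard violation routes to 0.25 regardless of the aim
count, the double-counting question for nested bounds is immaterial. The
packaged default bounds are transcribed from the published EMBRACE II
protocol and are labelled external reference values — they must be replaced
by site-specific values for clinical use.

## Feature selection

One-way ANOVA F (between- over within-class mean square; 0/0 defined as 0)
and mutual information (k-nearest-neighbour estimator, k = 3, seeded
tie-breaking jitter, clamped at 0 — the estimator is a choice; only the
quantity is canonical) are computed per feature on the raw, un-oversampled
cohort: oversampling duplicates points and would bias the k-NN MI
estimate. The headline reduction keeps the six HR-CTV geometry metrics as
a group — on the synthetic cohort, as in clinical experience, this group
dominates both rankings — while a data-driven top-k-intersection rule
(features in the top k under *both* scores, ties broken by F-score then by
fixed feature order, short intersections topped up by F rank with a
warning) is provided as the generalization.

## Model pipeline

Twelve classifier families are registered (AdaBoost, Gaussian naive Bayes,
Gaussian process, gradient boosting, k-NN, LDA, logistic regression, MLP,
nearest centroid, Nu-SVC, QDA, random forest) with a per-family flag for
sample-weight support (ABC, GNB, GBC, LRC, NuSVC, RFC). Scale-sensitive
families are wrapped in a standardizing pipeline. Hyperparameter grids are
deliberately small (2–4 points per axis, e.g. ensemble size {50, 100},
depth {2, 3}) and overridable; they keep the inner search meaningful at
desk scale rather than exhaustive.

- **Oversampling**: the minority class is duplicated by seeded sampling
  with replacement to exact balance, *inside training splits only*; test
  sets contain only original samples. (Balancing before the split is
  reproducible via the estimator's `oversample` flag for comparison, but
  leaks duplicates across the split and is not the default.)
- **Nested CV**: outer 5-fold (shuffled, random_state = iteration number)
  for performance, inner 5-fold grid search maximizing unweighted accuracy
  for tuning; refit on the oversampled outer-train with weights iff the
  variant is weighted. Weights enter fitting only, not inner scoring.
- **Voting model**: equal-weight soft voting over the top three weighted
  variants (default ABC/GBC/RFC); predicted probability is the arithmetic
  member mean; a tie at 0.5 resolves to IS, because failing to flag a
  needle-requiring case risks target underdosage. IS is the positive class
  for precision/recall/F1/ROC-AUC; ROC-AUC of the ensemble uses the
  averaged probabilities (members without probabilities fall back to
  decision values, then to hard predictions).
- **Evaluation**: (i) repeated stratified 85/15 splits, random_state =
  iteration number, members tuned and fit per split; (ii) leave-one-out CV,
  where no split seed exists and member internals are fixed at seed 0. For
  LOOCV the members are fit at registry-default hyperparameters by default
  — n grid searches are prohibitive — with a builder hook to tune.
- **Importances**: impurity-based relative importances per tree-ensemble
  member, normalized to sum 1; non-tree members are omitted with a warning.

Everything is deterministic given the iteration seeds: reruns reproduce
fold assignments, chosen hyperparameters, and metrics bit-identically.

## Synthetic cohort

The generator emulates the statistical structure of an institutional
cohort of 233 fractions (147 IC / 86 IS): the HR-CTV is an ellipsoid with
lognormal semi-axes (medians 22 × 18 × 28 mm, σ_log 0.25), laterally
offset from the tandem axis by a half-normal magnitude (σ 6 mm), resting
on the ring plane and contoured at 2 mm slices (so 1 mm rasterization is
genuinely exercised); bladder, rectum and sigmoid are ellipsoids placed
anterior, posterior and supero-posterior with face gaps sampled from
3–15 mm. The label is Bernoulli with

    logit P(IS) = −0.5 + 0.25 (latmax − 25 mm) + 0.12 (V − 30 cm³),

rejection-sampled to the exact 147:86 class counts. Dosimetric records are
drawn so the three weight strata match 134:32:67 proportions, and
low-quality strata are preferentially swapped onto fractions whose label
disagrees with the deterministic geometry rule — emulating sub-optimal
applicator choices producing sub-optimal plans.

What the generator does **not** emulate: real contour irregularity and
inter-observer variability, needle arrangements, anatomy deformation by
the applicator, correlated OAR filling states, and any dose calculation
(records are sampled to hit violation strata, not computed from plans).
Passing tests therefore demonstrate internal correctness and recoverable
signal, not clinical performance.

### The attainable-accuracy ceiling

The label model is intentionally noisy, and this bounds every classifier.
`label_model_oracle_accuracy` computes two oracles on a generated cohort:
the Bayes rule of the class-rebalanced distribution (posterior adjusted by
Monte-Carlo integration of the sampling-marginal class probability), and
the balanced-threshold rule — thresholding the raw label probability at
0.5, which is what training on class-balanced (oversampled) data targets.
On the default configuration these evaluate to ≈ 0.86 and ≈ 0.77
respectively; the measured hold-out accuracy of the voting model lands
near the balanced-threshold oracle (≈ 0.77–0.80 depending on the seed),
i.e. the ensemble extracts essentially all the signal the protocol
admits. The gap between the two oracles is the
cost of the balanced decision threshold on an imbalanced test
distribution, not a deficiency of the members. Clinical cohorts, where the
applicator choice follows the geometry far more deterministically, support
much higher accuracies than this noise model does.

## Numerical choices and degenerate inputs

- Tandem-axis and ring-plane fits use SVD; collinear ring dwells raise a
  degenerate-plane error. Signs: the axis points from ring to tandem tip,
  the normal along the axis.
- Proximity uses a k-d tree with an exact bounding-box prefilter (a voxel
  whose lower-bound distance exceeds the m-th smallest upper bound cannot
  be among the m nearest); results equal the brute-force all-pairs
  computation to 1e-9.
- Constant features score F = 0 and MI = 0; single-class training sets,
  empty masks, absent structures, and infeasible rejection sampling raise
  typed errors rather than propagating silently.
- Problem sizes in the shipped tests and the acceptance script — 20
  hold-out iterations, 10-iteration nested-CV sweeps, brute-force oracles
  on ≤ 50³ masks — are the package's chosen desk-scale defaults; all
  protocol constants (5 outer/inner folds, 85/15 split, 1.5 cm³
  subvolume, weight strata) are independent of them.

## Known limitations

- DICOM support covers plain RT-STRUCT contour geometry; no registration,
  contour editing, dose-grid parsing, or DVH extraction.
- The EMBRACE-derived default bounds are reference values, not a clinical
  configuration.
- Feature extraction assumes axial planar contours; oblique contour planes
  are out of scope.
- The pipeline predicts the applicator class only — needle arrangements
  and pre-insertion (diagnostic-image) prediction are not modelled.
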