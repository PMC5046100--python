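# Methods

`nodulecad` implements a three-stage computer-aided detection (CAD) pipeline
for pulmonary-nodule candidates in chest CT: (1) extraction of a fixed
42-dimensional feature vector from each segmented candidate region of
interest (ROI), (2) feature-level fusion by rough-set attribute reduction,
and (3) classification with a grid-optimized RBF-kernel SVM.  Candidate
segmentation itself is out of scope: the toolkit starts from an intensity
volume plus a co-registered binary mask.

## ROI model and conventions

An ROI is a 3D gray-value array with an aligned binary mask and per-axis
voxel spacing, indexed `(z, y, x)` with any nonzero mask value counting as
foreground.  All feature formulas operate in voxel units (lattice
coordinates); spacing is carried for provenance.  The 2D descriptors need a
single slice per ROI; the package uses the axial slice with maximal
foreground area (ties to the lowest index) and records the choice in the
slice provenance, so alternative policies (e.g. per-slice averaging) can be
added without changing the schema.

## The 42-feature schema

* **Shape, fs1–fs18.** Perimeter (foreground pixels with a 4-connected
  background neighbor), area, 3D volume, circularity C²/(4πS),
  rectangularity S/(H·W), bounding-box elongation, Euler number
  (8-connected components minus 4-connected holes — the standard
  complementary-connectivity pairing), three 3D sphericity descriptors
  (below), the maximum 3D Feret diameter, and Hu's seven moment invariants
  computed from gray-weighted normalized central moments
  (γ = (p+q)/2 + 1) and compressed as log₁₀|C_k| with a machine-epsilon
  floor (a signed variant sign(C)·log₁₀(1+|C|) is available).  If the
  masked intensity sum is zero the binary mask is used as the density, so
  the moments never divide by zero.
* **3D sphericity descriptors.** ESV = V/V_sphere(dim), where dim is the
  maximum pairwise distance between surface-voxel centers (surface voxel =
  foreground voxel with a 6-connected background neighbor; the distance is
  computed over the convex hull for large surfaces).  SCDSTD = std/mean of
  surface-voxel distances to the ROI centroid (0 for a sphere).  ERCLD =
  mean distance from the ROI centroid to the 12 edge midpoints of the
  tight bounding box, normalized by the same mean taken from the box
  center; the normalization makes it dimensionless, scale-invariant, and
  exactly 1 for centrally symmetric ROIs.  Degenerate single-voxel ROIs
  return ESV = 1, SCDSTD = 0, ERCLD = 1.
* **Intensity, fi1–fi8.** Mean, population variance, max−min range,
  skewness, Pearson kurtosis (normal → 3; constant regions → 0 by
  convention); the erosion intensity-gradient score E4; and the mean (LDM)
  and range (LDD) of a 6-neighbor discrete-Laplacian response over
  foreground voxels (zero padding outside the array; the stencil is
  zero-sum, so constant fields give 0).
* **Erosion gradient.** The mask is eroded repeatedly with the 6-connected
  cross; each step's removed shell gets a mean intensity, and the ratio of
  each shell mean to the previous one (first ratio defined as 1) indicates
  whether the region brightens toward its core.  E4 = K/n, with n the
  number of steps until the mask empties and K the number of steps with
  ratio > 1.  Bright-core nodules approach (n−1)/n; radially constant
  regions give 0.  An alternative K (index of the last nonzero ratio) is
  available behind a flag.
* **Texture, ft1–ft16.** Tamura contrast (σ/α₄^¼), directionality
  (energy Σp² of the gradient-orientation histogram, 16 bins mod π,
  thresholded at 10% of the peak gradient magnitude), and coarseness (mean
  best window size 2^k per pixel, comparing adjacent 2^k-window averages at
  offset 2^k; the adjacent-window form responds correctly down to period-2
  textures, which the symmetric-difference form misses).  The remaining 13
  slots are Haralick statistics of a symmetric gray-level co-occurrence
  matrix: ASM, contrast, inverse difference moment, sum average, variance,
  sum variance, difference variance, entropy, sum entropy, difference
  entropy, information measure of correlation 1, correlation, and the
  maximal correlation coefficient (√ of the second eigenvalue of the
  chain matrix, 0 for degenerate single-level crops).  Defaults: 16 gray
  levels (min–max quantization, hence invariance to additive intensity
  shifts), distance 1, four directions averaged, log base 2.  Texture is
  computed on the ROI bounding-box crop with out-of-mask pixels replaced by
  the ROI mean so background never enters the co-occurrence counts.

All extracted values are finite by contract; degenerate inputs map to the
conventions above rather than NaN.

## Rough-set feature-level fusion

The labeled feature table is min–max normalized per column and discretized
into integer codes, giving a decision system (objects × condition
attributes, binary decision).  Indiscernibility blocks, lower/upper
approximations, the positive region POS_P(D) and the dependency degree
γ = |POS|/|U| follow the standard definitions; a *reduct* is a minimal
attribute subset preserving POS of the full set exactly, and the *core* is
the set of attributes whose individual removal shrinks POS.

Reducts are found by backward elimination: candidates are visited in order
of increasing single-attribute dependency (significance), with
equal-significance groups (two-decimal rounding) visited in a
seed-dependent random order; passes repeat until no attribute can be
dropped, so minimality holds by construction and is also re-checkable
exactly (`is_reduct`).  Significance-guided ordering matters: purely random
elimination order frequently drops strongly informative attributes whose
role a noise-driven attribute combination can imitate on the training
table, and the resulting reducts measurably degrade the downstream
classifier.  Because reducts are not unique, the fusion driver repeats the
search for five seeds (RS1–RS5) and returns, for each reduct, the
*continuous* normalized table projected onto its columns — discretization
only drives the search; the classifier never sees the codes.

Discretization default: equal-width, 2 bins per attribute (configurable;
equal-frequency and any bin count are supported).  The choice is
deliberate: quantile (equal-frequency) cuts act as near-optimal
per-attribute splits on class-separated features, which collapses reducts
to a handful of attributes and hurts the fused classifier, whereas coarse
equal-width codes keep individual attributes weak, producing richer
reducts (8–13 of 42 on the synthetic benchmark) whose projections track
full-table accuracy closely.

## Classifier and evaluation protocols

The detector is a soft-margin SVM with RBF kernel
K(x_i, x) = exp(−g‖x_i − x‖²).  C and g are selected by exhaustively
traversing a log₂ grid (defaults log₂C ∈ [−5, 15], log₂g ∈ [−15, 3],
step 2), scoring every node by stratified k-fold CV accuracy with ties
broken toward smaller C then smaller g; rows are put in a canonical sort
order first, so the selection is deterministic for a fixed seed and
invariant to row order.  Three protocols are provided:

* **cv10** — stratified 10-fold CV reporting per-fold and mean accuracy,
  sensitivity (TP rate on nodules) and specificity (TN rate on
  non-nodules), plus the pooled confusion matrix.  `nested=True` re-runs
  the grid inside each training fold (no selection leakage, 5-fold inner
  scoring); `nested=False` selects once on the full table, which is the
  cheaper select-then-validate variant used by the batch experiments.
* **stability** — repeated random stratified splits at train/test ratios
  50/20, 40/30, 35/35, 30/40, 20/50 (10 repeats each by default), with
  per-split grid selection.
* **pca_compare** — a 7-row side-by-side table: the full 42-feature table,
  the five reduct projections, and a PCA baseline keeping 95% explained
  variance.

Reported accuracy always satisfies the exact identity
acc = (sens·P + spec·N)/(P+N) on the pooled confusion matrix.
Wall-clock timings are logged but never asserted (hardware-dependent).

## Synthetic phantoms

The generator emulates the three nodule morphologies — solitary (ball),
vascular-adhesion (ball with an attached tube), pleural-adhesion (ball
clipped by a plane) — and the common false-positive structures: vessel-like
tubes, plate-like slabs, and irregular blobs (unions of 3–6 jittered balls
whose jitter spread controls how spherical they look).  Intensities are
constant, center-bright (linear radial decay to 40% contrast at the rim) or
ramped, over a darker background, with optional additive Gaussian noise.
Every phantom is a pure function of its spec and seed and carries analytic
ground truth (volume, diameter, centroid) for oracle tests.

The default benchmark mirrors a balanced 70-nodule / 70-distractor cohort
in two regimes.  *separable*: disjoint contrast ranges (nodules 70–100 vs
distractors 30–50 above background 30), low noise (σ=2), distinct
morphologies — CV accuracy saturates at 100%.  *noisy*: overlapping
contrast (40–70 vs 30–65), heavy noise (σ=15), 10% of ROIs with a flipped
intensity profile (flat nodules / bright-core vessels), and most
distractors as compact near-spherical blobs — accuracy drops below
saturation (~97–99%) while the class signal stays concentrated in a few
strong morphology/profile cues.  The preset is deliberately the strongest
ambiguity under which reduct-level fusion remains non-degrading: pushing
ambiguity further (to the ~90% accuracy regime) spreads the class signal
over many weak features, and a minimal positive-region reduct of a 140-row
table then necessarily sheds several accuracy points relative to the full
table — the non-degradation property, not a fixed accuracy figure, is what
the noisy regime is designed to probe.  Harder regimes remain reachable
through the generator parameters (contrast ranges, σ, blob spread, flip
rate).

What the phantoms do **not** model: CT physics (beam hardening, HU
calibration, reconstruction kernels), anatomical context, segmentation
error in the masks (masks are exact geometry), and inter-patient
variability.  Passing tests therefore demonstrate correctness of the
feature formulas, the reduction machinery and the evaluation protocols on
controlled geometry — not clinical detection performance.

## Numerical choices and edge cases

* Feret diameter via convex hull when the surface exceeds 500 voxels,
  brute-force pairwise distances otherwise (and as the fallback for
  degenerate hulls).
* Erosion/Laplacian neighborhoods are both the 6-connected cross, so the
  two intensity descriptors probe the same notion of adjacency.
* Shell-ratio guard: a zero previous shell mean gives ratio ∞ if the next
  shell mean is positive, 1 if both are zero.
* Grid-search tie-break (smaller C, then smaller g) plus canonical row
  ordering make every reported (C, g) reproducible bit-for-bit.
* Feature CSVs are written with 12 significant digits; write→read round
  trips are exact at that precision, and repeated pipeline runs from one
  seed are byte-identical.

## Problem sizes

Default study sizes, chosen to keep the full synthetic study at desk
scale: 70+70 ROIs on 40³ voxel grids, 42 features, 5 (or 10 where a
repetition experiment calls for it) reduction seeds, a 110-node (C, g)
grid, 10-fold outer CV with 5-fold inner scoring where nesting is enabled.

## Known limitations

* The rough-set reduction is the positive-region variant only;
  discernibility-matrix, entropy and swarm-based reductions are out of
  scope, as are rough-set rule classifiers.
* 2D features come from a single representative slice; whether averaging
  across slices is preferable is untested.
* Anisotropic spacing is carried but not applied to the feature formulas
  by default (voxel-unit convention).
* The exact reducts of any particular clinical dataset depend on the
  discretization scheme; with the scheme unreported for the original
  cohort (and the cohort private), reduct identities are not comparable
  across implementations — only their behavior is.
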