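# Methods

This note documents the models, conventions and design choices behind
shapefeat: what is computed, under which assumptions, and where the
implementation had to make a call that the underlying method leaves open.

## Distance-distribution descriptors

The object descriptor is the multiset of Euclidean distances from each
object pixel to the nearest background pixel.  Conventions:

* **Distance convention.** Distances run from object-pixel *center* to
  the nearest background-pixel *center*, so a boundary object pixel has
  distance exactly 1.0 and every stored distance is strictly positive;
  `-1` is the only non-positive value in a distance map and marks
  off-object cells.
* **Border padding.** The mask is padded with one background pixel
  before the transform, so objects touching the image border still have
  finite distances.
* **Sorting** is ascending and stable; sorting discards pixel order,
  which makes the series exactly invariant under translation, the three
  lattice rotations and axis flips (those permute pixels but preserve
  the distance multiset).
* **Scale behaviour.** The `scaled` and `accuScaled` mappings are
  approximately scale invariant (both end at exactly 1); `sort` and
  `accu` are deliberately not, since absolute size is itself a usable
  cue when acquisition geometry is fixed.

### RSFS

The resampling indices are idx_j = round(j·(N−1)/10) for j = 0…10 with
half-up rounding (fixed for determinism), the j = 0 value is discarded.
It needs N ≥ 11 object pixels.

### LPFS

The basis p_1 = 1, p_2 = x, p_{n+2} = [(2n+1)·x·p_{n+1} − n·p_n]/(n+1)
is evaluated by the recursion on equidistant abscissae
x_i = 2(i−1)/(N−1) − 1.  Ten basis functions (degree 9) are the default;
the order is a parameter.

**Estimator.** The textbook projection a_n = ⟨p_n, y⟩/⟨p_n, p_n⟩ is
exact only if the basis is orthogonal under the discrete inner product.
On a finite equidistant grid it is not: ⟨p_n, p_m⟩/N is O(1/N) for
n ≠ m with n + m even, so the projection leaks ≈ (2n−1)/N of each
coefficient into the others (about 1e−2 at N = 1000).  The default
estimator (`method="lstsq"`) therefore solves the full discrete
least-squares problem, which recovers exactly representable series to
machine precision; `method="projection"` keeps the literal ratio for
comparison.  Note the continuous normalizer is 2/(2n−1) and the N-point
discrete sum converges to N/(2n−1); the implementation always computes
the discrete sums exactly rather than substituting a closed form.

### Resolution limits

All descriptors quantize at the pixel scale.  The value of a low-rank
component of a mapped series is a small multiple of 1 px, and
re-rasterization (rotation by a non-lattice angle, rescaling) perturbs
each distance by up to ~0.5 px.  The relative error of the 10%-rank
feature is therefore ≈ 0.5·P/(0.1·A) for an object with area A and
perimeter P and only falls below a few percent for objects tens of
pixels wide.  Structures a few pixels wide (thin stems) are below the
descriptor's resolution: their features are exactly reproducible (the
pipeline is deterministic) but not stable under re-rasterization.
Consequently the invariance test suite measures componentwise
differences *relative to the feature vector's sup norm* — the components
of one descriptor share a common scale, and near-zero components carry
rasterization noise whose relative error is unbounded at any finite
resolution — and uses single-leaflet fixtures (semi-axes 100×20 and
90×55 px) wide enough that quantization sits well below the tolerance.

## Preprocessing

* Smoothing: the normalized 3×3 binomial kernel (the standard discrete
  3×3 Gaussian) per channel with reflective borders (avoids darkening
  edges, which would bias ExG near borders).
* ExG = 2g − r − b on chromatic coordinates r, g, b = R, G, B/(R+G+B);
  pixels with zero intensity map to 0.  Chromatic normalization cancels
  uniform gain.
* Underexposed pixels (R+G+B below `intensity_floor`, default 45) are
  colour-unreliable and excluded from the foreground.  The default
  excludes near-black background while keeping dim leaves; it is
  configurable.
* Segmentation is a documented threshold segmenter: Otsu's threshold on
  the ExG values of reliable pixels (default), or a fixed threshold.
  This replaces region growing used in earlier silhouette pipelines,
  which is not reproducible from its description; users who need it can
  substitute their own mask input.
* Rejoining: while more than one 8-connected component remains, the pair
  with the smallest contour-to-contour Euclidean distance is bridged by
  a Bresenham line between the closest contour points, dilated to
  `strip_width_px` (default 2 — keeps the bridge negligible in area
  while guaranteeing 8-connectivity).  Ties are broken by the
  lexicographically smallest (row, col) pair, making the procedure
  deterministic.  Object pixels are never removed.

## Common feature set (CFS)

* The contour is the 0.5-level marching-squares isoline with collinear
  vertices pruned, oriented counter-clockwise.  Raw isolines staircase
  along the lattice and overestimate arc length by ≈ 5%, so arc length
  is measured after one 3-point moving-average pass on the closed
  polyline (a disk's perimeter is then within 0.3% of 2πR).
* area = object pixel count; convex_area = pixel count of the filled
  convex hull (guarantees solidity ≤ 1); convex_perimeter = hull polygon
  perimeter; compactness = 4πA/P², clamped to (0, 1] (sub-pixel shapes
  can exceed 1 on the lattice).
* Eccentricity comes from the second-moment equivalent ellipse.
* Circular/elliptic variance are the Peura–Iivarinen definitions on
  contour vertices (radial spread about the centroid; Mahalanobis-radius
  spread under the contour covariance).  Both are similarity invariant.
* Skeleton features: length(skeleton)/perimeter, endpoint count,
  branch-point count, mean medial distance / max distance.  Lattice
  thinning is anisotropic (the skeleton of a rotated mask is not the
  rotated skeleton), so the skeleton is computed on a canonical dihedral
  orientation of the mask — the lexicographically smallest of its eight
  rotations/flips — which makes all four statistics exactly invariant
  under lattice transforms.  Which four skeleton statistics the
  comparison literature used is not recoverable; these four are standard
  and testable, and the substitution is documented, not asserted as
  faithful.
* hu_7 changes sign under mirror reflection by construction; invariance
  claims for it cover translations and rotations only.

## Evaluation protocol

* Scaling: per-feature affine map of the *training fold* to [−1, 1]
  (min → −1, max → 1, constant features → 0), applied unchanged to the
  test fold.  Fitting the scaler inside the fold avoids information
  leakage; protocols that scale globally before splitting will differ
  slightly.
* Folds: stratified, per-class shuffled round-robin assignment, so
  per-class fold counts differ by at most one; deterministic in the
  seed.
* Classifiers: k-NN (k = 3), Gaussian naive Bayes (per-class empirical
  priors, variance floor 1e−9), linear SVM and RBF SVM (kernel
  exp(−‖u−v‖²/2σ²)) with C = 0.279 — the defaults carry the reference
  protocol's published parameter values.  A fixed kernel width is only
  meaningful for the dataset it was tuned on (σ = 706.87 on unit-scaled
  features of a different dataset makes the kernel numerically constant
  and the SVM underfit), so the pipeline's RBF configuration defaults to
  the median pairwise training distance per fold, the standard
  heuristic; both the width and the convention are configurable.
* Accuracy is pooled over folds: (TP + TN)/N with N the total sample
  count (micro-average), not the mean of fold accuracies.
* Overlap coefficient: per-class histograms on 64 shared bins spanning
  the pooled min–max, each normalized to unit mass; overlap =
  Σ min(h_A, h_B).
* Forward selection: greedy wrapper maximizing CV accuracy; ties go to
  the earlier feature in table order; rounds continue until all features
  are included, so the trace is complete and deterministic.  Greedy CV
  accuracy need not be monotone in subset size.

## Synthetic data

The generator emulates two-class cotyledon-stage silhouettes on a dark
background (masks only — no texture, lighting or soil synthesis).  Each
plant is a union of filled ellipses joined to a common center by ~3 px
stems: two opposite cotyledons plus, with probability ½, a smaller
(0.45×) true leaf perpendicular to the cotyledon axis — the arrangement
at growth stage BBCH 12, where whole-plant elongation is governed by
cotyledon shape.  The two classes differ in leaflet aspect ratio
(elongated 5.0 ± 0.3 vs rounded 1.6 ± 0.3, clipped at 1.05 so leaflets
never invert); leaflet length 40–80 px and petiole 2–8 px at the default
256×256 canvas, roughly matching seedlings a few cm across imaged at
~3 px/mm.  Pose, sizes and aspect are random per sample; each sample
draws from its own stream derived from (seed, class, index), so
generation is bit-reproducible and order-independent.

With `fragment_prob > 0` a leaflet tip is disconnected by erasing a
narrow band across the leaflet (perpendicular to its axis, ~35% along
its length, widening until the mask splits), to exercise rejoining.

What the generator does *not* emulate — occlusion, leaf texture,
serrated margins, shadows, segmentation noise, within-class growth-stage
variation — bounds what passing tests show: they validate the machinery
and its invariances, not field-condition recognition accuracy.  The two
synthetic classes are deliberately well separated, so near-perfect grid
accuracies are expected and published accuracies on real imagery are
not reproduced here.

## Problem sizes

Tests and the acceptance script use 100 + 100 default samples (seed 7)
for the evaluation grid and forward selection, 100 fragmented samples
(seed 11) for the rejoining contract, N = 1000 with 100 trials for
coefficient recovery, N = 10,000 for discrete orthogonality, an R = 80
disk for the closed-form oracle and 5000 draws per class for the overlap
statistic — sizes at which every stochastic check is comfortably inside
its tolerance while the whole suite runs in well under a minute of
compute for these stages.
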