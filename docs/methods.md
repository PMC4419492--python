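# Methods

## Problem setting

Candidate lung-nodule ROIs are classified as nodule (+1, minority) or
non-nodule (−1, majority) from eight shape features. Training sets are
heavily imbalanced (ratios of 2–20 majority per minority sample are
typical), which biases a soft-margin SVM toward the majority class. The
package balances the training data with a combined
undersampling/oversampling procedure and compares the result against plain,
biased-penalty and SMOTE-only SVM baselines under repeated stratified
half/half cross-validation.

## The combined balancer

Given a labelled training set, `balance()` applies, in order:

1. **Class geometry.** Centers are arithmetic means of each class's feature
   rows; average radii are mean Euclidean distances of class members to
   their own center.
2. **Boundary-noise removal.** The boundary set is the top
   `ceil(0.05·n_maj)` majority samples by distance from the majority center
   (descending, ties broken by original index). A boundary sample closer to
   the minority center than the minority average radius is deleted. Only
   majority samples are ever removed: the asymmetry is deliberate — the
   harm modelled is majority points dragging the hyperplane into the
   minority cloud, and the minority class is too small to sacrifice.
3. **Random undersampling.** `ru_rounds` halving passes at overall rate
   `RU = 2^ru_rounds`. "Adjacent pair" is made concrete by sorting the
   current majority set by distance to its center (ties by index) and
   keeping every second element starting with the first, so each pass maps
   `m → ceil(m/2)` and preserves the radial distribution; the procedure is
   deterministic. A two-sample KS check on 10⁴-sample mixtures confirms the
   retained set is distributionally indistinguishable from the original.
4. **SMOTE.** Every minority sample contributes `N − 1` synthetic points,
   each interpolated toward a neighbour drawn uniformly (with replacement)
   from its `K` nearest minority neighbours, `δ ~ U[0,1]`; total minority
   count becomes `N·n_min`. `K` is clamped to `n_min − 1` with a warning
   when necessary. Provenance (base, neighbour, δ) is recorded for every
   synthetic point so each one can be replayed exactly.

**Standardization.** The eight features span orders of magnitude (volumes
in the hundreds of mm³ next to ratios in (0,1]), and every distance above is
scale-sensitive. All distances are therefore computed on z-scored features
(fit on the data being balanced, i.e. the training fold); interpolation is
replayed on the original scale, which is exact because the segment map is
affine-equivariant. Sample counts — the quantities the balancer is
specified by — are scale-invariant. Standardization can be disabled.

**Parameter selection.** From `N_ratio = n_maj/n_min`, under the
constraints `RU ≥ 2` and `K ∈ [3,6]`:

    ru_rounds = max(1, floor(log2(sqrt(N_ratio))))
    N  = clamp(round(N_ratio / 2^ru_rounds), 1, 6)
    K  = clamp(N, 3, 6)

This reproduces the reference worked settings (ratio 6 → RU 2, K 3;
10 → RU 2, K 5; 20 → RU 4, K 5) and keeps the post-balance class ratio
within [1/2, 2] for any input ratio up to 20: at mildly imbalanced inputs
the amplification drops below the `K` range (down to `N = 1`, i.e. no
synthetics) instead of overshooting the minority. `round` is half away
from zero.

**Randomness.** One seed is expanded through `SeedSequence` into
independent sub-streams per stage, so changing the SMOTE amplification
cannot perturb the undersampling draw. `balance` is bit-for-bit
deterministic given (data, parameters, seed).

## Classifiers

The C-SVM dual is solved by libsvm's SMO (scikit-learn `SVC`), tolerance
1e-4, iteration cap 10⁶ with an explicit non-convergence warning. Per-class
penalties for the biased SVM enter as class weights on a unit base penalty,
which scales the dual box constraints to exactly `C+`/`C−`; with equal
penalties the model reduces to the C-SVM (asserted to 1e-6 on the dual
coefficients). The trained model is extracted into a self-contained object
(support vectors, `α_i y_i`, offset, kernel, standardization constants) and
prediction is an explicit kernel expansion, independent of the solver — a
decision value of exactly 0 maps to +1.

Defaults: RBF kernel with `γ = 1/(d·var(X))` on the (standardized) training
features — a scale-free choice; `C = 10`; biased penalty
`C− = max(1, round(C+/round(N_ratio)))`. Standardization is fit on the
training fold only and applied inside `predict`.

## Shape features

2D features are computed on the axial slice of largest foreground area
(ties → lowest slice index), in mm via the voxel spacing:

* circularity = largest-inscribed-circle radius (Euclidean distance
  transform maximum) / circumscribed radius (farthest foreground pixel from
  the centroid), clipped to 1;
* elongation = `r_min/r_max`: `r_max` as above; `r_min` is the distance
  from the centroid to the nearest background pixel minus half a pixel,
  which tracks the smooth boundary without the staircase dip that
  inner-boundary pixel centers exhibit;
* compactness = `4πA/P²` with the Crofton perimeter (4 directions), the
  estimator that is asymptotically unbiased for smooth shapes — a radius-20
  disc scores 0.968, and the value is clipped to 1;
* moment = `η₂₀ + η₀₂`, the normalised second-order central moments
  (1/(2π) for a disc), computed in physical coordinates.

3D features: volume = voxel count × voxel volume; surface area = exposed
voxel faces under 6-connectivity × per-face area (600 mm² for a 10 mm
cube); sphericity = `π^(1/3)(6V)^(2/3)/A`; centroid offset = mean in-plane
distance between per-slice centroids and the projected 3D centroid,
normalised by the volume-equivalent radius.

Degenerate one-pixel masks take ratio features 1 and moment 0; masks with
several connected components are reduced to the largest, with a log
message. Masks are indexed `(z, y, x)` with spacing stated in the same
order.

*Known discretization effects.* The face-count surface estimator
overestimates smooth areas by a direction-dependent factor (up to ~1.5 for
a sphere), so absolute sphericities are depressed and sphericity is not
strictly monotone under mild stretching of a sphere (it becomes monotone
from axis ratio ≈1.5 onward, and a sphere always outranks a 3:1 prolate).
Dimensionless features are stable to within ~2 % under halving the voxel
pitch for nodule-scale shapes (radius ≥ 8 voxels); small shapes
(radius ≈ 5) see up to ~7 % drift in compactness.

## Synthetic data

No reference dataset is deposited, so the package generates its own:

* **Feature clouds.** Two isotropic Gaussian clusters, minority at the
  origin, majority displaced along the first axis by `separation` (in
  within-class SD units, default 3 — far enough apart to be learnable,
  close enough that a plain SVM at ratio 6 visibly loses minority recall).
  Planted boundary-noise points (a requested fraction of the majority,
  ≤ 5 %) are placed past the minority center at 50–85 % of the minority
  cloud's empirical average radius, which puts them inside the minority
  cloud *and* beyond the majority's 95th-percentile radius — both clauses
  of the detection rule — and the detector recovers ≥ 80 % of them
  (98 % averaged over 20 seeds in the test suite).
* **Voxel masks.** Nodules are near-spherical ellipsoids (pairwise axis
  ratios within [0.8, 1.25]) with a mild smooth radial perturbation;
  non-nodules are tubes with long/short axis ≥ 3. Both fit the protocol's
  10–50 px in-plane / 5–13 slice envelope. The study-scale cohort is 150
  nodules + 908 non-nodules.

What the generators do **not** emulate: the heavy-tailed, correlated,
multi-modal feature distributions of real CT candidates, annotation noise,
and the severe feature overlap that makes real nodule recall collapse to
~35 %. Consequently the *absolute* performance numbers obtained on
synthetic cohorts say nothing about real CT data; only counting rules,
invariances and directional orderings are meaningful, and those are what
the tests assert. In particular, the claim that the combined balancer's
accuracy is the most stable across training ratios is a real-data
phenomenon we could not reproduce on Gaussian clouds (a plain SVM is
already stable there, while resampling adds stochastic variation), so the
ratio sweep is exercised for protocol correctness, not for that ordering.

## Cross-validation harness

`m × 2` cross-validation is read as `m` independent stratified half/half
splits with the first half used for training — with odd class counts the
extra sample goes to the training half. A `swap_halves` option adds the
mirrored fold of each split. All four classifiers within a repeat are
evaluated on the identical test half. Aggregation reports both the mean of
per-repeat metrics and the metrics of summed confusion counts, since the
two readings differ in general; displayed confusion counts are means
rounded to integers. The ratio sweep trains one model set per requested
ratio and scores all of them against a single fixed test cohort
(75/454 by default).

Default experiment sizes (75/454 training halves, m = 5, cohorts of 1058
masks) match the reference protocol and run in seconds on one CPU.
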