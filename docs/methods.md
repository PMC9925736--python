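# Methods

This note documents the models, the synthetic data, the numerical choices
and the limitations of the package. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate conventions and units

Global frame: x = body axis (anterior → posterior), y = lateral,
z = vertical up, floor near z = 0. All coordinates are metres; tabular
circumferences/lengths are centimetres, weights kilograms, ages whole
days — matching the units of the farm records the tabular pipeline
emulates.

## Synthetic pig and scene

The pig body is a loft of superellipse cross-sections
`|y/a(t)|^p + |z/b(t)|^p = 1` along the body parameter `t ∈ [0, 1]`, with a
dorsal arch `arch(t) = A·sin(πt)` and four short vertical leg cylinders.
The default ("standard") shape has a head bump near `t = 0.07`, a neck dip
at `t = 0.20`, a withers bump at `t = 0.33` and an abdominal width maximum
at `t = 0.55`; the half-height scale is solved so the withers local
maximum sits exactly at the requested withers height, and the head
overtops the withers — the property the anterior-end detector relies on.
The width profile tapers to a rounded snout and tail while the dorsal
profile stays gentle, so the ridge arc is the back and not the end caps.

`body_length` is defined as the dorsal-ridge **arc** length; the generator
solves for the straight axial span whose ridge arc equals the requested
length (Brent's method on a dense ridge grid), so the ground truth always
equals the parameter. All ground truth is obtained by dense numerical
integration of the parametric shape (20,001-point grids; 400,001 chords
for section perimeters), independent of the sampled points.

Default shape values approximate a finishing Duroc-line pig: length
1.2 m, withers height 0.63 m, abdominal half-width 0.19 m (circumference
≈ 1.18 m), leg stubs 0.22 m, section exponent 2.4.

Scenes add a floor plane (vertical scatter truncated at ±4σ), two railing
bars parallel to the body axis at flank height, and sparse uniform noise,
each point labeled by class. The floor point count (12,000 against 20,000
pig points) is chosen so floor and pig surface sampling densities are
comparable, as they are for a real depth sensor imaging both. The camera
rig holds three poses (top/left/right) with rotations within ±30° and
ranges within the depth camera's 0.5–4.5 m working band, plus a 0.4 m
reference cube resting on the floor.

What the generator does **not** emulate: occlusion and self-shadowing,
depth-sensor noise physics (noise is isotropic Gaussian), animal posture
variation, and multi-animal scenes. Passing tests therefore demonstrate
algorithmic correctness under clean capture conditions, not robustness to
every farm artifact.

## Registration

Per view, point normals are estimated by local PCA (k = 12 neighbours),
coplanar clusters grown on the kNN graph (normal agreement within 6°,
point-to-plane compatibility), and each face plane fitted by least
squares with trim-refit rounds (points beyond 3× the median absolute
residual are discarded — region growing can bridge two faces through the
noisy edge zone, and a low retained fraction flags and rejects such
merged clusters). Opposite faces pair into axes; the nearest proper
rotation to the axis triplet (SVD polar factor, with one axis flipped
first if the triplet is left-handed) gives the cube orientation, and the
centre solves the least-squares system `nᵢ·c = dᵢ − s/2` over the outward
faces.

A cube has 24 rotational symmetries; the ambiguity is resolved by taking
the cube-group element that makes the recovered view pose closest to the
global frame (maximum trace). This is valid while camera rotations stay
below 45°, which the rig geometry guarantees. Measured recovery: exact to
machine precision on noiseless cubes; worst case ≈ 0.14° / 4.3 mm over
20 seeds at 2 mm sensor noise.

## Filtering

RANSAC floor segmentation uses 3-point hypotheses, inlier-count scoring
at a 1 cm distance threshold, 1000 iterations, a seeded generator and a
final least-squares refit on the consensus set. The minimum inlier
fraction defaults to 0.10: after the pass-through crop to the pen strip
the floor retains roughly 10–15 % of the points while remaining the
dominant plane. Radius outlier removal counts strict neighbours (the
query point excluded) via a k-d tree; defaults r = 3 cm, h = 5. Railing
bars are removed by the pass-through crop (their lateral offset is fixed
by the pen geometry), not by RANSAC.

## Morphometry

**Orientation.** The body axis is the principal direction of the
horizontal spread (rotation about z only — the floor fixes the vertical);
the anterior end is the end whose nearest height-profile maximum is
higher.

**Length.** The dorsal ridge is extracted per 2 cm axial bin as the mean
of the top 1 cm vertical band, projected onto the longitudinal section
(the vertical plane through the body axis — the ridge of a bilaterally
symmetric body lies there, and projecting removes the lateral jitter of
the band means, which otherwise inflates the arc by ~1.5 %). The polyline
is extended to the exact axial extremes, fitted with a smoothing
parametric cubic spline (s = m·(1 mm)²) and integrated by composite
Simpson quadrature on 4097 samples. Clouds that are already bare ridge
curves (detected by their small lateral spread) are chord-summed
directly, with the end bins sub-binned vertically so near-vertical arcs
(e.g. a semicircular ridge) are traversed, not collapsed; this path
recovers a semicircle's arc to 0.03 %.

**Withers height.** Heights above the floor plane are reduced to per-bin
maxima, smoothed by a 3-bin moving maximum, and scanned with a peak
finder (prominence ≥ 1.5 cm). Counted from the anterior end, the first
maximum is the head, the second is the withers; fewer than two maxima is
an error (a cylinder has no withers).

**Abdominal slice.** Limb positions are the bins whose lowest point
reaches below 40 % of the belly line; the slab (2 cm thick) of greatest
lateral extent strictly between the innermost limbs is the measurement
site. Ties (a uniform cylinder) resolve to the lowest-x candidate. With
no limbs detected the central 70 % of the body is searched.

**Polar conversion.** The slice is projected to (y, z) and converted
about its centroid pole with the two-branch rule
`θ = arctan(−(y−y₀)/(z−z₀)) + π/2` (y ≥ y₀) or `+ 3π/2` (y < y₀). This
rule is *not* the continuous counter-clockwise angle: it maps each (y, z)
quadrant to a different angular quadrant (upper-left → (3π/2, 2π), etc.).
It is a bijection on the slice, and for cross-sections centrally
symmetric about the pole (superellipse-like animal sections) the induced
radius function — and hence the circumference integral — is identical to
the continuous convention's. For strongly asymmetric slices about an
off-centre pole the scrambling would corrupt the fit; the pipeline's
slices have full angular coverage and near-central poles, where the rule
is safe. A point coincident with the pole keeps ρ = 0 and gets θ = 0.

**Closed curve and circumference.** ρ(θ) is fitted with a periodic cubic
b-spline (FITPACK), requiring ≥ 8 samples spanning ≥ 270°; angular gaps
(railing shadow) are bridged by the periodic basis. The default smoothing
`s = m·(3 mm)²` matches the few-millimetre scatter of slab-projected
sensor data; for exact synthetic profiles the tests pass `s = 0`
(interpolation), which reconstructs a 30°-occluded ellipse to 0.02 % and
its perimeter to <0.1 % of a 10⁶-chord oracle. The circumference integral
uses the spline's analytic derivative and composite Simpson on 4097
points (`f ≡ r` recovers `2πr` to < 10⁻⁶ relative).

Recovery on zero-noise 10⁵-point synthetic pigs is within 2 % for all
four measures (typically < 1 %), degrades monotonically with noise, and
is invariant (< 0.5 %) to yaw-plus-translation repositioning. Extremal
statistics (per-bin maxima, slice extent) are sensitive to heavy noise:
beyond ~3 mm isotropic noise the limb detector and width estimator lose
reliability, so the pipeline assumes roughly Kinect-class (≈ 2 mm) noise.

## Tabular pipeline

Cleaning derives age in whole days, one-hot encodes gender and breed, and
imputes missing heights with the median of observed heights over the
whole table (the reference protocol; a strict train-only median is
available via `PigRecordCleaner(use_fitted_median=True)`).

Row normalization divides each feature row by the Euclidean norm of the
full 11-value row *including the weight*; the weight label itself stays
in kilograms. This is the only convention that reproduces the published
normalized sample at 4 decimals (row-1 norm √105276.25 ≈ 324.463). It
carries an inherent label leakage — each feature row depends on its own
weight — which is reproduced faithfully because it is the reference
protocol; `include_weight_in_norm=False` provides the leakage-free
variant. Notably, the one-hot columns of a normalized row equal 1/norm,
so a sufficiently flexible model given all ten normalized features could
in principle invert the leakage; the 5-4-4 perceptron is far too small to
do so.

Feature variance for the threshold filter is population variance
(divide by n), and retention is strict inequality (> threshold).
Correlation is Pearson over the ten features plus weight; a constant
column raises an error rather than returning NaN.

## Weight model

The network is `[D, 5, 4, 4, 1]` (parameter count 5·D + 54): ReLU on the
three hidden layers, linear output — a rectified output would forbid
negative pre-activations and contradicts regression practice. Training is
mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) on the exact MSE
gradient, learning rate 0.01, 300 epochs, batch 10, per-epoch seeded
shuffling, uniform fan-in initialization (U(±1/√fan_in) for weights and
biases). No early stopping, learning-rate schedule or weight decay; the
validation split only monitors loss. Loss histories store all 300 epochs.

**Optimization caveat.** A network this small driven at learning rate
0.01 from raw-scale inputs occasionally collapses onto the constant
predictor or a mediocre local optimum: the violent initial transient
(errors ≈ −110 kg) can kill an entire hidden layer's rectifiers, after
which little or no gradient flows. The same attractors are reachable
with scikit-learn's `MLPRegressor` under the identical protocol, so this
is a property of the protocol, not of this implementation. Training is
therefore multi-start: an attempt is accepted once it explains at least
85 % of the training-target variance, otherwise it is re-initialized
from the next seeded draw (up to 4 restarts) and the attempt with the
lowest final training MSE is kept; `n_restarts_used_` records the count. On the default synthetic herd (10,000 records,
σ = 2 kg additive noise, weight a linear-plus-tanh function of abdominal
circumference and age), model 1 then recovers the noise floor with test
RMSE ≈ 2.0–2.5 kg across seeds. On the row-normalized table the tiny
network typically plateaus well above the floor for every variant, and
the reduced models (2, 3, 4) match or beat the all-feature model — the
qualitative ordering the reference protocol reports.

## Splits and metrics

70:15:15 shuffled partition (test and validation sizes floored, remainder
to train), deterministic per seed. Metrics: MSE, RMSE = √MSE, MAE, and
MAPE reported as a *fraction* (0.04, not 4 %); MAPE is undefined (an
error) when an actual value is zero. `rmse² = mse` and `mae ≤ rmse` hold
to 10⁻¹² and are property-tested.

## Reproducibility

Every stochastic component (cloud sampling, scene composition, per-view
sensor noise, RANSAC, splits, network initialization and shuffling)
consumes a `numpy` `default_rng` seeded from the caller; identical
seed + configuration reproduces clouds, tables, trained weights and
result files byte-for-byte. Problem sizes used by the test suite and the
acceptance script — 10⁵-point clouds for geometry recovery, 3,000-point
cube views, 500-point brute-force filter oracles, 10,000-record herds —
were chosen as the smallest sizes at which the asymptotic behavior is
clearly expressed.

## Known limitations

- No occlusion model: views see the whole scene, so view merging triples
  density rather than completing missing surfaces.
- The chest and waist circumferences of the tabular records are treated
  as given measurements; only the abdominal slice is localized
  geometrically.
- Anatomical landmarks (ear line, tail root) are approximated by the
  ridge extremes; true landmark detection is out of scope.
- The printed polar-angle branch rule is unsafe for strongly asymmetric
  slices about an off-centre pole (see above); a continuous-angle
  convention would be preferable for heavily occluded real captures.
- The weight model's published headline RMSE values depend on the private
  farm dataset and are not reproduced; the synthetic-herd noise-floor
  recovery is the substitute check.
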