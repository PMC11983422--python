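# Methods

This note records the models and procedures implemented in `stemleaf3d`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Synthetic plants and analytic fields

Every quantitative claim in the test suite is checked against procedurally
generated data with closed-form ground truth.

A synthetic plant is a cylindrical stem (radius r, length L, optional tilt
from vertical) plus leaf ribbons.  A leaf ribbon is a planar centerline
curve — a circular arc of given radius and sweep leaving the stem at a
droop angle, or a parabola — swept by a flat transverse segment whose width
follows a taper profile.  Ground truth is analytic: stem height = L, stem
"geometric" diameter = 2r, leaf length = centerline arc length by
quadrature, leaf width = maximum of the width profile.  Points are sampled
approximately uniformly per unit blade area (the centerline parameter is
drawn with probability proportional to local width), which is what a
uniform surface scan produces and keeps nearest-neighbor spacing
homogeneous across the blade.  The default taper (`"blade"`, sin^0.35 of
the arc-length fraction) widens quickly above the ligule and ends in a
pointed tip, as maize blades do; a pure sine taper is also available but
its vanishing width near base and tip starves those regions of sample
points and truncates the observed extremes.  Isotropic Gaussian noise with
sd = 0.1% of stem length is added by default.  All randomness derives from
a single integer seed per plant; the toy-dataset builder draws plant
parameters from documented ranges (stem length 8–12, radius 0.08–0.15,
tilt up to 20°, 2–4 leaves with phyllotactic azimuths, arc radius 3–6,
sweep 50–90°, maximum width 0.8–1.2, 1024 points per organ) and emits an
80/20 train/validation split.

The analytic implicit fields are a constant-density slab (in z) and ball.
For constant density σ₀ occupied over ray interval [t₀, t₁] of length
Λ, the expected depth has the closed form

    E[t] = t₀ + (1/σ₀ − e^{−σ₀Λ}(Λ + 1/σ₀)) / (1 − e^{−σ₀Λ}),

which tends to t₀ (an opaque surface) as σ₀→∞ and to the interval midpoint
as σ₀→0⁺.  Discrete compositing at 4096 midpoint samples reproduces it to
better than 1e-3 relative error, which bounds the discretization bias of
the extraction pipeline.

What the synthetic plants do **not** emulate: occlusion and view-dependent
density of real reconstructions, leaf rolling and twist (ribbons are flat
transversally), organ intersections, sensor-specific noise anisotropy, and
color variation beyond per-point jitter.  Passing the recovery suite shows
the geometric procedures are implemented correctly and are well-conditioned
at realistic sampling density; it does not certify accuracy on scanner or
radiance-field data.

## Depth extraction

Per-ray opacities are α_i = 1 − exp(−σ_i δ_i), transmittance
T_i = ∏_{j<i}(1 − α_j), weights w_i = T_i α_i and the surface depth is the
weight-averaged sample depth.  The final sample's interval extends to the
far bound of the sampling range.  A ray yields a point only when Σw_i ≥
`weight_floor` (default 0.5, i.e. the ray must be at least half absorbed);
this suppresses background "floaters" at the cost of dropping grazing
rays, and is exposed as a parameter.  Sampling is uniform (midpoint or
stratified) within [t1, t2]; importance sampling is out of scope because
the extraction math is independent of the sampler.

## PointSegNet

The reference configuration is frozen in `configs/reference.yaml`: stem
width 32, encoder stage widths (72, 160, 200, 448), decoder widths
(256, 176, 80, 64), head width 96, FPS rate 0.5 per stage, ball-query
k = 24 with radius 0.1·2^stage on the unit-normalized cloud, decoder edge
K = 16, two classes, 6 input channels (xyz + normals).  The published
constraints on the architecture are its budgets, not its widths; the frozen
configuration was calibrated once so that the instantiated network carries
1.33 M parameters and 4.73 G analytic FLOPs per 2048-point pass, and so
that the parameter counts of the five single/double-ablation variants
reproduce the published ordering (full > −CAM-SE > −EAFP > −ResMLP > −RSA >
−RSA&EAFP, with the −RSA variant near 1.07 M).  Three architecture-level
choices follow from that joint calibration: ball-query k is 24 rather than
the PointNet++-conventional 32 (FLOPs scale linearly in k while parameters
do not, and no width assignment meets both budgets at k = 32); the RSA
attention MLP has two layers; and the decoder ResMLP uses an identity
residual (no projection shortcut), while the encoder ResMLP keeps a
projected shortcut — which is exactly the parameter mass that disappears in
the −ResMLP variant.

Other conventions: FPS inside the network starts from the lexicographically
smallest point, making the whole forward pass permutation-equivariant; ball
query returns the k nearest points within the radius, padding shortfalls
with the nearest found; the fusion gate is the sigmoid of one learnable
scalar per stage; CAM-SE's per-channel statistic is u_c and
sd_c = sqrt(var_c + ε) with ε = 1e-5, combined by per-channel weights and
batch-normalized over the batch of pooled statistics (an affine transform
when the batch has a single row); feature interpolation is
inverse-distance-weighted over the 3 nearest coarse points with weights
1/(d + 1e-8).  RSA consumes the same downsampled input as the ResMLP
branch (parallel branches).  The analytic FLOP counter walks exactly these
layers, counts 2 ops per multiply-accumulate, includes batch-norm,
activation, gating, interpolation and edge-term arithmetic, and excludes
combinatorial neighbor-search index construction.

The engine underneath is a ~400-line reverse-mode autodiff on numpy arrays
(`autodiff.py`), with numba-accelerated kernels for farthest point sampling
and the gather backward scatter-add (`_fast.py`, with bit-identical numpy
fallbacks).  Feature math runs in float32; geometry in float64.

## Training protocol

AdamW (weight decay 1e-4), initial learning rate 1e-3 (the schedule's decay
epochs dominate late behavior; the initial rate is a convention), multistep
×0.1 decay at epochs 210 and 270 of 300, batch size 4, 2048 input points.
Augmentation: uniform scale in [0.8, 1.2], center-normalization to the unit
sphere, per-point Gaussian jitter (sd 0.001, clipped at ±0.005), and FPS
resampling with a random start when the cloud size differs from the input
size.  The PolyFocal loss uses γ = 2 and ε = 1.0 by default (the loss
family's source convention; both exposed), computed one-vs-rest with a
sigmoid so the same form covers 2- and 3-class plants; probabilities are
clamped to [1e-7, 1−1e-7] before logarithms — the polynomial coefficient
and the numerical-stability constant are deliberately separate quantities.
Metrics are one-vs-rest per class (IoU, precision, recall, F1) and their
macro averages; a class absent from both prediction and truth scores 1.

The scaled-down benchmark used by the test suite trains the quarter-width
configuration (`configs/tiny.yaml`, 512 input points) on 64 synthetic
plants for 30 epochs at batch 4, with milestones scaled to (21, 27); the
median over three seeds reaches validation mIoU ≈ 0.97 in roughly 80
seconds per seed on one CPU, against an acceptance floor of 0.85.  This
shows the network, loss, optimizer and data path learn the geometry
end-to-end; it says nothing about accuracy on real scans.

## Trait extraction

Alignment orients the stem's first principal axis to +z (sign chosen
upward-positive; ties broken toward +x).  Stem height is the stem's
z-extent after alignment.

Stem diameter is the plane-residual statistic: split the stem z-range into
four equal-height bins, fit z = ax + by + c to the lowest bin by least
squares (falling back to a level plane with a warning when the base is
degenerate in x/y), and report twice the median absolute residual.  This
procedure does not in general equal a cylinder's geometric diameter — for
a near-vertical cylinder the z-residuals of such a fit measure the axial
spread of the base bin, not its cross-section — so the package validates
it against an independent brute-force implementation of the same procedure
and reports it as defined, alongside the generator's geometric 2r ground
truth, without conflating the two.

Leaf instances are separated from the semantic leaf class by Euclidean
connected components with linking radius 6× the median nearest-neighbor
spacing; the factor was validated on the synthetic recovery suite (smaller
factors fragment sparse blade interiors, while genuinely distinct leaves
sit many multiples of the spacing apart).  Instances are reported in order
of attachment height (z of the leaf point nearest the stem).

Within a leaf, segments are equal-width slices of the projection onto the
leaf's PCA principal vector (default 15 segments; empty slices merge into
neighbors).  The width polyline of a segment joins its two extreme points
along the segment's own principal vector through `m_insert` (default 20)
uniformly spaced chord points snapped to the nearest cloud point — snapping
is what lets the polyline climb an arched cross-section (for a circular
arch the snapped points converge to the radial projections, and the
polyline length to the arc length; the exactly-semicircular arch, whose
chord passes through the circle center, is the one degenerate case).  The
length polyline chains the snapped midpoints of each segment's extreme
pair — for transverse-dominated segments these midpoints sit on the
centerline — bracketed by the leaf's global extreme points so base and tip
are included.  Both polylines are smoothed by 1-D Gaussian filtering of
each coordinate sequence (default σ = 1.0 vertex units, reflect boundary)
with the first and last vertices pinned: the endpoints are the measured
extremes, and unpinned filtering drags them inward and systematically
shortens the polyline.  Snapping ties resolve to the lowest point index;
width snapping searches the segment's own points, length-midpoint snapping
the whole leaf.

On the 20-plant toy benchmark these defaults recover stem height to ~0.1%,
leaf length to ~0.9% and leaf width to ~3.6% median relative error
(acceptance floors 1% / 3% / 5%).  Width errors are the largest because
residual snap jitter inflates the chord slightly and smoothing removes
most but not all of it.

Prediction quality is scored by R² = 1 − SS_res/SS_tot and RMSE; a constant
measured vector makes R² undefined and is rejected.

## Numerical and degenerate-input choices

Normal estimation flips eigenvectors to a positive z-component (+x on
ties) and returns (0, 0, 1) with a warning for rank-deficient
neighborhoods.  Otsu ground removal rescales the chosen color scalar
(default excess green, 2G − R − B) to [0, 255], thresholds at the 256-bin
between-class-variance maximum, and returns the cloud unchanged with a
warning when the scalar is constant or one class is empty.  The statistical
outlier filter uses k = 16 neighbors and threshold mean + 2·sd of the mean
neighbor distances.  Distances are Euclidean in raw input units throughout;
coordinates are treated as z-up.  Single-point or coincident clouds
normalize with scale 1 and warn.  A dataset of one plant trains with an
empty validation split only after an explicit warning, and `train_model`
refuses empty splits.

## Known limitations

The autodiff engine is single-threaded numpy and trains desk-scale
configurations only; the reference configuration is instantiated and
counted but not trained in the test suite.  The stem-diameter statistic is
reported as defined, with the caveat above.  Leaf instance separation by
connected components fails when predicted labels bridge touching leaves.
The depth extractor assumes the field is queryable at arbitrary points and
does not implement importance sampling or appearance embeddings.
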