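# stemleaf3d

3D plant phenotyping from point clouds: extraction of dense surface points
from an implicit radiance field, a lightweight stem/leaf semantic
segmentation network, and geometric measurement of four phenotypic traits —
stem height, stem diameter, leaf length and leaf width — from the segmented
cloud.  The package is aimed at plant-phenotyping researchers who want a
desk-testable implementation of this pipeline: every stage can be exercised
against procedurally generated plants and analytic density fields with
closed-form ground truth, no scanner or dataset required.

## What is implemented

**Depth extraction from an implicit field.**  Given per-ray density samples
σ_i at depths d_i with intervals δ_i, the discrete volume-rendering weights
are

    α_i = 1 − exp(−σ_i δ_i),   T_i = ∏_{j<i} (1 − α_j),   w_i = T_i α_i,

the surface depth is the expectation t_surf = Σ d_i w_i / Σ w_i (rays whose
total weight stays below a floor are discarded), and the surface point is
p = o + t_surf · d, colored by querying the field at p.

**PointSegNet.**  An encoder–decoder segmentation network with 1.33 M
parameters and 4.73 GFLOPs per 2048-point forward pass.  Four Global-Local
Set Abstraction (GLSA) encoder stages each halve the cloud by farthest point
sampling and fuse a local branch (ResMLP: ball-query grouping → shared
two-layer MLP → max-pool → residual shortcut) with a global branch
(Relative Spatial Attention: sigmoid attention over mean-centered
coordinates and features) through a learnable scalar gate, followed by a
channel attention built from pooled per-channel mean/sd statistics (CAM-SE).
Four Edge-Aware Feature Propagation (EAFP) decoder stages interpolate
features back up, fuse encoder skips, and smooth them with a KNN edge term
(mean over ReLU-rectified neighbor feature differences, K = 16).  Every
block can be ablated by a config flag.  Training uses the PolyFocal loss

    L = mean( −log(P_t) · (1−P_t)^γ + ε · (1−P_t)^{γ+1} ),

AdamW with weight decay 1e-4, a ×0.1 learning-rate decay at epochs 210 and
270 of 300, and scale/jitter/resampling augmentation.  The network runs on
a small numpy reverse-mode autodiff engine included in the package.

**Trait extraction.**  The cloud is rotated so the stem's PCA axis is +z;
stem height is the stem's z-extent.  Stem diameter follows the
plane-residual procedure: a least-squares plane z = ax + by + c is fitted
to the lowest quarter of the stem and the diameter is reported as twice the
median absolute residual.  Each leaf (instances split by Euclidean
clustering) is sliced into segments along its PCA principal vector; per
segment, the extreme points along the segment's own principal vector are
joined by a chord whose uniformly inserted points are snapped onto the
cloud (following arched cross-sections), giving the segment width — the
maximum over segments is the leaf width.  The snapped midpoints of the
segment extremes, bracketed by the leaf's global extreme points, form the
length polyline.  Both polylines are Gaussian-smoothed.  Predictions are
scored with R² and RMSE.

## Worked example

```bash
stemleaf3d synth --n-plants 4 --seed 1 --out-dir demo
stemleaf3d traits --in demo/plant_000.ply --out demo/measured.csv
```

The generator writes each plant as a labeled PLY plus a ground-truth table.
For plant 0 (three leaves) the analytic truth and the measured values are:

```
# demo/traits.csv (ground truth)          # demo/measured.csv
stem_height  leaf  length   width         stem_height  leaf  length   width
9.12164      0     4.14627  1.01526       9.13494      0     4.1169   1.03502
9.12164      1     5.67699  0.981399      9.13494      1     5.64407  0.98353
9.12164      2     3.92636  0.904925      9.13494      2     3.88792  0.926499
```

Stem height is recovered to 0.15%, leaf lengths to within ~1% and widths to
within ~2.5%.  The `stem_diameter` column (1.06 here versus the cylinder's
geometric 0.265) is the plane-residual statistic defined above — it is a
reproducible procedure validated against its own brute-force oracle, not an
estimate of the geometric diameter; see `docs/methods.md`.

Training and segmentation run the same way at desk scale:

```bash
stemleaf3d synth --n-plants 64 --seed 11 --out-dir data
stemleaf3d train --data-dir data --epochs 30 --seed 0 --out run
# -> best val mIoU 0.9788
stemleaf3d segment --weights run/weights.npz --in data/plant_000.ply --out seg.ply
```

From Python, the architecture budgets are one call each:

```python
>>> from stemleaf3d import reference_config, count_parameters, count_flops
>>> count_parameters(reference_config()) / 1e6
1.331766
>>> count_flops(reference_config()) / 1e9
4.726687008
```

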