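"""Procedural plant point clouds and analytic implicit fields.

Every downstream stage (preprocessing, segmentation, trait extraction, depth
extraction from a radiance field) is testable against closed-form ground
truth generated here, without any external dataset:

* plants are a cylindrical stem plus parametric leaf ribbons (a centerline
  curve swept by a flat transverse segment of known width), so stem height,
  stem diameter, leaf arc length and maximum leaf width are all analytic;
* implicit fields are constant-density slabs and spheres whose expected
  ray depth has a closed form, exercising the volume-rendering path.

All randomness flows from a single integer seed per plant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad

from .preprocess import LabeledPointCloud

__all__ = [
    "LeafSpec",
    "PlantSpec",
    "GroundTruthTraits",
    "AnalyticField",
    "ToyDataset",
    "STEM_LABEL",
    "LEAF_LABEL",
    "GROUND_LABEL",
    "generate_plant",
    "add_ground_disk",
    "make_slab_field",
    "make_sphere_field",
    "make_toy_dataset",
    "leaf_arc_length",
    "leaf_max_width",
]

STEM_LABEL = 0
LEAF_LABEL = 1
GROUND_LABEL = 255  # scene background; removed by Otsu before segmentation

PLANT_COLOR = np.array([70.0, 165.0, 60.0])  # green, byte scale
GROUND_COLOR = np.array([125.0, 95.0, 60.0])  # brown


@dataclass(frozen=True)
class LeafSpec:
    """A leaf blade: a planar centerline curve swept by a flat cross-segment.

    The centerline lies in the vertical plane through ``azimuth_deg``.  Two
    curve families are supported:

    * ``kind="arc"`` — a circular arc of ``radius`` and ``sweep_deg``; the
      blade leaves the stem at elevation ``droop_deg`` above horizontal and
      curves downward.  Arc length is radius * sweep (checked by quadrature).
    * ``kind="parabola"`` — z = coeff * u**2 over u in [0, extent].

    The width profile is ``max_width`` modulated by the taper function:
    ``"blade"`` (default) is a maize-like profile that widens quickly above
    the ligule and narrows to a pointed tip; ``"sine"`` is zero at base and
    tip and maximal mid-blade; ``"linear"`` is maximal at the base.
    """

    attach_height_frac: float = 0.6
    azimuth_deg: float = 0.0
    kind: str = "arc"
    radius: float = 5.0
    sweep_deg: float = 80.0
    coeff: float = -0.1
    extent: float = 5.0
    droop_deg: float = 45.0
    max_width: float = 0.9
    taper: str = "blade"

    def __post_init__(self):
        if self.max_width <= 0:
            raise ValueError("max_width must be positive")
        if self.kind not in ("arc", "parabola"):
            raise ValueError(f"unknown centerline kind {self.kind!r}")
        if not 0.0 <= self.attach_height_frac <= 1.0:
            raise ValueError("attach_height_frac must lie in [0, 1]")


@dataclass(frozen=True)
class PlantSpec:
    """Geometry and sampling parameters of one synthetic plant."""

    stem_radius: float = 0.1
    stem_length: float = 10.0
    stem_tilt_deg: float = 0.0
    leaves: tuple = ()
    points_per_organ: int = 512
    noise_sd: Optional[float] = None  # default: 0.1% of stem length
    seed: int = 0

    def __post_init__(self):
        if self.stem_radius <= 0 or self.stem_length <= 0:
            raise ValueError("stem dimensions must be positive")
        if not 0.0 <= self.stem_tilt_deg < 90.0:
            raise ValueError("stem_tilt_deg must lie in [0, 90)")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        fracs = [leaf.attach_height_frac for leaf in self.leaves]
        if len(fracs) != len(set(fracs)):
            raise ValueError("duplicate leaf attach heights (degenerate duplicate organ)")

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is None:
            return 1e-3 * self.stem_length
        return self.noise_sd


@dataclass(frozen=True)
class GroundTruthTraits:
    stem_height: float
    stem_diameter: float
    leaf_lengths: tuple
    leaf_widths: tuple


@dataclass
class AnalyticField:
    """A density + color field with (optionally) closed-form expected depth."""

    density_fn: Callable[[np.ndarray], np.ndarray]
    color_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    closed_form_depth: Optional[Callable] = None


# ---------------------------------------------------------------------------
# Leaf geometry


def _centerline_local(leaf: LeafSpec, s: np.ndarray):
    """Centerline in the local (u, z) plane.

    Returns (u, z, phi) where phi is the tangent direction angle.  For arcs
    the parameter s is arc length; for parabolas it is the horizontal run u.
    """
    s = np.asarray(s, dtype=np.float64)
    if leaf.kind == "arc":
        theta0 = np.deg2rad(leaf.droop_deg)
        phi = theta0 - s / leaf.radius
        u = leaf.radius * (np.sin(theta0) - np.sin(phi))
        z = leaf.radius * (np.cos(phi) - np.cos(theta0))
        return u, z, phi
    u = s
    z = leaf.coeff * u**2
    phi = np.arctan(2.0 * leaf.coeff * u)
    return u, z, phi


def _param_range(leaf: LeafSpec) -> float:
    if leaf.kind == "arc":
        return leaf.radius * np.deg2rad(leaf.sweep_deg)
    return leaf.extent


def _speed(leaf: LeafSpec, s: np.ndarray) -> np.ndarray:
    if leaf.kind == "arc":
        return np.ones_like(np.asarray(s, dtype=np.float64))
    return np.sqrt(1.0 + (2.0 * leaf.coeff * np.asarray(s)) ** 2)


def leaf_arc_length(leaf: LeafSpec) -> float:
    """Centerline arc length by numeric quadrature."""
    length, _ = quad(lambda s: float(_speed(leaf, s)), 0.0, _param_range(leaf))
    return length


def _width_at(leaf: LeafSpec, frac: np.ndarray) -> np.ndarray:
    """Blade width at normalized arc-length position frac in [0, 1]."""
    frac = np.asarray(frac, dtype=np.float64)
    if leaf.taper == "sine":
        return leaf.max_width * np.sin(np.pi * frac)
    if leaf.taper == "blade":
        # maize-like profile: widens quickly above the ligule, pointed tip
        return leaf.max_width * np.sin(np.pi * frac) ** 0.35
    if leaf.taper == "linear":
        return leaf.max_width * (1.0 - frac)
    raise ValueError(f"unknown taper {leaf.taper!r}")


def leaf_max_width(leaf: LeafSpec) -> float:
    frac = np.linspace(0.0, 1.0, 2001)
    return float(_width_at(leaf, frac).max())


def _arc_frac_grid(leaf: LeafSpec, n_grid: int = 512):
    """Parameter grid and its normalized-arc-length positions."""
    smax = _param_range(leaf)
    grid = np.linspace(0.0, smax, n_grid)
    if leaf.kind == "arc":
        frac = grid / smax
    else:
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (_speed(leaf, grid[1:]) + _speed(leaf, grid[:-1])) * np.diff(grid))])
        frac = cum / cum[-1]
    return grid, frac


def _sample_leaf(leaf: LeafSpec, attach: np.ndarray, n: int, rng) :
    """Sample n points approximately uniformly per unit blade area.

    The centerline parameter is drawn with probability proportional to the
    local blade width (inverse-CDF on a fine grid), which is what a uniform
    surface scan of the ribbon produces; the transverse coordinate is
    uniform across the local width.
    """
    grid, frac_grid = _arc_frac_grid(leaf)
    w_grid = np.maximum(_width_at(leaf, frac_grid), 1e-9)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w_grid[1:] + w_grid[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    s = np.interp(rng.uniform(0.0, 1.0, n), cdf, grid)
    u, z, phi = _centerline_local(leaf, s)
    frac = np.interp(s, grid, frac_grid)
    w = _width_at(leaf, frac)
    v = rng.uniform(-0.5, 0.5, n) * w
    az = np.deg2rad(leaf.azimuth_deg)
    e_az = np.array([np.cos(az), np.sin(az), 0.0])
    e_t = np.array([-np.sin(az), np.cos(az), 0.0])
    pts = attach + u[:, None] * e_az + z[:, None] * np.array([0.0, 0.0, 1.0]) + v[:, None] * e_t
    normals = np.cos(phi)[:, None] * np.array([0.0, 0.0, 1.0]) - np.sin(phi)[:, None] * e_az
    return pts, normals


def _tilt_rotation(tilt_deg: float) -> np.ndarray:
    """Rotation about the y-axis tilting the z-axis toward +x."""
    t = np.deg2rad(tilt_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def generate_plant(spec: PlantSpec) -> tuple[LabeledPointCloud, GroundTruthTraits]:
    """Sample a labeled plant cloud and its analytic trait ground truth.

    Labels: 0 = stem, 1 = leaf.  Points are sampled on the organ surfaces
    (stem lateral surface, leaf ribbons) plus isotropic Gaussian noise of
    sd ``spec.effective_noise_sd``.  Ground-truth stem height is the axial
    extent of the stem; leaf lengths come from centerline quadrature.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.points_per_organ
    # stem lateral surface
    z = rng.uniform(0.0, spec.stem_length, n)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    stem_pts = np.stack(
        [spec.stem_radius * np.cos(theta), spec.stem_radius * np.sin(theta), z], axis=1
    )
    stem_nrm = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    pts = [stem_pts]
    nrms = [stem_nrm]
    labels = [np.full(n, STEM_LABEL)]
    for leaf in spec.leaves:
        az = np.deg2rad(leaf.azimuth_deg)
        attach = np.array(
            [
                spec.stem_radius * np.cos(az),
                spec.stem_radius * np.sin(az),
                leaf.attach_height_frac * spec.stem_length,
            ]
        )
        lp, ln = _sample_leaf(leaf, attach, n, rng)
        pts.append(lp)
        nrms.append(ln)
        labels.append(np.full(n, LEAF_LABEL))
    positions = np.concatenate(pts)
    normals = np.concatenate(nrms)
    labels = np.concatenate(labels)
    rot = _tilt_rotation(spec.stem_tilt_deg)
    positions = positions @ rot.T
    normals = normals @ rot.T
    sd = spec.effective_noise_sd
    if sd > 0:
        positions = positions + rng.normal(0.0, sd, positions.shape)
    colors = np.clip(PLANT_COLOR + rng.normal(0.0, 12.0, positions.shape), 0, 255)
    cloud = LabeledPointCloud(
        positions=positions, normals=normals, colors=colors, labels=labels
    )
    traits = GroundTruthTraits(
        stem_height=spec.stem_length,
        stem_diameter=2.0 * spec.stem_radius,
        leaf_lengths=tuple(leaf_arc_length(leaf) for leaf in spec.leaves),
        leaf_widths=tuple(leaf_max_width(leaf) for leaf in spec.leaves),
    )
    return cloud, traits


def add_ground_disk(
    cloud: LabeledPointCloud,
    radius: float = 6.0,
    n_points: int = 1024,
    z: float = 0.0,
    seed: int = 0,
) -> LabeledPointCloud:
    """Append a flat brown disk (label 255) to exercise Otsu ground removal."""
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, n_points))
    t = rng.uniform(0.0, 2.0 * np.pi, n_points)
    pts = np.stack([r * np.cos(t), r * np.sin(t), np.full(n_points, z)], axis=1)
    colors = np.clip(GROUND_COLOR + rng.normal(0.0, 8.0, pts.shape), 0, 255)
    normals = np.tile([0.0, 0.0, 1.0], (n_points, 1))
    if cloud.colors is None:
        raise ValueError("cloud must have colors to compose a ground scene")
    return LabeledPointCloud(
        positions=np.concatenate([cloud.positions, pts]),
        normals=None
        if cloud.normals is None
        else np.concatenate([cloud.normals, normals]),
        colors=np.concatenate([cloud.colors_as_bytes(), colors]),
        labels=None
        if cloud.labels is None
        else np.concatenate([cloud.labels, np.full(n_points, GROUND_LABEL)]),
    )


# ---------------------------------------------------------------------------
# Analytic implicit fields


def _interval_expected_depth(t_entry: float, t_exit: float, sigma0: float) -> float:
    """Closed-form expected depth of a constant-density interval on a ray.

    With density sigma0 on [t_entry, t_exit] and zero elsewhere, the
    render-weight density is w(t) = sigma0 * exp(-sigma0 (t - t_entry)) and

        E[t] = t_entry + (1/s - e^{-sL} (L + 1/s)) / (1 - e^{-sL}),

    which tends to t_entry as sigma0 -> inf (opaque surface) and to the
    interval midpoint as sigma0 -> 0+.
    """
    L = t_exit - t_entry
    sL = sigma0 * L
    if sL < 1e-12:
        return t_entry + 0.5 * L
    em = np.exp(-sL)
    return t_entry + (1.0 / sigma0 - em * (L + 1.0 / sigma0)) / (1.0 - em)


def make_slab_field(near: float, far: float, sigma0: float) -> AnalyticField:
    """Constant-density slab near <= z <= far with closed-form expected depth."""
    if not 0 < near < far:
        raise ValueError("require 0 < near < far")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")

    def density(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        zc = p[:, 2]
        return np.where((zc >= near) & (zc <= far), sigma0, 0.0)

    def color(p: np.ndarray, d: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        return np.tile([0.2, 0.7, 0.3], (len(p), 1))

    def depth(origin: np.ndarray, direction: np.ndarray) -> float:
        dz = direction[2]
        if abs(dz) < 1e-12:
            return np.nan
        t0 = (near - origin[2]) / dz
        t1 = (far - origin[2]) / dz
        t_entry, t_exit = min(t0, t1), max(t0, t1)
        if t_exit <= 0:
            return np.nan
        t_entry = max(t_entry, 0.0)
        return _interval_expected_depth(t_entry, t_exit, sigma0)

    return AnalyticField(density_fn=density, color_fn=color, closed_form_depth=depth)


def make_sphere_field(
    center, radius: float, sigma0: float
) -> AnalyticField:
    """Constant-density ball with closed-form expected depth along any ray."""
    center = np.asarray(center, dtype=np.float64)
    if radius <= 0 or sigma0 <= 0:
        raise ValueError("radius and sigma0 must be positive")

    def density(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        return np.where(
            np.linalg.norm(p - center, axis=1) <= radius, sigma0, 0.0
        )

    def color(p: np.ndarray, d: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        return np.tile([0.3, 0.6, 0.2], (len(p), 1))

    def depth(origin: np.ndarray, direction: np.ndarray) -> float:
        oc = np.asarray(origin, dtype=np.float64) - center
        d = np.asarray(direction, dtype=np.float64)
        b = np.dot(oc, d)
        c = np.dot(oc, oc) - radius**2
        disc = b * b - c
        if disc <= 0:
            return np.nan
        root = np.sqrt(disc)
        t_entry, t_exit = -b - root, -b + root
        if t_exit <= 0:
            return np.nan
        t_entry = max(t_entry, 0.0)
        return _interval_expected_depth(t_entry, t_exit, sigma0)

    return AnalyticField(density_fn=density, color_fn=color, closed_form_depth=depth)


# ---------------------------------------------------------------------------
# Toy dataset

DEFAULT_SPEC_RANGES: dict = {
    "stem_length": (8.0, 12.0),
    "stem_radius": (0.08, 0.15),
    "stem_tilt_deg": (0.0, 20.0),
    "n_leaves": (2, 4),
    "leaf_radius": (3.0, 6.0),
    "sweep_deg": (50.0, 90.0),
    "droop_deg": (30.0, 60.0),
    "max_width": (0.8, 1.2),
    "attach_frac": (0.35, 0.95),
    "points_per_organ": 1024,
}


@dataclass
class ToyDataset:
    """Reproducible labeled plants with an 80/20 train/validation split."""

    samples: list  # (LabeledPointCloud, GroundTruthTraits)
    train_indices: np.ndarray
    val_indices: np.ndarray
    specs: list = field(default_factory=list)


def _draw_spec(rng, ranges: dict, seed: int) -> PlantSpec:
    u = lambda key: rng.uniform(*ranges[key])
    n_leaves = int(rng.integers(ranges["n_leaves"][0], ranges["n_leaves"][1] + 1))
    lo, hi = ranges["attach_frac"]
    # evenly spaced attachment heights with jitter, phyllotactic azimuths
    base = np.linspace(lo, hi, n_leaves)
    gap = (hi - lo) / max(n_leaves - 1, 1)
    fracs = np.clip(base + rng.uniform(-0.2, 0.2, n_leaves) * gap, lo, hi)
    fracs = np.sort(fracs)
    azimuths = (rng.uniform(0, 360) + 137.5 * np.arange(n_leaves)
                + rng.uniform(-20, 20, n_leaves)) % 360.0
    leaves = tuple(
        LeafSpec(
            attach_height_frac=float(fracs[i]),
            azimuth_deg=float(azimuths[i]),
            kind="arc",
            radius=u("leaf_radius"),
            sweep_deg=u("sweep_deg"),
            droop_deg=u("droop_deg"),
            max_width=u("max_width"),
        )
        for i in range(n_leaves)
    )
    return PlantSpec(
        stem_radius=u("stem_radius"),
        stem_length=u("stem_length"),
        stem_tilt_deg=u("stem_tilt_deg"),
        leaves=leaves,
        points_per_organ=int(ranges["points_per_organ"]),
        seed=seed,
    )


def make_toy_dataset(
    n_plants: int, spec_ranges: dict | None = None, seed: int = 0
) -> ToyDataset:
    """Draw ``n_plants`` reproducible plants and an 80/20 split.

    Per-plant specs are drawn uniformly from ``spec_ranges`` (see
    ``DEFAULT_SPEC_RANGES``); the same seed always yields identical plants.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        ranges.update(spec_ranges)
    rng = np.random.default_rng(seed)
    specs = [_draw_spec(rng, ranges, int(rng.integers(2**31))) for _ in range(n_plants)]
    samples = [generate_plant(s) for s in specs]
    perm = rng.permutation(n_plants)
    n_val = int(n_plants * 0.2)
    if n_val == 0:
        warnings.warn("dataset too small for a validation split; validation set empty")
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])
    return ToyDataset(
        samples=samples, train_indices=train_idx, val_indices=val_idx, specs=specs
    )
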