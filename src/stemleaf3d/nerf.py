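"""Expected-depth point-cloud extraction from an implicit radiance field.

Given per-ray density samples, the discrete volume-rendering quantities are

    alpha_i = 1 - exp(-sigma_i * delta_i)            (opacity of interval i)
    T_i     = prod_{j<i} (1 - alpha_j)               (accumulated transmittance)
    w_i     = T_i * alpha_i                          (rendering weight)
    t_surf  = sum_i d_i w_i / sum_i w_i              (expected depth)

and the surface point is back-projected as p = o + t_surf * d.  Rays whose
total weight falls below ``weight_floor`` are treated as not having hit a
surface.  The field is anything exposing ``density(p) -> sigma`` and
``color(p, d) -> rgb``; the analytic slab/sphere fields in
:mod:`stemleaf3d.synthetic` provide closed-form oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .preprocess import LabeledPointCloud

__all__ = [
    "CameraRay",
    "RaySamples",
    "DepthResult",
    "alphas",
    "transmittance",
    "render_weights",
    "expected_depth",
    "backproject",
    "sample_ray",
    "extract_pointcloud",
    "orbit_rays",
    "orthographic_rays",
]

DEFAULT_WEIGHT_FLOOR = 0.5


@dataclass(frozen=True)
class CameraRay:
    """A ray o + t*d with unit direction."""

    origin: np.ndarray
    direction: np.ndarray
    pixel_id: Optional[tuple] = None

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64))
        d = np.asarray(self.direction, dtype=np.float64)
        norm = np.linalg.norm(d)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("ray direction must be nonzero")
            d = d / norm
        object.__setattr__(self, "direction", d)


@dataclass
class RaySamples:
    """Ascending sample depths with intervals, densities and optional colors."""

    depths: np.ndarray
    deltas: np.ndarray
    densities: np.ndarray
    colors: Optional[np.ndarray] = None

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.float64)
        self.deltas = np.asarray(self.deltas, dtype=np.float64)
        self.densities = np.asarray(self.densities, dtype=np.float64)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("sample depths must be strictly increasing")
        if np.any(self.deltas <= 0):
            raise ValueError("sample intervals must be positive")
        if np.any(self.densities < 0):
            raise ValueError("densities must be nonnegative")


@dataclass
class DepthResult:
    t_surface: float
    weights: np.ndarray
    total_weight: float
    valid: bool


def alphas(samples: RaySamples) -> np.ndarray:
    """Per-sample opacity alpha_i = 1 - exp(-sigma_i * delta_i), in [0, 1)."""
    return 1.0 - np.exp(-samples.densities * samples.deltas)


def transmittance(alpha: np.ndarray) -> np.ndarray:
    """Accumulated transmittance T_i = prod_{j<i} (1 - alpha_j); T_1 = 1."""
    alpha = np.asarray(alpha, dtype=np.float64)
    T = np.empty_like(alpha)
    T[..., 0] = 1.0
    if alpha.shape[-1] > 1:
        T[..., 1:] = np.cumprod(1.0 - alpha[..., :-1], axis=-1)
    return T


def render_weights(samples: RaySamples) -> np.ndarray:
    """Rendering weights w_i = T_i * alpha_i; sums to 1 - prod(1 - alpha)."""
    a = alphas(samples)
    return transmittance(a) * a


def expected_depth(
    samples: RaySamples, weight_floor: float = DEFAULT_WEIGHT_FLOOR
) -> DepthResult:
    """Weight-averaged sample depth; invalid when the ray is barely absorbed."""
    w = render_weights(samples)
    total = float(w.sum())
    if total < weight_floor or total <= 0.0:
        return DepthResult(t_surface=np.nan, weights=w, total_weight=total, valid=False)
    t = float(np.dot(samples.depths, w) / total)
    return DepthResult(t_surface=t, weights=w, total_weight=total, valid=True)


def backproject(ray: CameraRay, t: float) -> np.ndarray:
    """World-space point p = o + t * d."""
    if t <= 0:
        raise ValueError("depth must be positive")
    return ray.origin + t * ray.direction


def sample_ray(
    ray: CameraRay,
    field,
    t1: float,
    t2: float,
    n_samples: int,
    rng: Optional[np.random.Generator] = None,
) -> RaySamples:
    """Sample the field along a ray: uniform bins, optionally stratified.

    Depths are bin midpoints (or stratified draws within each bin when a
    generator is supplied); the last interval extends to the far bound.
    """
    if not t1 < t2:
        raise ValueError("require t1 < t2")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    edges = np.linspace(t1, t2, n_samples + 1)
    if rng is None:
        depths = 0.5 * (edges[:-1] + edges[1:])
    else:
        depths = edges[:-1] + rng.uniform(0.0, 1.0, n_samples) * np.diff(edges)
    deltas = np.empty(n_samples)
    deltas[:-1] = np.diff(depths)
    deltas[-1] = t2 - depths[-1]
    points = ray.origin[None, :] + depths[:, None] * ray.direction[None, :]
    densities = np.asarray(field.density_fn(points), dtype=np.float64).reshape(-1)
    return RaySamples(depths=depths, deltas=deltas, densities=densities)


def extract_pointcloud(
    field,
    rays: Sequence[CameraRay],
    t1: float,
    t2: float,
    n_samples: int = 256,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
    rng: Optional[np.random.Generator] = None,
) -> LabeledPointCloud:
    """One surface point per sufficiently absorbed ray, colored by the field.

    Rays from multiple views are simply concatenated in the world frame.
    Returns a cloud with zero points (and a warning) when no ray is valid.
    """
    if len(rays) == 0:
        raise ValueError("need at least one ray")
    points, colors = [], []
    for ray in rays:
        samples = sample_ray(ray, field, t1, t2, n_samples, rng=rng)
        result = expected_depth(samples, weight_floor=weight_floor)
        if not result.valid:
            continue
        p = backproject(ray, result.t_surface)
        points.append(p)
        colors.append(
            np.asarray(field.color_fn(p[None, :], ray.direction[None, :])).reshape(3)
        )
    if not points:
        warnings.warn("no ray accumulated enough weight; extracted cloud is empty")
        return LabeledPointCloud(positions=np.zeros((0, 3)))
    return LabeledPointCloud(
        positions=np.asarray(points), colors=np.asarray(colors)
    )


def orthographic_rays(
    n_u: int,
    n_v: int,
    extent: float,
    direction=(0.0, 0.0, 1.0),
    origin_plane: float = 0.0,
) -> list[CameraRay]:
    """A grid of parallel rays along +direction starting on a z=const plane."""
    direction = np.asarray(direction, dtype=np.float64)
    us = np.linspace(-extent, extent, n_u)
    vs = np.linspace(-extent, extent, n_v)
    rays = []
    for i, u in enumerate(us):
        for j, v in enumerate(vs):
            rays.append(
                CameraRay(
                    origin=np.array([u, v, origin_plane]),
                    direction=direction,
                    pixel_id=(i, j),
                )
            )
    return rays


def orbit_rays(
    target,
    orbit_radius: float,
    n_views: int,
    rays_per_view: int,
    cone_half_angle_deg: float = 12.0,
    elevation_deg: float = 15.0,
    seed: int = 0,
) -> list[CameraRay]:
    """Rays from cameras orbiting a target point, jittered within a view cone."""
    target = np.asarray(target, dtype=np.float64)
    rng = np.random.default_rng(seed)
    rays = []
    elev = np.deg2rad(elevation_deg)
    for v in range(n_views):
        az = 2.0 * np.pi * v / n_views
        origin = target + orbit_radius * np.array(
            [np.cos(az) * np.cos(elev), np.sin(az) * np.cos(elev), np.sin(elev)]
        )
        forward = target - origin
        forward /= np.linalg.norm(forward)
        # orthonormal basis around the viewing direction
        up = np.array([0.0, 0.0, 1.0])
        right = np.cross(forward, up)
        right /= np.linalg.norm(right)
        true_up = np.cross(right, forward)
        half = np.tan(np.deg2rad(cone_half_angle_deg))
        offs = rng.uniform(-half, half, (rays_per_view, 2))
        for k in range(rays_per_view):
            d = forward + offs[k, 0] * right + offs[k, 1] * true_up
            rays.append(CameraRay(origin=origin, direction=d / np.linalg.norm(d),
                                  pixel_id=(v, k)))
    return rays
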