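"""Phenotypic trait extraction from segmented plant clouds.

Four traits are measured from a stem/leaf-labeled cloud:

* **stem height** — the cloud is rotated so the stem's first principal axis
  is the +z axis, then height = max z - min z over stem points;
* **stem diameter** — the stem's z-range is split into four equal-height
  bins; a least-squares plane z = a*x + b*y + c is fitted to the lowest
  bin and the diameter is reported as twice the median absolute residual
  (the procedure is applied verbatim; see the methods note for the caveat
  that this is not in general the geometric diameter of a cylinder);
* **leaf length / width** — the leaf is sliced into segments of equal
  extent along its PCA principal vector.  Within each segment the extreme
  points along the segment's own principal vector are joined by a chord
  with uniformly inserted points snapped onto the cloud, giving a width
  polyline that follows an arched cross-section; the longest segment
  polyline is the leaf width.  The snapped midpoints of the segment
  extremes, bracketed by the leaf's global extreme points, form the length
  polyline.  Both polylines are Gaussian-smoothed per coordinate.

Leaf instances are separated from the semantic leaf class by Euclidean
connected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .preprocess import LabeledPointCloud

__all__ = [
    "Polyline",
    "LeafMeasurement",
    "TraitReport",
    "TraitParams",
    "align_stem_to_z",
    "stem_height",
    "stem_diameter",
    "split_leaf_instances",
    "leaf_segments",
    "segment_width_polyline",
    "leaf_length_polyline",
    "gaussian_smooth_polyline",
    "extract_traits",
    "r2_rmse",
]


@dataclass
class Polyline:
    vertices: np.ndarray  # (V, 3), ordered
    role: str = "length"  # or "width"
    smoothed: bool = False

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        if len(self.vertices) < 2:
            raise ValueError("a polyline needs at least 2 vertices")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum())


@dataclass
class LeafMeasurement:
    leaf_id: int
    length: float
    width: float
    length_polyline: Polyline
    width_polyline: Polyline


@dataclass
class TraitReport:
    stem_height: Optional[float]
    stem_diameter: Optional[float]
    leaves: list
    alignment_rotation: np.ndarray


@dataclass
class TraitParams:
    n_segments: int = 15
    m_insert: int = 20
    sigma: float = 1.0
    stem_label: int = 0
    leaf_label: int = 1
    cluster_factor: float = 6.0  # times the median NN spacing
    min_leaf_points: int = 20


# ---------------------------------------------------------------------------
# Stem traits


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping ``axis`` onto +z (Rodrigues construction)."""
    a = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(np.dot(a, z))
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def align_stem_to_z(
    cloud: LabeledPointCloud, stem_label: int = 0
) -> tuple[LabeledPointCloud, np.ndarray]:
    """Rotate the whole cloud so the stem's principal axis is +z."""
    if cloud.labels is None:
        raise ValueError("cloud has no labels")
    stem = cloud.positions[cloud.labels == stem_label]
    if len(stem) < 3:
        raise ValueError("need at least 3 stem points for PCA alignment")
    axis = _principal_axis(stem)
    # orient upward: prefer positive z-component, positive x on ties
    if axis[2] < 0 or (axis[2] == 0 and axis[0] < 0):
        axis = -axis
    R = _rotation_to_z(axis)
    rotated = cloud.with_positions(cloud.positions @ R.T)
    if rotated.normals is not None:
        rotated.normals = rotated.normals @ R.T
    return rotated, R


def stem_height(cloud: LabeledPointCloud, stem_label: int = 0) -> float:
    """Axial stem extent of an aligned cloud: max z - min z over stem points."""
    stem_z = cloud.positions[cloud.labels == stem_label][:, 2]
    if len(stem_z) == 0:
        raise ValueError("no stem points")
    if len(stem_z) == 1:
        warnings.warn("single-point stem; height is 0")
        return 0.0
    return float(stem_z.max() - stem_z.min())


def stem_diameter(cloud: LabeledPointCloud, stem_label: int = 0) -> float:
    """Twice the median absolute z-residual of a plane fit to the stem base.

    The stem z-range is split into four equal-height bins and the plane
    z = a*x + b*y + c is least-squares fitted to the lowest bin.
    """
    stem = cloud.positions[cloud.labels == stem_label]
    if len(stem) == 0:
        raise ValueError("no stem points")
    z = stem[:, 2]
    zmin, zmax = z.min(), z.max()
    cut = zmin + 0.25 * (zmax - zmin)
    base = stem[z <= cut]
    if len(base) < 8:
        raise ValueError(
            f"only {len(base)} stem points in the lowest quarter; need >= 8"
        )
    A = np.column_stack([base[:, 0], base[:, 1], np.ones(len(base))])
    rank = np.linalg.matrix_rank(A)
    if rank < 3:
        warnings.warn("stem base degenerate in x/y; falling back to a level plane")
        pred = np.full(len(base), base[:, 2].mean())
    else:
        coef, *_ = np.linalg.lstsq(A, base[:, 2], rcond=None)
        pred = A @ coef
    residuals = base[:, 2] - pred
    diameter = 2.0 * float(np.median(np.abs(residuals)))
    scale = max(1.0, float(np.abs(base).max()))
    if diameter <= 1e-12 * scale:
        warnings.warn("stem base residuals are all zero; diameter is 0")
    return diameter


# ---------------------------------------------------------------------------
# Leaf instance separation and morphometry


def split_leaf_instances(
    positions: np.ndarray, cluster_factor: float = 3.0
) -> list[np.ndarray]:
    """Euclidean connected components with an adaptive distance threshold.

    The linking radius is ``cluster_factor`` times the median nearest
    neighbor spacing; returns index arrays, one per component.
    """
    n = len(positions)
    if n == 0:
        return []
    if n == 1:
        return [np.array([0])]
    tree = cKDTree(positions)
    nn_dist = tree.query(positions, k=2)[0][:, 1]
    radius = cluster_factor * float(np.median(nn_dist))
    pairs = tree.query_pairs(radius, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)
    return [np.flatnonzero(comp == c) for c in range(n_comp)]


def _axis_deterministic(points: np.ndarray) -> np.ndarray:
    """Principal axis with a deterministic sign (positive dominant entry)."""
    axis = _principal_axis(points)
    j = int(np.argmax(np.abs(axis)))
    if axis[j] < 0:
        axis = -axis
    return axis


def leaf_segments(positions: np.ndarray, n_segments: int) -> list[np.ndarray]:
    """Slice a leaf into segments of equal extent along its principal vector.

    Returns index arrays ordered along the projection; empty slices are
    merged into their neighbors, so fewer than ``n_segments`` segments can
    come back for very uneven clouds.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if len(positions) < n_segments:
        raise ValueError(
            f"{len(positions)} points cannot fill {n_segments} segments"
        )
    axis = _axis_deterministic(positions)
    proj = positions @ axis
    edges = np.linspace(proj.min(), proj.max(), n_segments + 1)
    bins = np.clip(np.digitize(proj, edges[1:-1]), 0, n_segments - 1)
    segments = [np.flatnonzero(bins == b) for b in range(n_segments)]
    return [s for s in segments if len(s) > 0]


def _snap(targets: np.ndarray, cloud_points: np.ndarray) -> np.ndarray:
    """Nearest cloud point for each target (ties resolved to lowest index)."""
    _, idx = cKDTree(cloud_points).query(targets)
    return cloud_points[np.atleast_1d(idx)]


def segment_width_polyline(points: np.ndarray, m_insert: int = 20) -> Polyline:
    """Width polyline across one segment.

    The extreme points along the segment's principal vector are joined by a
    chord; ``m_insert`` uniformly spaced interior chord points are snapped
    onto the cloud so the polyline follows an arched cross-section.
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 2:
        raise ValueError("a segment needs at least 2 points")
    axis = _axis_deterministic(points)
    proj = points @ axis
    start = points[int(np.argmin(proj))]
    end = points[int(np.argmax(proj))]
    verts = [start]
    if m_insert > 0:
        t = np.linspace(0.0, 1.0, m_insert + 2)[1:-1, None]
        chord = start[None, :] * (1 - t) + end[None, :] * t
        verts.extend(_snap(chord, points))
    verts.append(end)
    return Polyline(np.asarray(verts), role="width")


def leaf_length_polyline(
    segments: list[np.ndarray], leaf_positions: np.ndarray
) -> Polyline:
    """Length polyline along the leaf.

    For each segment the midpoint of its two extreme points (along the
    segment's principal vector) is snapped onto the full leaf cloud; the
    chain of midpoints is bracketed by the leaf's global extreme points
    along its principal vector, so base and tip are included.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    leaf_positions = np.asarray(leaf_positions, dtype=np.float64)
    mids = []
    for seg_idx in segments:
        pts = leaf_positions[seg_idx]
        axis = _axis_deterministic(pts)
        proj = pts @ axis
        mid = 0.5 * (pts[int(np.argmin(proj))] + pts[int(np.argmax(proj))])
        mids.append(mid)
    mids = _snap(np.asarray(mids), leaf_positions)
    global_axis = _axis_deterministic(leaf_positions)
    gproj = leaf_positions @ global_axis
    base = leaf_positions[int(np.argmin(gproj))]
    tip = leaf_positions[int(np.argmax(gproj))]
    verts = np.vstack([base, mids, tip])
    return Polyline(verts, role="length")


def gaussian_smooth_polyline(polyline: Polyline, sigma: float = 1.0) -> Polyline:
    """1-D Gaussian filtering of each coordinate sequence (reflect boundary).

    The first and last vertices are the measured extreme points and are kept
    fixed; smoothing removes undulation of the interior chain only.
    """
    if sigma <= 0:
        return Polyline(polyline.vertices.copy(), role=polyline.role, smoothed=False)
    if len(polyline.vertices) < 3:
        return Polyline(polyline.vertices.copy(), role=polyline.role, smoothed=True)
    smoothed = np.column_stack(
        [
            gaussian_filter1d(polyline.vertices[:, i], sigma, mode="reflect")
            for i in range(3)
        ]
    )
    smoothed[0] = polyline.vertices[0]
    smoothed[-1] = polyline.vertices[-1]
    return Polyline(smoothed, role=polyline.role, smoothed=True)


# ---------------------------------------------------------------------------
# Full report


def _leaf_attachment_z(leaf_points: np.ndarray, stem_points: np.ndarray) -> float:
    """z of the leaf point closest to the stem (attachment height proxy)."""
    if len(stem_points) == 0:
        return float(leaf_points[:, 2].min())
    d, _ = cKDTree(stem_points).query(leaf_points)
    return float(leaf_points[int(np.argmin(d)), 2])


def extract_traits(
    cloud: LabeledPointCloud, params: TraitParams | None = None
) -> TraitReport:
    """Measure stem height/diameter and per-leaf length/width.

    Leaves are separated by Euclidean connected components and reported in
    order of attachment height (z of the point nearest the stem).  Missing
    classes yield a partial report with the corresponding fields ``None``
    or an empty leaf list.
    """
    params = params or TraitParams()
    if cloud.labels is None:
        raise ValueError("trait extraction needs labels")
    have_stem = np.any(cloud.labels == params.stem_label)
    have_leaf = np.any(cloud.labels == params.leaf_label)
    if have_stem:
        aligned, R = align_stem_to_z(cloud, params.stem_label)
        height = stem_height(aligned, params.stem_label)
        diameter = stem_diameter(aligned, params.stem_label)
    else:
        warnings.warn("no stem points; skipping alignment and stem traits")
        aligned, R = cloud, np.eye(3)
        height = diameter = None
    leaves: list[LeafMeasurement] = []
    if have_leaf:
        leaf_positions = aligned.positions[aligned.labels == params.leaf_label]
        stem_positions = (
            aligned.positions[aligned.labels == params.stem_label]
            if have_stem
            else np.zeros((0, 3))
        )
        instances = [
            idx
            for idx in split_leaf_instances(leaf_positions, params.cluster_factor)
            if len(idx) >= params.min_leaf_points
        ]
        instances.sort(
            key=lambda idx: _leaf_attachment_z(leaf_positions[idx], stem_positions)
        )
        for leaf_id, idx in enumerate(instances):
            pts = leaf_positions[idx]
            segs = leaf_segments(pts, min(params.n_segments, max(2, len(pts) // 2)))
            widths = [
                gaussian_smooth_polyline(
                    segment_width_polyline(pts[s], params.m_insert), params.sigma
                )
                for s in segs
                if len(s) >= 2
            ]
            width_poly = max(widths, key=lambda p: p.length)
            length_poly = gaussian_smooth_polyline(
                leaf_length_polyline(segs, pts), params.sigma
            )
            leaves.append(
                LeafMeasurement(
                    leaf_id=leaf_id,
                    length=length_poly.length,
                    width=width_poly.length,
                    length_polyline=length_poly,
                    width_polyline=width_poly,
                )
            )
    return TraitReport(
        stem_height=height,
        stem_diameter=diameter,
        leaves=leaves,
        alignment_rotation=R,
    )


def r2_rmse(measured, predicted) -> tuple[float, float]:
    """Coefficient of determination and root-mean-square error.

    R^2 = 1 - sum((v - vhat)^2) / sum((v - vbar)^2);
    RMSE = sqrt(mean((v - vhat)^2)).
    """
    v = np.asarray(measured, dtype=np.float64).ravel()
    vhat = np.asarray(predicted, dtype=np.float64).ravel()
    if v.shape != vhat.shape or len(v) == 0:
        raise ValueError("measured and predicted must have equal nonzero length")
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for a constant measured vector")
    ss_res = float(np.sum((v - vhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((v - vhat) ** 2)))
    return r2, rmse
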