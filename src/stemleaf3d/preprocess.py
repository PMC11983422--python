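"""Point-cloud I/O and preprocessing.

Implements the four preprocessing measures applied to raw plant clouds before
segmentation: color-threshold ground removal (Otsu on a vegetation index),
statistical outlier filtering, farthest point sampling, and PCA normal
estimation, plus centering/normalization and PLY / whitespace-text I/O.

Coordinates are treated as z-up throughout; the trait-extraction code relies
on this convention.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

__all__ = [
    "LabeledPointCloud",
    "TransformRecord",
    "read_point_cloud",
    "write_point_cloud",
    "otsu_ground_removal",
    "statistical_outlier_removal",
    "farthest_point_sampling",
    "estimate_normals",
    "center_normalize",
]


@dataclass
class LabeledPointCloud:
    """Positions with optional per-point normals, colors and integer labels.

    ``color_dialect`` records whether colors are stored on the unit scale
    (max value <= 1) or as 0..255 bytes.  All optional channels stay aligned
    with their point through every operation in this module.
    """

    positions: np.ndarray
    normals: np.ndarray | None = None
    colors: np.ndarray | None = None
    labels: np.ndarray | None = None
    frame: str = "z-up"
    color_dialect: str = "byte"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        n = len(self.positions)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(n, 3)
            norms = np.linalg.norm(self.normals, axis=1)
            bad = np.abs(norms - 1.0) > 1e-6
            if bad.any():
                nz = norms > 0
                self.normals[nz] /= norms[nz, None]
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64).reshape(n, 3)
            if self.colors.max(initial=0.0) <= 1.0:
                self.color_dialect = "unit"
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(n)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def select(self, indices) -> "LabeledPointCloud":
        """Subset or reorder points; every channel follows its point."""
        indices = np.asarray(indices)
        return LabeledPointCloud(
            positions=self.positions[indices],
            normals=None if self.normals is None else self.normals[indices],
            colors=None if self.colors is None else self.colors[indices],
            labels=None if self.labels is None else self.labels[indices],
            frame=self.frame,
            color_dialect=self.color_dialect,
        )

    def with_positions(self, positions: np.ndarray) -> "LabeledPointCloud":
        return replace(self, positions=np.asarray(positions, dtype=np.float64))

    def colors_as_bytes(self) -> np.ndarray:
        if self.colors is None:
            raise ValueError("cloud has no colors")
        if self.color_dialect == "unit":
            return self.colors * 255.0
        return self.colors


@dataclass
class TransformRecord:
    """Record of a center-and-scale normalization; supports exact inversion."""

    centroid: np.ndarray
    scale: float

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return (positions - self.centroid) / self.scale

    def invert(self, positions: np.ndarray) -> np.ndarray:
        return positions * self.scale + self.centroid


# ---------------------------------------------------------------------------
# I/O
#
# Accepted whitespace-text layouts (columns):
#   3  -> x y z
#   6  -> x y z nx ny nz
#   7  -> x y z r g b label
#   9  -> x y z nx ny nz r g b
#   10 -> x y z nx ny nz r g b label
_TXT_LAYOUTS = {
    3: ("xyz",),
    6: ("xyz", "normals"),
    7: ("xyz", "colors", "label"),
    9: ("xyz", "normals", "colors"),
    10: ("xyz", "normals", "colors", "label"),
}

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "txt" if path.suffix.lower() in {".txt", ".xyz", ".pts"} else "ply"


def read_point_cloud(path, format: str | None = None) -> LabeledPointCloud:
    """Read a PLY (ascii or binary-little-endian) or whitespace-text cloud."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = _infer_format(path, format)
    if fmt == "txt":
        return _read_txt(path)
    if fmt == "ply":
        return _read_ply(path)
    raise ValueError(f"unknown format {fmt!r} (expected 'ply' or 'txt')")


def _layout_from_names(names: list[str]):
    layout = []
    if names[:3] == ["x", "y", "z"]:
        layout.append("xyz")
        names = names[3:]
    else:
        return None
    while names:
        if names[:3] == ["nx", "ny", "nz"]:
            layout.append("normals")
            names = names[3:]
        elif names[:3] in (["r", "g", "b"], ["red", "green", "blue"]):
            layout.append("colors")
            names = names[3:]
        elif names[0] == "label":
            layout.append("label")
            names = names[1:]
        else:
            return None
    return tuple(layout)


def _read_txt(path: Path) -> LabeledPointCloud:
    rows = []
    ncols = None
    declared = None  # layout from a "# columns: ..." header comment
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("columns:"):
                    declared = _layout_from_names(body.split(":", 1)[1].split())
                continue
            if not line:
                continue
            parts = line.split()
            if ncols is None:
                ncols = len(parts)
                if declared is None and ncols not in _TXT_LAYOUTS:
                    raise ValueError(
                        f"unsupported column count {ncols} in {path.name}; "
                        f"accepted layouts: {sorted(_TXT_LAYOUTS)} "
                        "(x y z [nx ny nz] [r g b] [label])"
                    )
            if len(parts) != ncols:
                raise ValueError(
                    f"malformed row at line {lineno} of {path.name}: "
                    f"expected {ncols} columns, found {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(
                    f"malformed row at line {lineno} of {path.name}: {exc}"
                ) from None
    if not rows:
        raise ValueError(f"{path.name} contains no points")
    arr = np.asarray(rows, dtype=np.float64)
    layout = declared if declared is not None else _TXT_LAYOUTS[ncols]
    col = 0
    fields: dict = {}
    for name in layout:
        if name == "xyz":
            fields["positions"] = arr[:, col : col + 3]
            col += 3
        elif name == "normals":
            fields["normals"] = arr[:, col : col + 3]
            col += 3
        elif name == "colors":
            fields["colors"] = arr[:, col : col + 3]
            col += 3
        elif name == "label":
            fields["labels"] = arr[:, col].astype(np.int64)
            col += 1
    return LabeledPointCloud(**fields)


def _read_ply(path: Path) -> LabeledPointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path.name} is not a PLY file")
        fmt = None
        n_vertices = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path.name}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertices = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ValueError("list properties on vertices are not supported")
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in {"ascii", "binary_little_endian"}:
            raise ValueError(f"unsupported PLY format {fmt!r}")
        if n_vertices is None:
            raise ValueError(f"{path.name}: no vertex element")
        dtype = np.dtype([(name, "<" + _PLY_DTYPES[t]) for name, t in props])
        if fmt == "binary_little_endian":
            data = np.frombuffer(fh.read(dtype.itemsize * n_vertices), dtype=dtype)
        else:
            raw = np.loadtxt(fh, max_rows=n_vertices, ndmin=2)
            data = np.zeros(n_vertices, dtype=dtype)
            for i, (name, _) in enumerate(props):
                data[name] = raw[:, i]
    names = {name for name, _ in props}
    positions = np.stack([data["x"], data["y"], data["z"]], axis=1).astype(np.float64)
    normals = None
    if {"nx", "ny", "nz"} <= names:
        normals = np.stack([data["nx"], data["ny"], data["nz"]], axis=1)
    colors = None
    for triple in (("red", "green", "blue"), ("r", "g", "b")):
        if set(triple) <= names:
            colors = np.stack([data[c] for c in triple], axis=1).astype(np.float64)
            break
    labels = None
    for lab in ("label", "scalar_label", "class"):
        if lab in names:
            labels = data[lab].astype(np.int64)
            break
    return LabeledPointCloud(
        positions=positions, normals=normals, colors=colors, labels=labels
    )


def write_point_cloud(cloud: LabeledPointCloud, path, format: str | None = None) -> Path:
    """Write a cloud as binary-little-endian PLY (default) or text.

    Positions (and normals) are stored as doubles so reads round-trip them
    bit-exactly.  Text output uses 6-significant-digit floats.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "txt":
            _write_txt(cloud, path)
        elif fmt == "ply":
            _write_ply(cloud, path)
        else:
            raise ValueError(f"unknown format {fmt!r} (expected 'ply' or 'txt')")
    except OSError as exc:
        raise OSError(f"cannot write point cloud to {path}: {exc}") from exc
    return path


def _write_txt(cloud: LabeledPointCloud, path: Path) -> None:
    cols = [cloud.positions]
    names = ["x", "y", "z"]
    if cloud.normals is not None:
        cols.append(cloud.normals)
        names += ["nx", "ny", "nz"]
    if cloud.colors is not None:
        cols.append(cloud.colors)
        names += ["r", "g", "b"]
    fmt = ["%.6g"] * sum(c.shape[1] for c in cols)
    arr = np.concatenate(cols, axis=1)
    if cloud.labels is not None:
        arr = np.concatenate([arr, cloud.labels[:, None].astype(np.float64)], axis=1)
        fmt.append("%d")
        names.append("label")
    # the header makes layouts that share a column count unambiguous
    np.savetxt(path, arr, fmt=" ".join(fmt).split(),
               header="columns: " + " ".join(names))


def _write_ply(cloud: LabeledPointCloud, path: Path) -> None:
    fields: list[tuple[str, str, np.ndarray]] = []
    for i, name in enumerate("xyz"):
        fields.append((name, "double", cloud.positions[:, i]))
    if cloud.normals is not None:
        for i, name in enumerate(("nx", "ny", "nz")):
            fields.append((name, "double", cloud.normals[:, i]))
    if cloud.colors is not None:
        if cloud.color_dialect == "byte":
            col = np.clip(np.rint(cloud.colors), 0, 255).astype(np.uint8)
            ctype = "uchar"
        else:
            col = cloud.colors.astype(np.float32)
            ctype = "float"
        for i, name in enumerate(("red", "green", "blue")):
            fields.append((name, ctype, col[:, i]))
    if cloud.labels is not None:
        fields.append(("label", "int", cloud.labels.astype(np.int32)))
    dtype = np.dtype([(name, "<" + _PLY_DTYPES[t]) for name, t, _ in fields])
    rec = np.zeros(len(cloud), dtype=dtype)
    for name, _, arr in fields:
        rec[name] = arr
    header = ["ply", "format binary_little_endian 1.0",
              f"element vertex {len(cloud)}"]
    header += [f"property {t} {name}" for name, t, _ in fields]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# Preprocessing operations


def _color_scalar(cloud: LabeledPointCloud, scalar) -> np.ndarray:
    colors = cloud.colors_as_bytes()
    if scalar == "exg":
        r, g, b = colors[:, 0], colors[:, 1], colors[:, 2]
        v = 2.0 * g - r - b  # excess green vegetation index
    elif scalar == "gray":
        v = colors.mean(axis=1)
    elif isinstance(scalar, (int, np.integer)):
        v = colors[:, int(scalar)]
    else:
        raise ValueError(f"unknown scalar {scalar!r}: use 'exg', 'gray' or a channel index")
    lo, hi = v.min(), v.max()
    if hi > lo:  # rescale to the 0..255 histogram range
        v = (v - lo) * (255.0 / (hi - lo))
    return v


def otsu_ground_removal(cloud: LabeledPointCloud, scalar="exg") -> LabeledPointCloud:
    """Drop ground points by Otsu-thresholding a color scalar.

    A 256-bin histogram of the chosen scalar (default: excess green, 2G-R-B,
    rescaled to [0, 255]) is thresholded at the value maximizing between-class
    variance; the higher-scalar (plant) side is retained.
    """
    if cloud.colors is None:
        raise ValueError("otsu_ground_removal requires colors")
    values = _color_scalar(cloud, scalar)
    if np.ptp(values) == 0:
        warnings.warn("color scalar is constant; Otsu threshold undefined, cloud unchanged")
        return cloud.select(np.arange(len(cloud)))
    thr = threshold_otsu(values, nbins=256)
    keep = values > thr
    if keep.all() or not keep.any():
        warnings.warn("Otsu produced an empty class; cloud returned unchanged")
        return cloud.select(np.arange(len(cloud)))
    return cloud.select(np.flatnonzero(keep))


def statistical_outlier_removal(
    cloud: LabeledPointCloud, k: int = 16, alpha: float = 2.0
) -> LabeledPointCloud:
    """Remove points whose mean k-NN distance exceeds mean + alpha * sd."""
    n = len(cloud)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the point count {n}")
    tree = cKDTree(cloud.positions)
    dists, _ = tree.query(cloud.positions, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)  # drop the self-match
    thr = mean_d.mean() + alpha * mean_d.std()
    keep = mean_d <= thr
    return cloud.select(np.flatnonzero(keep))


def farthest_point_sampling(cloud, m: int, start: int = 0, rng=None) -> np.ndarray:
    """Greedy max-min farthest point sampling; returns indices in selection order.

    ``start`` is the first selected index; pass ``rng`` (a numpy Generator) to
    draw it at random instead.
    """
    positions = cloud.positions if isinstance(cloud, LabeledPointCloud) else np.asarray(cloud)
    n = len(positions)
    if not 1 <= m <= n:
        raise ValueError(f"m={m} must be between 1 and the point count {n}")
    if rng is not None:
        start = int(rng.integers(n))
    from ._fast import fps_indices

    return fps_indices(positions, m, int(start))


def estimate_normals(cloud: LabeledPointCloud, k: int = 16) -> LabeledPointCloud:
    """Estimate unit normals from the k-NN covariance eigenvector.

    The normal of each point is the eigenvector of the smallest eigenvalue of
    its neighborhood covariance, oriented to a positive z-component (positive
    x breaks ties).  Degenerate (collinear) neighborhoods get (0, 0, 1).
    """
    n = len(cloud)
    if k < 3:
        raise ValueError("k must be >= 3")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the point count {n}")
    tree = cKDTree(cloud.positions)
    _, idx = tree.query(cloud.positions, k=k + 1)
    nbrs = cloud.positions[idx]  # (N, k+1, 3), includes the point itself
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k + 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    normals = eigvecs[:, :, 0].copy()
    # rank < 2 neighborhoods: middle eigenvalue vanishes relative to largest
    degenerate = eigvals[:, 1] <= 1e-12 * np.maximum(eigvals[:, 2], 1e-300)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} degenerate neighborhoods; normal set to (0,0,1)"
        )
        normals[degenerate] = [0.0, 0.0, 1.0]
    flip = (normals[:, 2] < 0) | ((normals[:, 2] == 0) & (normals[:, 0] < 0))
    normals[flip] *= -1.0
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norms, out=np.zeros_like(normals), where=norms > 0)
    normals[(norms == 0).ravel()] = [0.0, 0.0, 1.0]
    return replace(cloud, normals=normals)


def center_normalize(cloud: LabeledPointCloud) -> tuple[LabeledPointCloud, TransformRecord]:
    """Subtract the centroid and divide by the max point norm (unit sphere)."""
    centroid = cloud.positions.mean(axis=0)
    centered = cloud.positions - centroid
    scale = float(np.linalg.norm(centered, axis=1).max())
    if scale == 0.0:
        warnings.warn("all points coincident; normalization scale set to 1")
        scale = 1.0
    record = TransformRecord(centroid=centroid, scale=scale)
    return cloud.with_positions(centered / scale), record
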