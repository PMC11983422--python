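"""PointSegNet: a lightweight encoder-decoder point-cloud segmentation network.

The encoder is four Global-Local Set Abstraction (GLSA) stages.  Each stage
halves the point count by farthest point sampling, then runs two branches on
the kept points: a local branch (ResMLP: ball-query grouping, a two-layer
shared MLP, max-pooling, a residual shortcut) and a global branch (Relative
Spatial Attention: coordinates and features are centered on their means,
concatenated, pushed through an MLP and a sigmoid to produce per-point
attention weights).  A learnable scalar gate fuses the branches, and a
channel attention with pooled mean/sd statistics (CAM-SE) re-weights the
channels.  The decoder mirrors the encoder with four Edge-Aware Feature
Propagation (EAFP) stages: inverse-distance interpolation to the skip
resolution, skip fusion, a pointwise ResMLP, and a KNN edge term
(mean over ReLU-rectified neighbor feature differences).  A two-layer head
emits per-point class scores.

Every block can be switched off independently (``ablation`` flags), which
reproduces the published ablation variants; removing a block also removes
its parameters, so parameter-count orderings across variants are meaningful.

The network runs on the numpy autodiff engine in :mod:`stemleaf3d.autodiff`.
Geometry (sampling, neighbor search, interpolation weights) is computed with
numpy/scipy and does not carry gradients; features do.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .autodiff import AdamW, BatchNorm, Linear, Module, Tensor, concat, gather
from .preprocess import farthest_point_sampling

__all__ = [
    "ModelConfig",
    "PointBatch",
    "ball_query_knn",
    "knn_indices",
    "interpolation_weights",
    "interpolate_features",
    "ResMLPBlock",
    "RSAAttention",
    "CAMSE",
    "GLSAStage",
    "EAFPStage",
    "PointSegNet",
    "pointsegnet_forward",
    "count_parameters",
    "count_flops",
    "reference_config",
    "tiny_config",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters and ablation switches.

    ``stage_widths`` are the four encoder output widths, ``decoder_widths``
    the four decoder output widths ordered deepest-first, so
    ``decoder_widths[-1]`` is the width entering the head.  ``ball_radius``
    is the stage-1 ball-query radius on the unit-normalized cloud; it doubles
    at each deeper stage.
    """

    in_channels: int = 6
    num_classes: int = 2
    npoints: int = 2048
    stem_width: int = 32
    stage_widths: tuple = (64, 128, 256, 512)
    decoder_widths: tuple = (256, 128, 64, 64)
    head_width: int = 64
    fps_rate: float = 0.5
    local_k: int = 32
    ball_radius: float = 0.1
    eafp_k: int = 16
    ablation: dict = field(
        default_factory=lambda: {"rsa": True, "cam_se": True, "eafp": True, "resmlp": True}
    )

    def __post_init__(self):
        if not 0.0 < self.fps_rate <= 1.0:
            raise ValueError("fps_rate must lie in (0, 1]")
        if self.eafp_k < 1 or self.local_k < 1:
            raise ValueError("neighbor counts must be >= 1")
        if any(w <= 0 for w in tuple(self.stage_widths) + tuple(self.decoder_widths)):
            raise ValueError("widths must be positive")
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        self.decoder_widths = tuple(int(w) for w in self.decoder_widths)
        flags = {"rsa": True, "cam_se": True, "eafp": True, "resmlp": True}
        flags.update(self.ablation)
        self.ablation = flags

    def to_yaml(self) -> str:
        d = asdict(self)
        d["stage_widths"] = list(self.stage_widths)
        d["decoder_widths"] = list(self.decoder_widths)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        d = yaml.safe_load(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PointBatch:
    """Batched positions + features with the encoder trace for skips."""

    positions: np.ndarray  # (B, N, 3)
    features: Tensor  # (B, N, C)
    stage_trace: list = field(default_factory=list)


def _canonical_start(points: np.ndarray) -> int:
    """Lexicographically smallest point: a permutation-invariant FPS start."""
    return int(np.lexsort((points[:, 2], points[:, 1], points[:, 0]))[0])


def ball_query_knn(
    centers: np.ndarray, points: np.ndarray, k: int, radius: float
) -> np.ndarray:
    """Indices of the k nearest points within ``radius`` of each center.

    Shortfalls are padded by repeating the nearest point found (which is the
    center itself when the centers are a subset of ``points``), so the
    returned grid always has shape (n_centers, k).
    """
    if k < 1 or radius <= 0:
        raise ValueError("require k >= 1 and radius > 0")
    n = len(points)
    kq = min(k, n)
    tree = cKDTree(points)
    dist, idx = tree.query(centers, k=kq)
    dist = np.atleast_2d(dist.reshape(len(centers), kq))
    idx = np.atleast_2d(idx.reshape(len(centers), kq))
    if kq < k:  # fewer points than neighbors requested: repeat the nearest
        pad = k - kq
        dist = np.concatenate([dist, np.repeat(dist[:, :1], pad, axis=1)], axis=1)
        idx = np.concatenate([idx, np.repeat(idx[:, :1], pad, axis=1)], axis=1)
    outside = dist > radius
    idx = np.where(outside, idx[:, :1], idx)
    return idx


def knn_indices(query: np.ndarray, points: np.ndarray, k: int) -> np.ndarray:
    """Plain k nearest neighbors (k clamped to the point count)."""
    kq = min(k, len(points))
    _, idx = cKDTree(points).query(query, k=kq)
    return np.atleast_2d(idx.reshape(len(query), kq))


def interpolation_weights(
    fine_positions: np.ndarray, coarse_positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """3-NN inverse-distance interpolation stencil from coarse to fine."""
    kq = min(3, len(coarse_positions))
    dist, idx = cKDTree(coarse_positions).query(fine_positions, k=kq)
    dist = dist.reshape(len(fine_positions), kq)
    idx = idx.reshape(len(fine_positions), kq)
    w = 1.0 / (dist + 1e-8)
    w = w / w.sum(axis=1, keepdims=True)
    return idx, w


def interpolate_features(
    coarse_positions: np.ndarray,
    coarse_features,
    fine_positions: np.ndarray,
):
    """Inverse-distance-weighted 3-NN feature interpolation (single cloud).

    Accepts a plain ndarray or an autodiff Tensor for the features.
    """
    idx, w = interpolation_weights(fine_positions, coarse_positions)
    if isinstance(coarse_features, Tensor):
        g = gather(coarse_features.reshape(1, *coarse_features.shape), idx[None])
        return (g * Tensor(w[None, :, :, None])).sum(axis=2).reshape(len(fine_positions), -1)
    return np.einsum("nk,nkc->nc", w, coarse_features[idx])


# ---------------------------------------------------------------------------
# Blocks


class ResMLPBlock(Module):
    """Grouped two-layer shared MLP with max-pool and residual shortcut.

    Input: grouped neighborhood features (B, m, k, C_in + 3) (relative
    coordinates prepended) and center features (B, m, C_in).  Output is
    (B, m, C_out).  ``residual=False`` removes the shortcut (the set
    abstraction ablation variant).
    """

    def __init__(self, c_in: int, c_out: int, rng, residual: bool = True):
        self.conv1 = Linear(c_in + 3, c_out, rng)
        self.bn1 = BatchNorm(c_out)
        self.conv2 = Linear(c_out, c_out, rng)
        self.bn2 = BatchNorm(c_out)
        self.residual = residual
        if residual:
            self.shortcut = Linear(c_in, c_out, rng)

    def __call__(self, grouped: Tensor, center_features: Tensor) -> Tensor:
        h = self.bn1(self.conv1(grouped)).relu()
        h = self.bn2(self.conv2(h))
        pooled = h.max(axis=2)
        if self.residual:
            pooled = pooled + self.shortcut(center_features)
        return pooled.relu()


class RSAAttention(Module):
    """Relative Spatial Attention: attention from mean-centered coords+features.

    P and F are the deviations of coordinates and features from their means
    over the (downsampled) cloud; a sigmoid MLP of [P, F] gates the input
    features, and a second MLP projects to the stage width.
    """

    def __init__(self, c_in: int, c_out: int, rng):
        self.mlp1a = Linear(c_in + 3, c_in, rng)
        self.mlp1b = Linear(c_in, c_in, rng)
        self.mlp2 = Linear(c_in, c_out, rng)
        self.bn = BatchNorm(c_out)

    def __call__(self, positions: np.ndarray, features: Tensor) -> Tensor:
        P = positions - positions.mean(axis=1, keepdims=True)
        F = features - features.mean(axis=1, keepdims=True)
        P = Tensor(P.astype(features.data.dtype))
        a = self.mlp1b(self.mlp1a(concat([P, F], axis=-1)).relu()).sigmoid()
        return self.bn(self.mlp2(features * a)).relu()


class CAMSE(Module):
    """Channel attention from pooled per-channel mean and sd statistics.

    u_c and sd_c are pooled over the points of each cloud; a per-channel
    weighted sum of [u_c, sd_c] is batch-normalized and squashed to a gate
    g in (0,1), and the output is g*f + f.
    """

    eps = 1e-5

    def __init__(self, channels: int, rng):
        self.w_mean = Tensor(
            rng.normal(0.0, 1.0, channels).astype(np.float32), requires_grad=True
        )
        self.w_sd = Tensor(
            rng.normal(0.0, 1.0, channels).astype(np.float32), requires_grad=True
        )
        self.bias = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.bn = BatchNorm(channels)

    def __call__(self, features: Tensor) -> Tensor:
        u = features.mean(axis=1)  # (B, C)
        centered = features - u.reshape(u.shape[0], 1, u.shape[1])
        sd = ((centered * centered).mean(axis=1) + self.eps).sqrt()
        s = u * self.w_mean + sd * self.w_sd + self.bias
        g = self.bn(s).sigmoid()  # (B, C)
        g = g.reshape(g.shape[0], 1, g.shape[1])
        return features * g + features


class GLSAStage(Module):
    """One encoder stage: FPS, local ResMLP, global RSA, gated fusion, CAM-SE."""

    def __init__(self, c_in: int, c_out: int, config: ModelConfig, stage_index: int, rng):
        self.c_in = c_in
        self.c_out = c_out
        self.k = config.local_k
        self.radius = config.ball_radius * (2.0**stage_index)
        self.fps_rate = config.fps_rate
        self.use_rsa = config.ablation["rsa"]
        self.use_cam = config.ablation["cam_se"]
        self.local = ResMLPBlock(c_in, c_out, rng, residual=config.ablation["resmlp"])
        if self.use_rsa:
            self.rsa = RSAAttention(c_in, c_out, rng)
            self.gate = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)
        if self.use_cam:
            self.cam = CAMSE(c_out, rng)

    def __call__(self, positions: np.ndarray, features: Tensor):
        B, N, _ = positions.shape
        m = math.ceil(N * self.fps_rate)
        if m < 1:
            raise ValueError("insufficient points for farthest point sampling")
        center_idx = np.stack(
            [
                farthest_point_sampling(positions[b], m, start=_canonical_start(positions[b]))
                for b in range(B)
            ]
        )
        centers = np.take_along_axis(positions, center_idx[:, :, None], axis=1)
        f_centers = gather(features, center_idx)
        nbr_idx = np.stack(
            [
                ball_query_knn(centers[b], positions[b], self.k, self.radius)
                for b in range(B)
            ]
        )
        rel = positions[np.arange(B)[:, None, None], nbr_idx] - centers[:, :, None, :]
        grouped = concat(
            [Tensor(rel.astype(features.data.dtype)), gather(features, nbr_idx)],
            axis=-1,
        )
        local = self.local(grouped, f_centers)
        if self.use_rsa:
            global_ = self.rsa(centers, f_centers)
            g = self.gate.sigmoid()
            fused = local * g + global_ * (1.0 - g)
        else:
            fused = local
        if self.use_cam:
            fused = self.cam(fused)
        return centers, fused


class EAFPStage(Module):
    """One decoder stage: interpolate, fuse skip, ResMLP, KNN edge term, MLP.

    With ``edge=False`` the stage degrades to classic feature propagation
    (interpolation, skip concat, two pointwise MLP layers).
    """

    def __init__(self, c_coarse: int, c_skip: int, c_out: int, config: ModelConfig, rng):
        c_cat = c_coarse + c_skip
        self.edge = config.ablation["eafp"]
        self.k = config.eafp_k
        self.conv1 = Linear(c_cat, c_out, rng)
        self.bn1 = BatchNorm(c_out)
        self.conv2 = Linear(c_out, c_out, rng)
        self.bn2 = BatchNorm(c_out)
        if self.edge:
            self.final = Linear(c_out, c_out, rng)
            self.bn3 = BatchNorm(c_out)

    def __call__(
        self,
        coarse_positions: np.ndarray,
        coarse_features: Tensor,
        skip_positions: np.ndarray,
        skip_features: Tensor,
    ) -> Tensor:
        B, Nf, _ = skip_positions.shape
        idx = np.empty((B, Nf, min(3, coarse_positions.shape[1])), dtype=np.int64)
        w = np.empty(idx.shape)
        for b in range(B):
            idx[b], w[b] = interpolation_weights(skip_positions[b], coarse_positions[b])
        up = (
            gather(coarse_features, idx)
            * Tensor(w[:, :, :, None].astype(coarse_features.data.dtype))
        ).sum(axis=2)
        h = concat([up, skip_features], axis=-1)
        if not self.edge:
            h = self.bn1(self.conv1(h)).relu()
            return self.bn2(self.conv2(h)).relu()
        h1 = self.bn1(self.conv1(h)).relu()
        h2 = (self.bn2(self.conv2(h1)) + h1).relu()  # identity residual
        k = min(self.k, Nf)
        knn = np.stack([knn_indices(skip_positions[b], skip_positions[b], k) for b in range(B)])
        e = (gather(h2, knn) - h2.reshape(B, Nf, 1, h2.shape[-1])).relu()
        h3 = h2 + e.mean(axis=2)
        return self.bn3(self.final(h3)).relu()


class SegmentationHead(Module):
    def __init__(self, c_in: int, width: int, num_classes: int, rng):
        self.fc1 = Linear(c_in, width, rng)
        self.bn = BatchNorm(width)
        self.fc2 = Linear(width, num_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.bn(self.fc1(x)).relu())


class PointSegNet(Module):
    """Stem MLP, four GLSA encoder stages, four EAFP decoder stages, head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        c = config.stem_width
        self.stem = Linear(config.in_channels, c, rng)
        self.stem_bn = BatchNorm(c)
        self.stages = []
        widths = [c] + list(config.stage_widths)
        for i in range(4):
            self.stages.append(GLSAStage(widths[i], widths[i + 1], config, i, rng))
        self.decoders = []
        dec = list(config.decoder_widths)
        coarse = widths[-1]
        # deepest decoder first: skip widths walk back down the encoder
        for i in range(4):
            skip = widths[3 - i]
            self.decoders.append(EAFPStage(coarse, skip, dec[i], config, rng))
            coarse = dec[i]
        self.head = SegmentationHead(dec[-1], config.head_width, config.num_classes, rng)

    def __call__(self, positions: np.ndarray, features) -> Tensor:
        positions = np.asarray(positions, dtype=np.float64)
        if positions.ndim == 2:
            positions = positions[None]
        feats = features if isinstance(features, Tensor) else Tensor(
            np.asarray(features, dtype=np.float32)
        )
        if feats.ndim == 2:
            feats = feats.reshape(1, *feats.shape)
        if feats.shape[-1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} feature channels "
                f"(xyz + normals by default), got {feats.shape[-1]}"
            )
        f = self.stem_bn(self.stem(feats)).relu()
        trace = [(positions, f)]
        pos = positions
        for stage in self.stages:
            pos, f = stage(pos, f)
            trace.append((pos, f))
        coarse_pos, coarse_f = trace[-1]
        for i, dec in enumerate(self.decoders):
            skip_pos, skip_f = trace[3 - i]
            coarse_f = dec(coarse_pos, coarse_f, skip_pos, skip_f)
            coarse_pos = skip_pos
        return self.head(coarse_f)


def pointsegnet_forward(positions, features, config: ModelConfig, seed: int = 0) -> np.ndarray:
    """Convenience one-shot forward pass returning a score ndarray."""
    model = PointSegNet(config, seed=seed)
    model.set_training(False)
    return model(positions, features).data


# ---------------------------------------------------------------------------
# Budgets


def count_parameters(config: ModelConfig) -> int:
    """Total learnable scalar count of the configured network."""
    model = PointSegNet(config, seed=0)
    return int(sum(p.data.size for p in model.parameters()))


def count_flops(config: ModelConfig, n_points: int | None = None) -> float:
    """Analytic floating-point operations of one forward pass (batch 1).

    Multiply-accumulates count as two operations.  Linear layers dominate;
    batch-norm, activations, attention gating, interpolation and the KNN
    edge term are included with their elementwise costs.  Neighbor-search
    index construction is combinatorial, not floating-point, and is not
    counted.  Returns raw operations (divide by 1e9 for G).
    """
    n = n_points or config.npoints

    def linear(rows, c_in, c_out):
        return rows * (2 * c_in * c_out + c_out)

    def bn_relu(rows, c):  # normalize+affine (4) + relu (1)
        return rows * 5 * c

    total = 0.0
    c = config.stem_width
    total += linear(n, config.in_channels, c) + bn_relu(n, c)
    widths = [c] + list(config.stage_widths)
    counts = [n]
    for i in range(4):
        counts.append(math.ceil(counts[-1] * config.fps_rate))
    k = config.local_k
    for i in range(4):
        c_in, c_out, m = widths[i], widths[i + 1], counts[i + 1]
        # local branch: grouped two-layer MLP on m*k positions
        total += linear(m * k, c_in + 3, c_out) + bn_relu(m * k, c_out)
        total += linear(m * k, c_out, c_out) + bn_relu(m * k, c_out)
        total += m * k * c_out  # max-pool comparisons
        if config.ablation["resmlp"]:
            total += linear(m, c_in, c_out) + m * c_out  # shortcut + add
        if config.ablation["rsa"]:
            total += m * (c_in + 3) * 2  # mean-centering of P and F
            total += linear(m, c_in + 3, c_in) + m * c_in  # mlp1a + relu
            total += linear(m, c_in, c_in) + 4 * m * c_in  # mlp1b + sigmoid
            total += m * c_in  # gating product
            total += linear(m, c_in, c_out) + bn_relu(m, c_out)
            total += 3 * m * c_out  # gated fusion
        if config.ablation["cam_se"]:
            total += m * c_out * 6  # pooled stats
            total += 4 * c_out + 10 * c_out  # per-channel gate
            total += 2 * m * c_out  # g*f + f
    dec = list(config.decoder_widths)
    coarse = widths[-1]
    for i in range(4):
        nf = counts[3 - i]
        skip = widths[3 - i]
        c_cat = coarse + skip
        total += nf * 3 * 2 * coarse  # 3-NN inverse-distance interpolation
        total += linear(nf, c_cat, dec[i]) + bn_relu(nf, dec[i])
        total += linear(nf, dec[i], dec[i]) + bn_relu(nf, dec[i])
        if config.ablation["eafp"]:
            total += nf * dec[i]  # identity-residual add
            ke = min(config.eafp_k, nf)
            total += nf * ke * dec[i] * 3  # edge differences, relu, mean
            total += nf * dec[i]  # residual add
            total += linear(nf, dec[i], dec[i]) + bn_relu(nf, dec[i])
        coarse = dec[i]
    total += linear(n, dec[-1], config.head_width) + bn_relu(n, config.head_width)
    total += linear(n, config.head_width, config.num_classes)
    return float(total)


# ---------------------------------------------------------------------------
# Frozen configurations


def _load_packaged_config(name: str) -> ModelConfig:
    from importlib.resources import files

    text = files("stemleaf3d").joinpath("configs", name).read_text()
    return ModelConfig.from_yaml(text)


def reference_config() -> ModelConfig:
    """The frozen reference architecture (see configs/reference.yaml)."""
    return _load_packaged_config("reference.yaml")


def tiny_config() -> ModelConfig:
    """Quarter-width configuration for desk-scale training runs."""
    return _load_packaged_config("tiny.yaml")


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(model: PointSegNet, path) -> None:
    """Serialize weights + config to an .npz container."""
    state = model.state_arrays()
    np.savez(path, __config__=np.frombuffer(
        model.config.to_yaml().encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> PointSegNet:
    data = np.load(path)
    config = ModelConfig.from_yaml(bytes(data["__config__"]).decode())
    model = PointSegNet(config, seed=0)
    model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    return model
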