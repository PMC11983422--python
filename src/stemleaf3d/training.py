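"""PolyFocal loss, augmentation, segmentation metrics and the training loop.

The loss is a focal loss with a polynomial correction term.  With p the
sigmoid activation of the score and y the one-hot label,

    P_t  = y*p + (1-y)*(1-p)
    L_CE = -[y*log p + (1-y)*log(1-p)]        (= -log P_t)
    L_FL = L_CE * (1-P_t)**gamma
    L    = mean( L_FL + eps * (1-P_t)**(gamma+1) )

gamma down-weights easy points (well-classified, P_t near 1), and the
epsilon-weighted polynomial term restores part of the gradient that focal
scaling removes near P_t = 1.  The loss is computed one-vs-rest per class
with a sigmoid, so the same form covers 2-class and 3-class plants.

Training follows a fixed protocol: AdamW (weight decay 1e-4), a multistep
schedule decaying the learning rate by 0.1 at epochs 210 and 270 of 300,
batch size 4, and augmentation by random scaling into [0.8, 1.2],
center-normalization, Gaussian jitter (sd 0.001 clipped at 0.005) and
farthest-point resampling to the model's input size.
"""

from __future__ import annotations

import copy
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import AdamW, Tensor
from .network import ModelConfig, PointSegNet
from .preprocess import LabeledPointCloud, center_normalize, farthest_point_sampling
from .synthetic import ToyDataset

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "poly_focal_loss",
    "augment",
    "confusion_counts",
    "segmentation_metrics",
    "learning_rate_at",
    "train_model",
    "cloud_features",
    "evaluate_model",
]


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 4
    optimizer: str = "adamw"
    weight_decay: float = 1e-4
    lr: float = 1e-3
    milestones: tuple = (210, 270)
    gamma_lr: float = 0.1
    points: int = 2048
    scale_range: tuple = (0.8, 1.2)
    jitter_sd: float = 0.001
    jitter_clip: float = 0.005
    gamma_focal: float = 2.0
    eps_poly: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.milestones = tuple(int(m) for m in self.milestones)
        self.scale_range = tuple(float(s) for s in self.scale_range)
        if any(m >= self.epochs for m in self.milestones):
            raise ValueError("milestones must precede the final epoch")
        if not self.scale_range[0] < self.scale_range[1]:
            raise ValueError("scale_range must be (low, high) with low < high")
        if self.jitter_clip < self.jitter_sd:
            raise ValueError("jitter_clip must be >= jitter_sd")


@dataclass
class ConfusionCounts:
    """One-vs-rest tallies per class; arrays indexed by class id."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def num_classes(self) -> int:
        return len(self.tp)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError("label outside [0, num_classes)")
    return np.eye(num_classes, dtype=np.float64)[labels]


def poly_focal_loss(scores, labels, gamma_focal: float = 2.0, eps_poly: float = 1.0):
    """PolyFocal loss, mean over points and classes.

    ``scores`` may be an autodiff Tensor (for training) or an ndarray (the
    value is then returned as a float).  ``labels`` are integer class ids or
    an already one-hot array aligned with the trailing score axis.
    """
    is_tensor = isinstance(scores, Tensor)
    s = scores if is_tensor else Tensor(np.asarray(scores, dtype=np.float64))
    labels = np.asarray(labels)
    if labels.shape == s.shape:
        y = labels.astype(np.float64)
    else:
        y = _one_hot(labels, s.shape[-1])
    p = s.sigmoid().clip(1e-7, 1.0 - 1e-7)
    y_t = Tensor(y.astype(s.data.dtype))
    p_t = y_t * p + (1.0 - y_t) * (1.0 - p)
    ce = -p_t.log()
    one_minus = 1.0 - p_t
    focal = ce * one_minus**gamma_focal
    loss = (focal + eps_poly * one_minus ** (gamma_focal + 1.0)).mean()
    return loss if is_tensor else float(loss.data)


def augment(
    cloud: LabeledPointCloud, config: TrainConfig, rng: np.random.Generator
) -> LabeledPointCloud:
    """Random scale, center-normalize, truncated jitter, FPS resample.

    Labels, colors and normals are untouched apart from following their
    point through resampling; jitter applies to positions only.
    """
    scale = rng.uniform(*config.scale_range)
    scaled = cloud.with_positions(cloud.positions * scale)
    normed, _ = center_normalize(scaled)
    jitter = np.clip(
        rng.normal(0.0, config.jitter_sd, normed.positions.shape),
        -config.jitter_clip,
        config.jitter_clip,
    )
    jittered = normed.with_positions(normed.positions + jitter)
    if len(jittered) != config.points:
        if len(jittered) < config.points:
            raise ValueError(
                f"cloud has {len(jittered)} points; cannot resample up to {config.points}"
            )
        idx = farthest_point_sampling(jittered, config.points, rng=rng)
        jittered = jittered.select(idx)
    return jittered


def confusion_counts(pred, true, num_classes: int) -> ConfusionCounts:
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction and truth must have equal length")
    for arr, name in ((pred, "pred"), (true, "true")):
        if arr.min(initial=0) < 0 or arr.max(initial=0) >= num_classes:
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    n = len(true)
    tp = np.zeros(num_classes, dtype=np.int64)
    fp = np.zeros(num_classes, dtype=np.int64)
    fn = np.zeros(num_classes, dtype=np.int64)
    tn = np.zeros(num_classes, dtype=np.int64)
    for c in range(num_classes):
        p = pred == c
        t = true == c
        tp[c] = np.sum(p & t)
        fp[c] = np.sum(p & ~t)
        fn[c] = np.sum(~p & t)
        tn[c] = n - tp[c] - fp[c] - fn[c]
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_ratio(num, den, absent):
    out = np.zeros(len(num), dtype=np.float64)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    out[~nz] = 1.0 * absent[~nz]
    return out


def segmentation_metrics(counts: ConfusionCounts) -> dict:
    """Per-class and macro-mean IoU, Precision, Recall, F1.

    A class absent from both prediction and truth scores 1 on every metric;
    a class predicted or present but never matched scores 0 on the ratios
    with empty denominators.
    """
    tp, fp, fn = (
        counts.tp.astype(np.float64),
        counts.fp.astype(np.float64),
        counts.fn.astype(np.float64),
    )
    absent = (tp + fp + fn) == 0  # class in neither pred nor truth
    precision = _safe_ratio(tp, tp + fp, absent)
    recall = _safe_ratio(tp, tp + fn, absent)
    f1 = np.where(
        absent,
        1.0,
        np.divide(
            2.0 * precision * recall,
            precision + recall,
            out=np.zeros_like(precision),
            where=(precision + recall) > 0,
        ),
    )
    iou = _safe_ratio(tp, tp + fp + fn, absent)
    return {
        "iou": iou,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "miou": float(iou.mean()),
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
    }


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Multistep schedule: lr * gamma_lr ** (#milestones reached)."""
    drops = sum(epoch >= m for m in config.milestones)
    return config.lr * config.gamma_lr**drops


def cloud_features(cloud: LabeledPointCloud, in_channels: int) -> np.ndarray:
    """Network input features: normalized xyz plus normals (zero-filled if absent)."""
    if in_channels == 3:
        return cloud.positions.astype(np.float32)
    normals = cloud.normals
    if normals is None:
        normals = np.zeros_like(cloud.positions)
    return np.concatenate([cloud.positions, normals], axis=1).astype(np.float32)


def _prepare_eval(cloud: LabeledPointCloud, points: int) -> LabeledPointCloud:
    normed, _ = center_normalize(cloud)
    if len(normed) != points:
        idx = farthest_point_sampling(normed, points, start=0)
        normed = normed.select(idx)
    return normed


def evaluate_model(model: PointSegNet, clouds, points: int, chunk: int = 8) -> dict:
    """Aggregate segmentation metrics of a model over held-out clouds."""
    model.set_training(False)
    preps = [_prepare_eval(c, points) for c in clouds]
    total = None
    for lo in range(0, len(preps), chunk):
        batch = preps[lo : lo + chunk]
        pos = np.stack([p.positions for p in batch])
        feats = np.stack(
            [cloud_features(p, model.config.in_channels) for p in batch]
        )
        scores = model(pos, feats).data
        pred = scores.argmax(axis=-1)
        true = np.stack([p.labels for p in batch])
        c = confusion_counts(pred, true, model.config.num_classes)
        total = c if total is None else total + c
    return segmentation_metrics(total)


def train_model(
    dataset: ToyDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    verbose: bool = False,
):
    """Train PointSegNet on a toy dataset; returns (model, history).

    The best-validation-mIoU weights are restored into the returned model.
    ``history`` is a list of per-epoch dicts (lr, train loss, val metrics).
    """
    train_clouds = [dataset.samples[i][0] for i in dataset.train_indices]
    val_clouds = [dataset.samples[i][0] for i in dataset.val_indices]
    if not train_clouds or not val_clouds:
        raise ValueError("both training and validation splits must be non-empty")
    rng = np.random.default_rng(train_config.seed)
    model = PointSegNet(model_config, seed=train_config.seed)
    opt = AdamW(
        model.parameters(),
        lr=train_config.lr,
        weight_decay=train_config.weight_decay,
    )
    history = []
    best = (-1.0, None)
    n_train = len(train_clouds)
    bs = train_config.batch_size
    for epoch in range(train_config.epochs):
        opt.lr = learning_rate_at(epoch, train_config)
        model.set_training(True)
        order = rng.permutation(n_train)
        losses = []
        t0 = time.time()
        for lo in range(0, n_train, bs):
            batch_ids = order[lo : lo + bs]
            pos, feats, labs = [], [], []
            for i in batch_ids:
                aug = augment(train_clouds[i], train_config, rng)
                pos.append(aug.positions)
                feats.append(cloud_features(aug, model_config.in_channels))
                labs.append(aug.labels)
            scores = model(np.stack(pos), np.stack(feats).astype(np.float32))
            loss = poly_focal_loss(
                scores,
                np.stack(labs),
                gamma_focal=train_config.gamma_focal,
                eps_poly=train_config.eps_poly,
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        metrics = evaluate_model(model, val_clouds, train_config.points)
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "val_miou": metrics["miou"],
            "val_iou": metrics["iou"].tolist(),
            "seconds": time.time() - t0,
        }
        history.append(entry)
        if metrics["miou"] > best[0]:
            best = (metrics["miou"], copy.deepcopy(model.state_arrays()))
        if verbose:
            print(
                f"epoch {epoch:3d} lr {opt.lr:.2e} "
                f"loss {entry['train_loss']:.4f} val mIoU {entry['val_miou']:.4f}"
            )
    if best[1] is not None:
        model.load_state_arrays(best[1])
    model.set_training(False)
    return model, history
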