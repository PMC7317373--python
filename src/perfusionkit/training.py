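"""Training harness shared by the four pipeline networks.

Defaults follow the original training recipe: batch size 32, Adam with
learning rate 1e-4, L2 weight 0.001 on convolution kernels only, dropout
0.5 on the fully-connected layers, early stopping on the validation metric
with a patience of 3000 iterations.  A ``desk`` preset scales the iteration
budget, batch size and learning rate down for CPU-scale phantom
experiments; the recipe values stay available as the ``paper`` preset.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import nn
from .core import PerfusionSeries

__all__ = [
    "AugmentRanges",
    "TrainConfig",
    "ArchSpec",
    "normalize_series",
    "normalize_stack",
    "augment",
    "build_model",
    "train_model",
    "NetworkModel",
    "TrainingLog",
    "paper_train_config",
    "desk_train_config",
]


@dataclass(frozen=True)
class AugmentRanges:
    """Half-widths of symmetric augmentation ranges (identity at zero)."""

    translation_px: float = 0.0
    rotation_deg: float = 0.0
    scale: float = 0.0
    intensity: float = 0.0
    noise_sd: float = 0.0

    @property
    def is_identity(self) -> bool:
        return all(
            v == 0 for v in (self.translation_px, self.rotation_deg, self.scale, self.intensity, self.noise_sd)
        )


@dataclass
class TrainConfig:
    batch_size: int = 32
    learning_rate: float = 1e-4
    l2_weight: float = 0.001  # convolution kernels only
    patience: int = 3000  # iterations without validation improvement
    dropout_p: float = 0.5  # fully-connected layers only
    max_iterations: int = 100_000
    eval_every: int = 100
    augment: AugmentRanges = field(default_factory=AugmentRanges)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def paper_train_config(**overrides) -> TrainConfig:
    """The original recipe with moderate on-the-fly augmentation."""
    cfg = TrainConfig(augment=AugmentRanges(8.0, 10.0, 0.1, 0.2, 0.02))
    return replace(cfg, **overrides)


def desk_train_config(**overrides) -> TrainConfig:
    """CPU-scale preset for phantom experiments."""
    cfg = TrainConfig(
        batch_size=16,
        learning_rate=1e-3,
        patience=200,
        max_iterations=500,
        eval_every=25,
        augment=AugmentRanges(2.0, 0.0, 0.03, 0.05, 0.01),
    )
    return replace(cfg, **overrides)


@dataclass(frozen=True)
class ArchSpec:
    """Architecture descriptor for the four network kinds.

    ``classifier_cnn`` / ``bbox_cnn``: four 3x3-conv + 2x2-pool + BN + ReLU
    blocks followed by two fully-connected layers.  ``unet_seg`` /
    ``unet_action``: U-Net with ``depth`` pooling levels and ``base``
    starting filters (sigmoid vs 4-way softmax output, applied by the loss).
    Channel widths are configuration, not contract.
    """

    kind: str
    in_channels: int = 1
    out_units: int = 2
    input_size: int = 256
    channels: tuple[int, ...] = (32, 64, 128, 256)
    fc_units: int = 256
    base: int = 32
    depth: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("classifier_cnn", "bbox_cnn", "unet_seg", "unet_action"):
            raise ValueError(f"unknown architecture kind {self.kind!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        return cls(**d)


def build_model(arch: ArchSpec, dropout_p: float = 0.5, rng: np.random.Generator | None = None):
    rng = rng or np.random.default_rng(0)
    if arch.kind in ("classifier_cnn", "bbox_cnn"):
        return nn.SimpleCNN(
            arch.in_channels,
            arch.out_units,
            arch.input_size,
            channels=arch.channels,
            fc_units=arch.fc_units,
            dropout_p=dropout_p,
            rng=rng,
        )
    out_ch = 1 if arch.kind == "unet_seg" else 4
    return nn.UNet(arch.in_channels, out_ch, base=arch.base, depth=arch.depth, rng=rng)


def normalize_series(series: PerfusionSeries) -> PerfusionSeries:
    """Min-max normalize to [0, 1] over the whole series (not per frame).

    A constant series maps to all zeros.
    """
    return series.with_frames(normalize_stack(series.frames))


def normalize_stack(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=np.float64)
    lo = frames.min()
    hi = frames.max()
    if hi <= lo:
        return np.zeros_like(frames)
    return (frames - lo) / (hi - lo)


def augment(
    image: np.ndarray,
    label: dict | None,
    rng: np.random.Generator,
    ranges: AugmentRanges,
) -> tuple[np.ndarray, dict | None]:
    """Apply one random spatial+intensity transform to an image and its labels.

    ``image`` is (H, W) or (C, H, W) in [0, 1].  ``label`` may contain
    ``mask`` (transformed nearest-neighbour), ``points`` ((K, 2) row/col,
    transformed through the same affine map) and any non-spatial entries
    (passed through).  Intensities are clipped back to [0, 1].
    """
    if ranges.is_identity:
        return image, label
    img = np.asarray(image, dtype=np.float64)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[None]
    h, w = img.shape[-2:]
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])

    t = rng.uniform(-ranges.translation_px, ranges.translation_px, size=2)
    ang = np.radians(rng.uniform(-ranges.rotation_deg, ranges.rotation_deg))
    s = 1.0 + rng.uniform(-ranges.scale, ranges.scale)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    fwd = s * rot  # content transform: p_out = fwd @ (p - c) + c + t
    inv = np.linalg.inv(fwd)
    offset = c - inv @ (c + t)

    out = np.stack([ndimage.affine_transform(ch, inv, offset=offset, order=1, mode="nearest") for ch in img])
    gain = 1.0 + rng.uniform(-ranges.intensity, ranges.intensity)
    out = out * gain
    if ranges.noise_sd > 0:
        out = out + rng.normal(0.0, ranges.noise_sd, out.shape)
    out = np.clip(out, 0.0, 1.0)
    if squeeze:
        out = out[0]

    new_label = None
    if label is not None:
        new_label = dict(label)
        if "mask" in label and label["mask"] is not None:
            new_label["mask"] = (
                ndimage.affine_transform(
                    np.asarray(label["mask"], dtype=np.float64), inv, offset=offset, order=0, mode="constant"
                )
                > 0.5
            )
        if "points" in label and label["points"] is not None:
            pts = np.asarray(label["points"], dtype=np.float64)
            new_label["points"] = (fwd @ (pts - c).T).T + c + t
    return out, new_label


class TrainingLog:
    """Per-iteration loss and periodic validation metric records."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, iteration: int, loss: float, val_metric: float | None = None) -> None:
        self.records.append({"iteration": iteration, "loss": loss, "val_metric": val_metric})

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("iteration,loss,val_metric\n")
        for r in self.records:
            vm = "" if r["val_metric"] is None else f"{r['val_metric']:.6f}"
            buf.write(f"{r['iteration']},{r['loss']:.6f},{vm}\n")
        return buf.getvalue()


_LOSSES = {
    "classifier_cnn": nn.softmax_cross_entropy,
    "unet_action": nn.softmax_cross_entropy,
    "bbox_cnn": nn.mse_loss,
    "unet_seg": nn.soft_dice_loss,
}


class NetworkModel:
    """A trained network plus its architecture metadata (checkpointable)."""

    def __init__(self, net, arch: ArchSpec, train_config: TrainConfig | None = None):
        self.net = net
        self.arch = arch
        self.train_config = train_config

    @property
    def input_size(self) -> int:
        return self.arch.input_size

    def predict(self, x: np.ndarray, chunk: int = 16) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = [self.net.forward(x[i : i + chunk], train=False) for i in range(0, len(x), chunk)]
        return np.concatenate(outs, axis=0)

    def save(self, path) -> None:
        meta = {"arch": self.arch.to_dict()}
        if self.train_config is not None:
            cfg = asdict(self.train_config)
            cfg["augment"] = asdict(self.train_config.augment)
            meta["train_config"] = cfg
        nn.save_checkpoint(path, self.net, meta)

    @classmethod
    def load(cls, path) -> "NetworkModel":
        meta, params, buffers = nn.load_checkpoint(path)
        arch = ArchSpec.from_dict(meta["arch"])
        net = build_model(arch, dropout_p=0.0)
        nn.restore_into(net, params, buffers)
        cfg = None
        if "train_config" in meta:
            d = dict(meta["train_config"])
            d["augment"] = AugmentRanges(**d["augment"])
            cfg = TrainConfig(**d)
        return cls(net, arch, cfg)


def _validation_metric(kind: str, model: NetworkModel, val_set) -> float:
    x, y = val_set
    logits = model.predict(x)
    if kind == "classifier_cnn":
        return float(np.mean(np.argmax(logits, axis=1) == y))
    if kind == "bbox_cnn":
        return -float(np.mean((logits - y) ** 2))
    if kind == "unet_seg":
        pred = (1.0 / (1.0 + np.exp(-logits)) >= 0.5).astype(np.float64)
        t = np.asarray(y, dtype=np.float64)
        inter = (pred * t).sum(axis=(1, 2, 3))
        denom = pred.sum(axis=(1, 2, 3)) + t.sum(axis=(1, 2, 3))
        return float(np.mean((2 * inter + 1e-6) / (denom + 1e-6)))
    if kind == "unet_action":
        return float(np.mean(np.argmax(logits, axis=1) == y))
    raise ValueError(kind)


def _snapshot(net) -> tuple[list[np.ndarray], dict[str, np.ndarray]]:
    return [p.value.copy() for p in net.params()], {k: v.copy() for k, v in net.buffers().items()}


def _restore(net, snap) -> None:
    values, buffers = snap
    for p, v in zip(net.params(), values):
        p.value[...] = v
    live = net.buffers()
    for k, v in buffers.items():
        live[k][...] = v


def train_model(
    arch: ArchSpec,
    train_set,
    val_set,
    cfg: TrainConfig,
    sampler=None,
) -> tuple[NetworkModel, TrainingLog]:
    """Train a network with Adam, early-stopping on the validation metric.

    ``train_set`` is an ``(X, y)`` pair; ``sampler(rng, batch_size)`` may
    override minibatch construction (e.g. class-balanced sampling or
    on-the-fly augmentation).  Returns the best-on-validation weights and
    the training log.  Loss: cross-entropy (classifier, action maps), MSE
    (bounding box), soft Dice (segmentation).
    """
    if sampler is None:
        if train_set is None or len(train_set[0]) == 0:
            raise ValueError("empty training set")
        xs, ys = train_set

        def sampler(rng, bs):
            idx = rng.integers(0, len(xs), size=bs)
            return xs[idx], ys[idx]

    if val_set is None or len(val_set[0]) == 0:
        raise ValueError("empty validation set")

    rng = np.random.default_rng(cfg.seed)
    net = build_model(arch, dropout_p=cfg.dropout_p, rng=rng)
    model = NetworkModel(net, arch, cfg)
    loss_fn = _LOSSES[arch.kind]
    opt = nn.Adam(net.params(), lr=cfg.learning_rate, l2_weight=cfg.l2_weight)
    log = TrainingLog()

    best_metric = -np.inf
    best_snap = _snapshot(net)
    last_improve = 0
    for it in range(1, cfg.max_iterations + 1):
        xb, yb = sampler(rng, cfg.batch_size)
        logits = net.forward(np.asarray(xb, dtype=np.float32), train=True)
        loss, grad = loss_fn(logits, yb)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at iteration {it}")
        opt.zero_grad()
        net.backward(grad)
        opt.step()
        if it % cfg.eval_every == 0 or it == cfg.max_iterations:
            metric = _validation_metric(arch.kind, model, val_set)
            log.add(it, loss, metric)
            if metric > best_metric + 1e-9:
                best_metric = metric
                best_snap = _snapshot(net)
                last_improve = it
            elif it - last_improve >= cfg.patience:
                break
        else:
            log.add(it, loss)
    _restore(net, best_snap)
    return model, log
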