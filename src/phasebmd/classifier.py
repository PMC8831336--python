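"""Slice-level three-class contrast-phase classifier (NE / AR / PV).

Training protocol: AdamW, class-weighted categorical cross-entropy (weights =
inverse class frequency normalized to mean 1), heavy label-preserving
augmentation (flips, rotation, zoom, random crop, random field of view),
early stopping on the validation macro-F1 score, and patient-level threefold
cross-validation so that no patient's scans straddle folds.

Two backbones are available. The default ``compact`` backbone is a small
densely-connected convolutional network (three dense blocks, growth 12, with
1x1-conv transitions) that trains in minutes on one CPU; ``dense161`` builds
the classic 161-layer bottlenecked DenseNet topology (blocks 6/12/36/24,
growth 48) for completeness — constructible and runnable, but not practical
to train without accelerator hardware, and no pretrained weights are bundled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import f1_score

from ._nn import (
    AdamW,
    AvgPool2d,
    Conv2d,
    DenseLayer,
    Flatten,
    GlobalAvgPool,
    Linear,
    Network,
    ReLU,
    Transition,
    softmax,
    weighted_cross_entropy,
)
from .anatomy import PHASES
from .errors import ConfigError, ValidationError
from .preprocess import SliceStack, crop_pad

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "build_model",
    "make_folds",
    "augment",
    "compute_class_weights",
    "train",
    "predict_slices",
    "save_checkpoint",
    "load_checkpoint",
    "weighted_cross_entropy",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Switches and ranges for label-preserving training augmentation."""

    vflip: bool = True
    hflip: bool = True
    rotation: bool = True
    zoom: bool = True
    crop: bool = True
    fov: bool = True
    p_flip: float = 0.5
    p_geom: float = 0.3  # per-transform probability for rotation/zoom/crop/fov
    rotation_deg: float = 10.0
    zoom_range: tuple[float, float] = (0.9, 1.1)
    crop_frac: tuple[float, float] = (0.85, 1.0)
    fov_frac: tuple[float, float] = (0.6, 0.9)

    @staticmethod
    def none() -> "AugmentConfig":
        return AugmentConfig(vflip=False, hflip=False, rotation=False, zoom=False,
                             crop=False, fov=False)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The defaults for batch size and learning rate (100, 1e-4) suit
    fine-tuning a large pretrained backbone; the pipeline's default YAML
    config raises the learning rate to 1e-3 for the compact backbone trained
    from scratch.
    """

    batch_size: int = 100
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    max_epochs: int = 30
    early_stop_patience: int = 5
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0
    backbone: str = "compact"
    image_size: int = 224

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.backbone not in ("compact", "dense161"):
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.image_size % 32:
            raise ConfigError("image_size must be divisible by 32")


def build_model(config: TrainConfig) -> Network:
    """Construct the backbone; identical seeds give identical initial weights."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    s = config.image_size
    if config.backbone == "compact":
        layers: list = [AvgPool2d(4), Conv2d(1, 16, k=3, pad=1, rng=rng), ReLU(), AvgPool2d(2)]
        ch = 16
        growth, per_block = 12, 2
        for b in range(3):
            for _ in range(per_block):
                layers.append(DenseLayer(ch, growth, rng))
                ch += growth
            if b < 2:
                layers.append(Transition(ch, ch // 2, rng))
                ch //= 2
        # flattened spatial head: slice crops are anatomy-centered, so
        # absolute position carries the aorta/liver enhancement cues
        n_spatial = (s // 32) ** 2
        layers += [Flatten(), Linear(ch * n_spatial, 3, rng)]
        return Network(layers, "compact", s)
    # dense161: 96-channel stem, bottleneck blocks 6/12/36/24, growth 48
    layers = [Conv2d(1, 96, k=7, stride=2, pad=3, rng=rng), ReLU(), AvgPool2d(2)]
    ch = 96
    for bi, n in enumerate((6, 12, 36, 24)):
        for _ in range(n):
            layers.append(DenseLayer(ch, 48, rng, bottleneck=True))
            ch += 48
        if bi < 3:
            layers.append(Transition(ch, ch // 2, rng))
            ch //= 2
    layers += [GlobalAvgPool(), Linear(ch, 3, rng)]
    return Network(layers, "dense161", s)


def make_folds(patients, k: int = 3, seed: int = 0) -> dict[str, int]:
    """Randomly split patients into k folds of near-equal size.

    Patient-level: the caller assigns every scan of a patient to that
    patient's fold, so scans never straddle folds. Deterministic under seed.
    """
    patients = sorted(set(map(str, patients)))
    if k < 1 or k > len(patients):
        raise ConfigError(f"cannot split {len(patients)} patients into {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
    order = rng.permutation(len(patients))
    folds = np.array_split(order, k)
    out: dict[str, int] = {}
    for fi, idxs in enumerate(folds):
        for i in idxs:
            out[patients[i]] = fi
    return out


def compute_class_weights(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Inverse class frequency, normalized to mean 1."""
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    if np.any(counts == 0):
        raise ValidationError("every class must be present to compute class weights")
    w = 1.0 / counts
    return w / w.mean()


def augment(image: np.ndarray, config: AugmentConfig,
            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Apply the configured random transforms to one slice (label-preserving).

    Transforms are drawn and applied in a fixed order (vflip, hflip,
    rotation, zoom, crop, fov); with all switches off the input is returned
    unchanged. Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    im = np.asarray(image, dtype=np.float32)
    if im.ndim != 2:
        raise ValidationError("augment expects a 2-D image")
    s = im.shape[0]
    if config.vflip and rng.random() < config.p_flip:
        im = im[::-1, :]
    if config.hflip and rng.random() < config.p_flip:
        im = im[:, ::-1]
    if config.rotation and rng.random() < config.p_geom:
        angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
        im = ndimage.rotate(im, angle, reshape=False, order=1, mode="constant",
                            cval=float(im.min()))
    if config.zoom and rng.random() < config.p_geom:
        f = rng.uniform(*config.zoom_range)
        im = crop_pad(ndimage.zoom(im, f, order=1), s)
    if config.crop and rng.random() < config.p_geom:
        f = rng.uniform(*config.crop_frac)
        w = max(8, int(round(f * s)))
        i0 = rng.integers(0, s - w + 1)
        j0 = rng.integers(0, s - w + 1)
        im = crop_pad(im[i0 : i0 + w, j0 : j0 + w], s)
    if config.fov and rng.random() < config.p_geom:
        f = rng.uniform(*config.fov_frac)
        w = max(8, int(round(f * s)))
        i0 = rng.integers(0, s - w + 1)
        j0 = rng.integers(0, s - w + 1)
        win = im[i0 : i0 + w, j0 : j0 + w]
        im = crop_pad(ndimage.zoom(win, s / w, order=1), s)
    return np.ascontiguousarray(im, dtype=np.float32)


def _flatten(data) -> tuple[np.ndarray, np.ndarray]:
    """Flatten (SliceStack, phase) pairs into slice images and int labels."""
    xs, ys = [], []
    for stack, phase in data:
        if phase not in PHASES:
            raise ValidationError(f"unknown phase label {phase!r}")
        for im in stack.images:
            xs.append(im)
            ys.append(PHASES.index(phase))
    return np.stack(xs).astype(np.float32), np.asarray(ys, dtype=np.int64)


def train(train_data, val_data, config: TrainConfig) -> tuple[Network, pd.DataFrame]:
    """Train the slice classifier with early stopping on validation macro-F1.

    ``train_data`` / ``val_data`` are sequences of ``(SliceStack, phase)``
    pairs. Returns the checkpoint with the best validation F1 together with
    the per-epoch history (epoch, train_loss, val_f1).
    """
    if not len(train_data) or not len(val_data):
        raise ValidationError("both training and validation splits must be non-empty")
    x_tr, y_tr = _flatten(train_data)
    x_va, y_va = _flatten(val_data)
    if len(np.unique(y_tr)) < 3:
        raise ValidationError("all three contrast phases must be present in training data")
    weights = compute_class_weights(y_tr)
    model = build_model(config)
    if x_tr.shape[1] != config.image_size:
        raise ValidationError(
            f"stack image size {x_tr.shape[1]} != configured image_size {config.image_size}"
        )
    opt = AdamW(model.params(), lr=config.learning_rate, weight_decay=config.weight_decay)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    aug_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 14]))

    best_f1, best_epoch, best_weights = -np.inf, 0, model.get_weights()
    rows = []
    n = len(x_tr)
    for epoch in range(1, config.max_epochs + 1):
        perm = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb = np.stack([augment(x_tr[i], config.augmentation, aug_rng) for i in idx])
            logits = model.forward(xb[:, None, :, :])
            loss, grad = weighted_cross_entropy(logits, y_tr[idx], weights)
            model.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_pred = predict_proba(model, x_va).argmax(axis=1)
        val_f1 = float(f1_score(y_va, val_pred, average="macro", zero_division=0))
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_f1": val_f1})
        if val_f1 > best_f1 + 1e-12:
            best_f1, best_epoch, best_weights = val_f1, epoch, model.get_weights()
        if epoch - best_epoch >= config.early_stop_patience:
            break
    model.set_weights(best_weights)
    return model, pd.DataFrame(rows)


def predict_proba(model: Network, images: np.ndarray, batch_size: int = 100) -> np.ndarray:
    """Class probabilities (n, 3) for a batch of slices (n, S, S)."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    if images.shape[1] != model.input_size or images.shape[2] != model.input_size:
        raise ValidationError(
            f"image size {images.shape[1:]} does not match model input {model.input_size}"
        )
    out = []
    for start in range(0, len(images), batch_size):
        logits = model.forward(images[start : start + batch_size, None, :, :])
        out.append(softmax(logits.astype(np.float64)))
    return np.concatenate(out, axis=0)


def predict_slices(model: Network, stack: SliceStack) -> np.ndarray:
    """Per-slice probability triples over (NE, AR, PV); rows sum to 1."""
    return predict_proba(model, stack.as_array())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Network, config: TrainConfig, path: str | Path,
                    fold: int | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = asdict(config)
    meta["augmentation"] = asdict(config.augmentation)
    meta["fold"] = fold
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, meta=json.dumps(meta), **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[Network, TrainConfig, int | None]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        fold = meta.pop("fold", None)
        aug = AugmentConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in meta.pop("augmentation").items()})
        config = TrainConfig(augmentation=aug, **meta)
        model = build_model(config)
        weights = [data[f"w{i}"] for i in range(len(model.get_weights()))]
    model.set_weights(weights)
    return model, config, fold
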