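"""The barcode classifier network: build, train, predict, save, load.

The model maps a z-normalised 1024-sample signal window to 13 class
probabilities (barcodes 1-12 plus no-barcode).  The reference stack is:
an input Gaussian-noise layer, repeated groups of same-padded
convolutions (constant filter count) followed by 2x max pooling, batch
normalisation and dropout — so the trace halves in length per group,
1024 -> 512 -> 256 -> ... — with one inception-style parallel module
(1-wide path, stacked-conv path, pooled path, each behind a
low-dimension bottleneck) mid-network, and a global-average-pooling +
softmax head.  Noise and dropout are active only during training.

Everything is configuration-driven: ``NetworkConfig.scale`` shrinks the
filter counts for desk-scale experiments while preserving the topology.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from squigglebin import nn

log = logging.getLogger(__name__)

N_CLASSES = 13  # barcodes 1..12 + no-barcode
NO_BARCODE_CLASS = 0  # class index 0; barcode b is class index b


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``base_filters`` is the constant filter count (48 in the reference
    network); ``scale`` multiplies it for smaller models.  Each of the
    ``n_groups`` conv groups halves the trace length, so ``input_len``
    must be divisible by ``2**n_groups``.
    """

    input_len: int = 1024
    n_classes: int = N_CLASSES
    base_filters: int = 48
    kernel_size: int = 9
    convs_per_group: int = 2
    n_groups: int = 6
    inception_after_group: int = 3
    bottleneck: int = 16
    dropout_rate: float = 0.15
    noise_sd: float = 0.02
    scale: float = 1.0
    seed: int = 0

    @property
    def filters(self) -> int:
        return max(4, int(round(self.base_filters * self.scale)))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        return cls(**json.loads(s))


def desk_scale_config(**overrides) -> NetworkConfig:
    """A small model for single-CPU work: same topology, a third of the
    filters, one convolution per group."""
    cfg = dict(scale=1 / 3, convs_per_group=1, bottleneck=8)
    cfg.update(overrides)
    return NetworkConfig(**cfg)


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    ``samples_per_epoch`` draws that many training samples (with
    replacement) each epoch; ``None`` uses the full training partition.
    ``augmentation_factor`` of 2 adds one freshly time-distorted copy of
    every sample drawn in an epoch; augmentation applies to the training
    partition only, never to validation.

    ``no_barcode_weight`` up-weights the no-barcode class in the loss.
    Training windows are mostly barcode-bearing while classification
    windows are mostly barcode-free; the weight counteracts that prior
    mismatch so barcode-free signal is not nudged toward a barcode class.
    """

    epochs: int = 15
    samples_per_epoch: int | None = 4000
    validation_fraction: float = 0.05
    augmentation_factor: int = 2
    batch_size: int = 64
    learning_rate: float = 3e-3
    plateau_patience: int = 3
    plateau_factor: float = 0.5
    no_barcode_weight: float = 3.0
    label_smoothing: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.augmentation_factor < 1:
            raise ValueError("augmentation factor must be >= 1")


@dataclass
class Model:
    """A built network plus its configuration (needed for save/load)."""

    net: nn.Sequential
    config: NetworkConfig

    def n_params(self) -> int:
        return self.net.n_params()


def build_model(config: NetworkConfig | None = None) -> Model:
    """Assemble the classifier from a NetworkConfig.

    Raises at build time if the input length is not divisible by the
    cumulative pooling factor.
    """
    config = config or NetworkConfig()
    if config.input_len % (2 ** config.n_groups):
        raise ValueError(
            f"input_len {config.input_len} not divisible by cumulative "
            f"pooling 2**{config.n_groups}")
    rng = np.random.default_rng(config.seed)
    F, k = config.filters, config.kernel_size
    b = config.bottleneck

    layers: list[nn.Layer] = [nn.GaussianNoise(config.noise_sd)]
    in_ch = 1
    for g in range(config.n_groups):
        for _ in range(config.convs_per_group):
            layers += [nn.Conv1D(in_ch, F, k, rng), nn.ReLU()]
            in_ch = F
        layers += [nn.MaxPool1D(2), nn.BatchNorm1D(F), nn.Dropout(config.dropout_rate)]
        if g + 1 == config.inception_after_group:
            # parallel module: 1-wide, stacked-conv and pooled paths,
            # each behind a low-dimension bottleneck
            inception = nn.Inception1D([
                [nn.Conv1D(F, b, 1, rng), nn.ReLU()],
                [nn.Conv1D(F, b, 1, rng), nn.ReLU(),
                 nn.Conv1D(b, F, k, rng), nn.ReLU()],
                [nn.SamePool1D(3), nn.Conv1D(F, b, 1, rng), nn.ReLU()],
            ])
            layers.append(inception)
            in_ch = F + 2 * b  # filter count increases above F here
    layers += [nn.GlobalAvgPool1D(), nn.Dense(in_ch, config.n_classes, rng)]
    return Model(nn.Sequential(layers), config)


def _resolve_xy(training_set) -> tuple[np.ndarray, np.ndarray]:
    """Accept a TrainingSet-like object (with .X/.y) or a plain tuple."""
    if hasattr(training_set, "X"):
        return training_set.X, training_set.y
    X, y = training_set
    return np.asarray(X), np.asarray(y)


def train_model(model: Model, training_set, config: TrainConfig | None = None
                ) -> tuple[Model, dict]:
    """Train by Adam on categorical cross-entropy with a random
    95:5 training:validation split.

    Returns (model, history); history holds per-epoch training and
    validation loss and accuracy.  Because augmentation, noise and
    dropout act on training batches only, validation metrics typically
    exceed training metrics.  Aborts on a non-finite loss.
    """
    from squigglebin.training_data import augment_signal

    config = config or TrainConfig()
    X, y = _resolve_xy(training_set)
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(X.shape[0])
    n_val = max(1, int(round(config.validation_fraction * X.shape[0])))
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xval, yval = X[val_idx], y[val_idx]
    Xtr, ytr = X[train_idx], y[train_idx]

    opt = nn.Adam(model.net.params(), lr=config.learning_rate)
    history = {"loss": [], "acc": [], "val_loss": [], "val_acc": [], "lr": []}
    best_val, since_best = np.inf, 0

    for epoch in range(config.epochs):
        n_draw = config.samples_per_epoch or Xtr.shape[0]
        idx = rng.integers(0, Xtr.shape[0], size=n_draw) \
            if config.samples_per_epoch else rng.permutation(Xtr.shape[0])
        Xe, ye = Xtr[idx], ytr[idx]
        if config.augmentation_factor > 1:
            copies = [Xe] + [
                np.stack([augment_signal(x, rng) for x in Xe]).astype(np.float32)
                for _ in range(config.augmentation_factor - 1)]
            Xe = np.concatenate(copies)
            ye = np.tile(ye, config.augmentation_factor)
            perm = rng.permutation(Xe.shape[0])
            Xe, ye = Xe[perm], ye[perm]

        ep_loss, ep_correct, n_seen = 0.0, 0, 0
        for i in range(0, Xe.shape[0], config.batch_size):
            xb = Xe[i:i + config.batch_size][..., None]  # (B, L, 1)
            yb = ye[i:i + config.batch_size]
            logits = model.net.forward(xb, training=True, rng=rng)
            probs = nn.softmax(logits)
            loss = nn.cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}: "
                    f"loss={loss}, lr={opt.lr}, batch labels={np.bincount(yb)}")
            # smoothed one-hot targets temper over-confident predictions,
            # which matters because one confident wrong window can spoil a
            # whole read's merged probability gap
            eps = config.label_smoothing
            target = np.full_like(probs, eps / probs.shape[1])
            target[np.arange(yb.size), yb] += 1.0 - eps
            grad = probs - target
            w = np.where(yb == NO_BARCODE_CLASS, config.no_barcode_weight, 1.0)
            grad *= (w / w.sum())[:, None]
            model.net.backward(grad.astype(np.float32))
            opt.step(model.net.grads())
            ep_loss += loss * yb.size
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
            n_seen += yb.size

        val_probs = model.net.predict(Xval[..., None])
        val_loss = nn.cross_entropy(val_probs, yval)
        val_acc = float((val_probs.argmax(axis=1) == yval).mean())
        history["loss"].append(ep_loss / n_seen)
        history["acc"].append(ep_correct / n_seen)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        log.info("epoch %d/%d loss %.4f acc %.3f val_loss %.4f val_acc %.3f",
                 epoch + 1, config.epochs, history["loss"][-1],
                 history["acc"][-1], val_loss, val_acc)

        if val_loss < best_val - 1e-4:
            best_val, since_best = val_loss, 0
        else:
            since_best += 1
            if since_best >= config.plateau_patience:
                opt.lr *= config.plateau_factor
                since_best = 0
    return model, history


def predict_probs(model: Model, windows: np.ndarray) -> np.ndarray:
    """Class probabilities for a batch of z-normalised windows.

    ``windows`` is (n, input_len); returns (n, n_classes) rows that are
    non-negative and sum to 1.
    """
    windows = np.asarray(windows, dtype=np.float32)
    if windows.ndim == 1:
        windows = windows[None, :]
    if windows.shape[1] != model.config.input_len:
        raise ValueError(f"window length {windows.shape[1]} != "
                         f"model input length {model.config.input_len}")
    return model.net.predict(windows[..., None])


def save_model(model: Model, path: str | Path) -> None:
    """Serialise weights (npz) plus a JSON sidecar with the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p for i, p in enumerate(model.net.params())}
    arrays.update({f"s{i}": s for i, s in enumerate(model.net.state())})
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
        else path.with_suffix(".json")
    sidecar.write_text(model.config.to_json())


def load_model(path: str | Path) -> Model:
    """Rebuild the architecture from the sidecar and restore the weights."""
    path = Path(path)
    if not path.exists() and path.with_suffix(".npz").exists():
        path = path.with_suffix(".npz")
    sidecar = path.with_suffix(".json")
    config = NetworkConfig.from_json(sidecar.read_text())
    model = build_model(config)
    data = np.load(path)
    for i, p in enumerate(model.net.params()):
        p[...] = data[f"p{i}"]
    for i, s in enumerate(model.net.state()):
        s[...] = data[f"s{i}"]
    return model
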