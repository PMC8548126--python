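"""The three-scale lightweight U-Net, its loss, and the SGD training loop.

The network is an encoder-decoder with five dense convolutional blocks
(each: conv3x3 -> ReLU -> dropout -> conv3x3 -> ReLU, all convolutions
padded so spatial size is preserved): two encoder blocks separated by 2x2
max-pooling, one bottleneck block, and two decoder blocks, each preceded by
2x upsampling with a channel-halving convolution and concatenation with the
mirrored encoder feature map.  Channel widths are 32/64/128 — half of the
classic U-Net's first three scales.  A 1x1 convolution and per-pixel softmax
emit two class channels (background, laser mark); class 1 is the laser-mark
class everywhere in this package.

Training is plain stochastic gradient descent on the pixel-wise categorical
cross-entropy.  A global 10% validation split of the patch pool monitors
progress: the learning rate is multiplied by ``lr_factor`` after
``lr_patience`` consecutive epochs without improvement in validation
accuracy, training stops early after ``early_stop_patience`` such epochs,
and the returned checkpoint holds the weights that minimized validation
loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from . import nnops
from .patchwork import PatchSet

LOSS_EPS = 1e-12


class TrainingError(RuntimeError):
    pass


@dataclass
class NetworkSpec:
    n_scales: int = 3
    block_channels: tuple[int, ...] = (32, 64, 128)
    window: int = 48
    in_channels: int = 3
    n_classes: int = 2
    dropout_p: float = 0.2
    conv_kernel: int = 3
    pool_kernel: int = 2
    upsample: str = "nearest"  # or "transposed"

    def __post_init__(self) -> None:
        if self.n_scales != len(self.block_channels):
            raise ValueError("n_scales must equal len(block_channels)")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.upsample not in ("nearest", "transposed"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")


@dataclass
class TrainConfig:
    batch_size: int = 128
    val_fraction: float = 0.10
    lr_init: float = 1e-3
    lr_factor: float = 0.3
    lr_patience: int = 10
    early_stop_patience: int = 40
    momentum: float = 0.0
    seed: int = 0
    max_epochs: int = 150

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must be in (0, 1)")


class PlateauTracker:
    """Counts consecutive epochs without improvement of a maximized metric.

    ``update`` returns True each time the count reaches ``patience``; the
    count resets on improvement and, if ``reset_on_trigger``, on trigger
    (the reduce-on-plateau behavior).  With ``reset_on_trigger=False`` the
    tracker keeps counting and fires once, which is early stopping.
    """

    def __init__(self, patience: int, min_delta: float = 0.0, reset_on_trigger: bool = True):
        self.patience = patience
        self.min_delta = min_delta
        self.reset_on_trigger = reset_on_trigger
        self.best: float | None = None
        self.count = 0

    def update(self, value: float) -> bool:
        if self.best is None or value > self.best + self.min_delta:
            self.best = value
            self.count = 0
            return False
        self.count += 1
        if self.count >= self.patience:
            if self.reset_on_trigger:
                self.count = 0
            return True
        return False


class _DenseBlock:
    """conv3x3 -> ReLU -> dropout -> conv3x3 -> ReLU, spatial size preserved."""

    def __init__(self, rng, cin, cout, k, dropout_p):
        self.conv1 = nnops.Conv2D(rng, cin, cout, k)
        self.relu1 = nnops.ReLU()
        self.drop = nnops.Dropout(dropout_p, rng)
        self.conv2 = nnops.Conv2D(rng, cout, cout, k)
        self.relu2 = nnops.ReLU()
        self._layers = [self.conv1, self.relu1, self.drop, self.conv2, self.relu2]

    def forward(self, x, train):
        for layer in self._layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self._layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for name, layer in (("conv1", self.conv1), ("conv2", self.conv2)):
            for pname, p, g in layer.parameters():
                yield f"{name}.{pname}", p, g


class _UpStep:
    """2x upsample followed by a channel-halving 2x2 convolution."""

    def __init__(self, rng, cin, cout, mode):
        if mode == "transposed":
            self.up = nnops.TransposedUpsample2x(rng, cin, cout)
            self.conv = None
        else:
            self.up = nnops.UpsampleNearest2x()
            self.conv = nnops.Conv2D(rng, cin, cout, 2)

    def forward(self, x, train):
        x = self.up.forward(x, train)
        if self.conv is not None:
            x = self.conv.forward(x, train)
        return x

    def backward(self, dy):
        if self.conv is not None:
            dy = self.conv.backward(dy)
        return self.up.backward(dy)

    def parameters(self):
        owner = self.conv if self.conv is not None else self.up
        for pname, p, g in owner.parameters():
            yield f"conv.{pname}", p, g


class LightweightUNet:
    """Forward/backward graph for the three-scale lightweight U-Net."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c1, c2, c3 = spec.block_channels
        k, p = spec.conv_kernel, spec.dropout_p
        self.enc1 = _DenseBlock(rng, spec.in_channels, c1, k, p)
        self.pool1 = nnops.MaxPool2x2()
        self.enc2 = _DenseBlock(rng, c1, c2, k, p)
        self.pool2 = nnops.MaxPool2x2()
        self.bottleneck = _DenseBlock(rng, c2, c3, k, p)
        self.up2 = _UpStep(rng, c3, c2, spec.upsample)
        self.dec2 = _DenseBlock(rng, c2 + c2, c2, k, p)
        self.up1 = _UpStep(rng, c2, c1, spec.upsample)
        self.dec1 = _DenseBlock(rng, c1 + c1, c1, k, p)
        self.head = nnops.Conv2D(rng, c1, spec.n_classes, 1)
        self._named = [
            ("enc1", self.enc1), ("enc2", self.enc2), ("bottleneck", self.bottleneck),
            ("up2", self.up2), ("dec2", self.dec2), ("up1", self.up1),
            ("dec1", self.dec1), ("head", self.head),
        ]

    @property
    def n_dense_blocks(self) -> int:
        return sum(1 for _, m in self._named if isinstance(m, _DenseBlock))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Input (N, window, window, 3) -> per-pixel class probabilities (N, window, window, K)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        e1 = self.enc1.forward(x, train)
        e2 = self.enc2.forward(self.pool1.forward(e1, train), train)
        b = self.bottleneck.forward(self.pool2.forward(e2, train), train)
        u2 = self.up2.forward(b, train)
        d2 = self.dec2.forward(np.concatenate([e2, u2], axis=-1), train)
        u1 = self.up1.forward(d2, train)
        d1 = self.dec1.forward(np.concatenate([e1, u1], axis=-1), train)
        logits = self.head.forward(d1, train)
        self._c_skip = (e1.shape[-1], e2.shape[-1]) if train else None
        return nnops.softmax_channels(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        c1, c2 = self.spec.block_channels[:2]
        dd1 = self.head.backward(dlogits)
        dcat1 = self.dec1.backward(dd1)
        de1_skip, du1 = dcat1[..., :c1], dcat1[..., c1:]
        dd2 = self.up1.backward(np.ascontiguousarray(du1))
        dcat2 = self.dec2.backward(dd2)
        de2_skip, du2 = dcat2[..., :c2], dcat2[..., c2:]
        db = self.up2.backward(np.ascontiguousarray(du2))
        de2 = self.pool2.backward(self.bottleneck.backward(db)) + de2_skip
        de1 = self.pool1.backward(self.enc2.backward(np.ascontiguousarray(de2))) + de1_skip
        self.enc1.backward(np.ascontiguousarray(de1))

    def parameters(self) -> Iterable[tuple[str, np.ndarray, np.ndarray]]:
        for prefix, module in self._named:
            for name, p, g in module.parameters():
                yield f"{prefix}.{name}", p, g

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.parameters():
            if name not in state:
                raise KeyError(f"checkpoint missing parameter {name}")
            if state[name].shape != p.shape:
                raise ValueError(
                    f"parameter {name}: shape {state[name].shape} != {p.shape}"
                )
            p[...] = state[name]


def build_network(spec: NetworkSpec, seed: int = 0) -> LightweightUNet:
    """Construct the parameterized lightweight U-Net described by ``spec``."""
    return LightweightUNet(spec, seed=seed)


@dataclass
class Checkpoint:
    weights: dict[str, np.ndarray]
    network_spec: NetworkSpec
    norm_stats_ref: str = ""
    training_log: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        meta = {
            "network_spec": asdict(self.network_spec),
            "norm_stats_ref": self.norm_stats_ref,
            "training_log": self.training_log,
        }
        np.savez(
            path,
            __meta__=np.array(json.dumps(meta)),
            **{f"w/{k}": v for k, v in self.weights.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz") if path.suffix else path.with_suffix(".npz")
        with np.load(path) as data:
            meta = json.loads(str(data["__meta__"]))
            weights = {k[2:]: data[k] for k in data.files if k.startswith("w/")}
        spec_d = meta["network_spec"]
        spec_d["block_channels"] = tuple(spec_d["block_channels"])
        return cls(
            weights=weights,
            network_spec=NetworkSpec(**spec_d),
            norm_stats_ref=meta["norm_stats_ref"],
            training_log=meta["training_log"],
        )


def pixelwise_crossentropy(predictions: np.ndarray, labels_onehot: np.ndarray) -> float:
    """Summed categorical cross-entropy over all pixels and classes in a batch.

    ``predictions`` are probabilities (clamped below at 1e-12); ``labels_onehot``
    is the matching one-hot array.
    """
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels_onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {p.shape} vs labels {y.shape}")
    return float(-(y * np.log(np.maximum(p, LOSS_EPS))).sum())


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    # channel order (background, laser mark): class 1 = laser mark
    out = np.zeros(labels.shape + (n_classes,), dtype=np.float32)
    for k in range(n_classes):
        out[..., k] = labels == k
    return out


def _batch_forward(model, x, batch_size):
    outs = []
    for i in range(0, len(x), batch_size):
        outs.append(model.forward(x[i : i + batch_size], train=False))
    return np.concatenate(outs) if outs else np.empty((0,))


def train(
    patchset: PatchSet,
    config: TrainConfig,
    init: Optional[Checkpoint] = None,
    spec: Optional[NetworkSpec] = None,
    norm_stats_ref: str = "",
) -> Checkpoint:
    """Train the lightweight U-Net on a patch pool and return the best checkpoint.

    Ten percent of the patch pool (a single global split, fixed by
    ``config.seed``) is held out for validation.  The per-step objective is
    the summed pixel-wise cross-entropy divided by the number of pixels in
    the batch (the per-pixel mean), so the update magnitude depends on
    neither batch size nor window size; logged losses are per-pixel means.
    """
    if len(patchset) == 0:
        raise TrainingError("patch set is empty")
    if init is not None:
        spec = init.network_spec
    elif spec is None:
        spec = NetworkSpec()
    model = build_network(spec, seed=config.seed)
    if init is not None:
        model.load_state_dict(init.weights)
    else:
        # initialize the head bias to the class log-odds of the patch pool so
        # the first epochs refine features instead of learning the class prior
        pos = float(np.clip(patchset.labels.mean(), 1e-4, 1 - 1e-4))
        model.head.bias[...] = np.array([0.0, np.log(pos / (1 - pos))],
                                        dtype=np.float32)

    rng = np.random.default_rng(config.seed)
    n = len(patchset)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise TrainingError("no training patches left after validation split")
    x_all = np.ascontiguousarray(patchset.images, dtype=np.float32)
    y_all = patchset.labels.astype(np.int64)

    lr = config.lr_init
    lr_tracker = PlateauTracker(config.lr_patience, reset_on_trigger=True)
    stop_tracker = PlateauTracker(config.early_stop_patience, reset_on_trigger=False)
    velocity = {name: np.zeros_like(p) for name, p, _ in model.parameters()} \
        if config.momentum > 0 else None

    best_val_loss = np.inf
    best_weights = model.state_dict()
    log: list[dict] = []
    stop_reason = "max_epochs"
    x_val, y_val = x_all[val_idx], y_all[val_idx]
    y_val_onehot = _one_hot(y_val, spec.n_classes)

    for epoch in range(1, config.max_epochs + 1):
        perm = train_idx[rng.permutation(len(train_idx))]
        epoch_losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb = x_all[idx]
            yb = _one_hot(y_all[idx], spec.n_classes)
            with np.errstate(over="ignore", invalid="ignore"):
                probs = model.forward(xb, train=True)
                n_px = yb.size / spec.n_classes
                loss = pixelwise_crossentropy(probs, yb) / n_px
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite loss at epoch {epoch}")
                epoch_losses.append(loss)
                dlogits = (probs - yb) / n_px
                model.backward(dlogits.astype(np.float32))
            for name, p, g in model.parameters():
                if velocity is not None:
                    v = velocity[name]
                    v *= config.momentum
                    v -= lr * g
                    p += v
                else:
                    p -= lr * g

        val_probs = _batch_forward(model, x_val, config.batch_size)
        val_loss = pixelwise_crossentropy(val_probs, y_val_onehot) / y_val.size
        val_acc = float((val_probs.argmax(axis=-1) == y_val).mean())
        log.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": float(val_loss),
                "val_acc": val_acc,
            }
        )
        if val_loss < best_val_loss:
            best_val_loss = val_loss
            best_weights = model.state_dict()
        if lr_tracker.update(val_acc):
            lr *= config.lr_factor
        if stop_tracker.update(val_acc):
            stop_reason = "early_stop"
            break

    log.append({"stop_reason": stop_reason})
    return Checkpoint(
        weights=best_weights,
        network_spec=spec,
        norm_stats_ref=norm_stats_ref,
        training_log=log,
    )


def predict_patches(
    checkpoint: Checkpoint, windows: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Laser-mark-class probability windows for a stack of preprocessed inputs.

    Dropout is disabled, so inference is deterministic.
    """
    windows = np.asarray(windows, dtype=np.float32)
    spec = checkpoint.network_spec
    if windows.ndim != 4 or windows.shape[1:] != (spec.window, spec.window, spec.in_channels):
        raise ValueError(
            f"windows must be (n, {spec.window}, {spec.window}, {spec.in_channels}), "
            f"got {windows.shape}"
        )
    model = build_network(spec)
    model.load_state_dict(checkpoint.weights)
    probs = _batch_forward(model, windows, batch_size)
    return probs[..., 1]
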