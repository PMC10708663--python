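"""Squeeze-and-excitation residual network for multi-analyte regression.

The regressor maps a hyperspectral image patch — spectral bands as input
channels — to five concentration values.  The architecture is the bottleneck
residual family: a 7x7/stride-2 stem convolution with batch normalization, a
3x3/stride-2 max pool, four stages of SE-augmented bottleneck blocks with
default counts (3, 4, 23, 3) and output channels (256, 512, 1024, 2048), a
global average pool, and a two-layer head narrowing 2048 -> 256 -> 5.  Each
bottleneck block ends in a squeeze-and-excitation unit (reduction 16 by
default): per-channel global averaging followed by a two-layer sigmoid
bottleneck whose output rescales the channels.  Pinning every excitation
weight to 1 reduces the network to a plain residual network (ablation switch).

The default depth is the full-fidelity profile; a reduced profile
(``ArchitectureSpec.reduced()``) with stage counts (1, 1, 2, 1) and narrow
channels trains in minutes on one CPU and is what the test-scale pipeline
uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    Adam, BatchNorm2d, Conv2d, Dense, GlobalAvgPool2d, MaxPool2d, Module,
    Param, ReLU, SEModule, Sigmoid,
)
from .preprocessing import StandardizeStats, standardize
from .segmentation import SampleRecord

__all__ = [
    "ArchitectureSpec", "TrainConfig", "SEResNet", "SEResNetRegressor",
    "build_model", "train_model", "predict",
    "channel_convolution", "se_recalibrate",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of the network."""

    input_hw: tuple[int, int] = (64, 64)
    in_channels: int = 128
    stem_channels: int = 64
    stem_kernel: int = 7
    stem_stride: int = 2
    stem_padding: int = 3
    pool_kernel: int = 3
    pool_stride: int = 2
    pool_padding: int = 1  # the geometrically sane choice; see docs/methods.md
    stage_blocks: tuple[int, int, int, int] = (3, 4, 23, 3)
    stage_channels: tuple[int, int, int, int] = (256, 512, 1024, 2048)
    se_reduction: int = 16
    head_widths: tuple[int, int] = (256, 5)
    n_outputs: int = 5

    def __post_init__(self) -> None:
        if len(self.stage_blocks) != 4 or len(self.stage_channels) != 4:
            raise ValueError("exactly four residual stages are expected")
        if any(b < 1 for b in self.stage_blocks):
            raise ValueError("every stage needs >= 1 block")
        for c in self.stage_channels:
            if c % self.se_reduction != 0:
                raise ValueError(
                    f"SE reduction {self.se_reduction} must divide stage "
                    f"channel count {c}"
                )
            if c % 4 != 0:
                raise ValueError("bottleneck stages need channel counts divisible by 4")
        if self.head_widths[-1] != self.n_outputs:
            raise ValueError(
                f"head must end at n_outputs={self.n_outputs}, "
                f"got widths {self.head_widths}"
            )

    @property
    def head_in(self) -> int:
        """Width entering the head = final stage channels after global pooling."""
        return self.stage_channels[-1]

    @property
    def total_blocks(self) -> int:
        return int(sum(self.stage_blocks))

    @classmethod
    def reduced(cls, input_hw: tuple[int, int] = (8, 8), in_channels: int = 128,
                ) -> "ArchitectureSpec":
        """Desk-scale profile used by the test pipeline.

        Depth is cut to (1, 1, 2, 1) blocks and the channel ladder narrowed;
        the stem stays comparatively wide (64) because the weakest spectral
        directions die in an aggressive 128-to-32 compression.
        """
        return cls(
            input_hw=input_hw, in_channels=in_channels, stem_channels=64,
            stage_blocks=(1, 1, 2, 1), stage_channels=(64, 128, 192, 256),
            se_reduction=4, head_widths=(64, 5),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "ArchitectureSpec":
        payload = dict(payload)
        for key in ("input_hw", "stage_blocks", "stage_channels", "head_widths"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class TrainConfig:
    """Optimisation settings; the seed fixes every stochastic component."""

    loss: str = "mse"
    optimizer: str = "adam"
    learning_rate: float = 2e-3
    epochs: int = 400
    batch_size: int = 32
    seed: int = 0
    weight_decay: float = 0.0
    lr_schedule: str = "cosine"  # "cosine" (decay to lr/50) or "constant"
    input_norm: str = "zca"  # "zca", "channel", or "none"
    zca_shrinkage: float = 1e-4  # eigenvalue shrinkage relative to the largest
    augment_flips: bool = True  # random H/V flips of the plate view
    augment_noise_sd: float = 0.0  # Gaussian noise on standardized inputs
    ema_decay: float = 0.998  # Polyak weight averaging; 0 disables
    mixup_alpha: float = 0.0  # Beta(alpha, alpha) sample mixing; 0 disables
    early_stopping_patience: int | None = None
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mse":
            raise ValueError("only mse loss is supported")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# functional views of the two core operations
# ---------------------------------------------------------------------------

def channel_convolution(X: np.ndarray, V: np.ndarray, stride: int = 1,
                        padding: int | str = "same") -> np.ndarray:
    """Multi-channel 2-D convolution: each output channel is the sum over
    input channels of 2-D spatial kernels applied to the matching channel.

    ``X`` is ``(H', W', C')`` and ``V`` is ``(C, C', kh, kw)``; the result is
    ``(H, W, C)``.  ``padding="same"`` keeps the spatial size at stride 1.
    """
    X = np.asarray(X, dtype=np.float32)
    V = np.asarray(V, dtype=np.float32)
    if X.ndim != 3 or V.ndim != 4:
        raise ValueError("X must be (H, W, C') and V must be (C, C', kh, kw)")
    if V.shape[1] != X.shape[2]:
        raise ValueError(
            f"kernel channel count {V.shape[1]} mismatches input channels {X.shape[2]}"
        )
    if V.shape[2] != V.shape[3]:
        raise ValueError("only square kernels are supported")
    k = V.shape[2]
    pad = (k - 1) // 2 if padding == "same" else int(padding)
    conv = Conv2d(X.shape[2], V.shape[0], k, stride=stride, padding=pad, weight=V)
    out = conv.forward(X.transpose(2, 0, 1)[None], train=False)
    return out[0].transpose(1, 2, 0)


def se_recalibrate(U: np.ndarray, reduction: int,
                   rng: np.random.Generator | None = None,
                   module: SEModule | None = None,
                   excitation_override: np.ndarray | None = None) -> np.ndarray:
    """Squeeze-and-excitation recalibration of a ``(H, W, C)`` feature map.

    ``module`` supplies trained excitation weights; otherwise a seeded
    randomly initialised bottleneck is used.  ``excitation_override`` replaces
    the excitation vector entirely (e.g. all-ones for the identity check).
    """
    U = np.asarray(U, dtype=np.float32)
    if U.ndim != 3:
        raise ValueError("U must be (H, W, C)")
    x = U.transpose(2, 0, 1)[None]
    if excitation_override is not None:
        s = np.asarray(excitation_override, dtype=np.float32).reshape(1, -1)
        out = x * s[:, :, None, None]
    else:
        se = module or SEModule(U.shape[2], reduction, rng=rng or np.random.default_rng())
        out = se.forward(x, train=False)
    return out[0].transpose(1, 2, 0)


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class Bottleneck(Module):
    """1x1 reduce -> 3x3 -> 1x1 expand, batch-normalized, SE-recalibrated,
    with an identity (or projected) shortcut."""

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 se_reduction: int, rng: np.random.Generator):
        mid = out_channels // 4
        self.conv1 = Conv2d(in_channels, mid, 1, rng=rng)
        self.bn1 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, mid, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.conv3 = Conv2d(mid, out_channels, 1, rng=rng)
        self.bn3 = BatchNorm2d(out_channels)
        self.relu1, self.relu2, self.relu_out = ReLU(), ReLU(), ReLU()
        self.se = SEModule(out_channels, se_reduction, rng=rng)
        if stride != 1 or in_channels != out_channels:
            self.proj = Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm2d(out_channels)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.relu2.forward(self.bn2.forward(self.conv2.forward(out, train), train), train)
        out = self.bn3.forward(self.conv3.forward(out, train), train)
        out = self.se.forward(out, train)
        shortcut = x if self.proj is None else self.proj_bn.forward(
            self.proj.forward(x, train), train)
        return self.relu_out.forward(out + shortcut, train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gout)
        gmain = self.se.backward(g)
        gmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self.relu2.backward(
                self.conv3.backward(self.bn3.backward(gmain))))))))
        if self.proj is None:
            gshort = g
        else:
            gshort = self.proj.backward(self.proj_bn.backward(g))
        return gmain + gshort


class SEResNet(Module):
    """The full regressor; build with :func:`build_model`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.stem = Conv2d(spec.in_channels, spec.stem_channels, spec.stem_kernel,
                           stride=spec.stem_stride, padding=spec.stem_padding, rng=rng)
        self.stem_bn = BatchNorm2d(spec.stem_channels)
        self.stem_relu = ReLU()
        self.pool = MaxPool2d(spec.pool_kernel, spec.pool_stride, spec.pool_padding)
        self.blocks: list[Bottleneck] = []
        in_c = spec.stem_channels
        for stage, (count, out_c) in enumerate(zip(spec.stage_blocks, spec.stage_channels)):
            for b in range(count):
                stride = 2 if (stage > 0 and b == 0) else 1
                self.blocks.append(
                    Bottleneck(in_c, out_c, stride, spec.se_reduction, rng)
                )
                in_c = out_c
        assert in_c == spec.head_in  # channel count entering the head
        self.gap = GlobalAvgPool2d()
        self.fc1 = Dense(spec.head_in, spec.head_widths[0], rng=rng)
        self.fc1_relu = ReLU()
        self.fc2 = Dense(spec.head_widths[0], spec.head_widths[1], rng=rng)
        # filled in by train_model
        self.y_stats: StandardizeStats | None = None
        self.x_stats: tuple[np.ndarray, np.ndarray] | None = None
        self.analyte_names: tuple[str, ...] | None = None

    # --- ablation switch -------------------------------------------------
    def pin_excitations(self, pinned: bool = True) -> None:
        """Force every excitation vector to 1 (plain residual network)."""
        for block in self.blocks:
            block.se.pinned = pinned

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected (N, {self.spec.in_channels}, H, W) input, got {x.shape}"
            )
        out = self.stem_relu.forward(self.stem_bn.forward(
            self.stem.forward(x, train), train), train)
        out = self.pool.forward(out, train)
        for block in self.blocks:
            out = block.forward(out, train)
        out = self.gap.forward(out, train)
        out = self.fc1_relu.forward(self.fc1.forward(out, train), train)
        return self.fc2.forward(out, train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.fc1.backward(self.fc1_relu.backward(self.fc2.backward(gout)))
        g = self.gap.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(
            self.pool.backward(g))))
        return g


def build_model(spec: ArchitectureSpec, seed: int = 0) -> SEResNet:
    """Construct the network described by ``spec`` (deterministic per seed)."""
    return SEResNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

def _apply_input_norm(X: np.ndarray,
                      stats: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Per-pixel affine map on the channel axis: ``x' = (x - mu) @ W``."""
    mu, W = stats
    Xc = X - mu[None, :, None, None]
    return np.einsum("nchw,cd->ndhw", Xc, W).astype(np.float32)


def _records_to_arrays(records: list[SampleRecord]) -> tuple[np.ndarray, np.ndarray]:
    patches, targets = [], []
    for rec in records:
        if rec.patch is None:
            raise ValueError(f"record {rec.sample_id!r} has no image patch")
        if rec.concentrations is None:
            raise ValueError(f"record {rec.sample_id!r} has no reference values")
        patches.append(np.asarray(rec.patch, dtype=np.float32).transpose(2, 0, 1))
        targets.append(rec.concentrations)
    return np.stack(patches), np.stack(targets).astype(np.float64)


def train_model(
    model: SEResNet,
    records: list[SampleRecord],
    config: TrainConfig,
) -> tuple[SEResNet, list[float]]:
    """Minimize MSE on z-scored targets with mini-batch Adam.

    Returns the trained model and the per-epoch training-loss history.
    Deterministic for a fixed seed, data and thread configuration.
    """
    if len(records) < 2:
        raise ValueError("need >= 2 records to train")
    X, Y = _records_to_arrays(records)
    _, y_stats = standardize(Y)
    Z = y_stats.transform(Y).astype(np.float32)
    model.y_stats = y_stats
    model.analyte_names = records[0].analyte_names

    # input normalization over the training pixels.  "channel" z-scores each
    # band; "zca" whitens across bands, which rescues weak spectral
    # directions (trace analytes) that per-band scaling leaves ~50x smaller
    # than the dominant ones.
    if config.input_norm not in ("zca", "channel", "none"):
        raise ValueError(f"unknown input_norm {config.input_norm!r}")
    if config.input_norm != "none":
        pix = X.transpose(0, 2, 3, 1).reshape(-1, X.shape[1]).astype(np.float64)
        mu = pix.mean(axis=0)
        if config.input_norm == "zca":
            cov = np.cov(pix - mu, rowvar=False)
            lam, U = np.linalg.eigh(cov)
            shrink = config.zca_shrinkage * lam.max()
            W = U @ np.diag(1.0 / np.sqrt(lam + shrink)) @ U.T
        else:
            W = np.diag(1.0 / np.maximum(pix.std(axis=0, ddof=0), 1e-6))
        model.x_stats = (mu.astype(np.float32), W.astype(np.float32))
        X = _apply_input_norm(X, model.x_stats)

    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.validation_fraction * len(X)))
    order0 = rng.permutation(len(X))
    val_idx, train_idx = order0[:n_val], order0[n_val:]
    Xt, Zt = X[train_idx], Z[train_idx]

    opt = Adam(model.params(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    params = model.params()
    ema = [p.value.copy() for p in params] if config.ema_decay > 0 else None
    history: list[float] = []
    best_val, patience_left = np.inf, config.early_stopping_patience
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine" and config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            floor = config.learning_rate / 50.0
            opt.lr = floor + 0.5 * (config.learning_rate - floor) * (
                1.0 + np.cos(np.pi * frac)
            )
        order = rng.permutation(len(Xt))
        epoch_loss, seen = 0.0, 0
        for lo in range(0, len(Xt), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, zb = Xt[idx], Zt[idx]
            if config.augment_flips:
                flips = rng.integers(0, 4, size=len(idx))
                xb = xb.copy()
                for b, f in enumerate(flips):
                    if f & 1:
                        xb[b] = xb[b, :, ::-1, :]
                    if f & 2:
                        xb[b] = xb[b, :, :, ::-1]
            if config.augment_noise_sd > 0:
                xb = xb + rng.normal(
                    0.0, config.augment_noise_sd, size=xb.shape
                ).astype(np.float32)
            if config.mixup_alpha > 0 and len(idx) > 1:
                lam = rng.beta(config.mixup_alpha, config.mixup_alpha,
                               size=len(idx)).astype(np.float32)
                perm = rng.permutation(len(idx))
                xb = lam[:, None, None, None] * xb + (1 - lam)[:, None, None, None] * xb[perm]
                zb = lam[:, None] * zb + (1 - lam)[:, None] * zb[perm]
            pred = model.forward(xb, train=True)
            err = pred - zb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            opt.zero_grad()
            model.backward((2.0 / err.size) * err.astype(np.float32))
            opt.step()
            if ema is not None:
                d = config.ema_decay
                for e, p in zip(ema, params):
                    e *= d
                    e += (1.0 - d) * p.value
            epoch_loss += loss * len(idx)
            seen += len(idx)
        history.append(epoch_loss / seen)

        if n_val and config.early_stopping_patience is not None:
            val_pred = model.forward(X[val_idx], train=False)
            val_rmse = float(np.sqrt(np.mean((val_pred - Z[val_idx]) ** 2)))
            if val_rmse < best_val - 1e-6:
                best_val, patience_left = val_rmse, config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if ema is not None:
        for e, p in zip(ema, params):
            p.value[...] = e
        _refresh_bn_stats(model, Xt, config.batch_size)
    return model, history


def _refresh_bn_stats(model: SEResNet, X: np.ndarray, batch_size: int) -> None:
    """Re-estimate batch-norm running statistics under the final weights
    (needed after Polyak averaging replaces the online weights)."""
    bns: list[BatchNorm2d] = []

    def walk(mod: Module) -> None:
        for attr in vars(mod).values():
            if isinstance(attr, BatchNorm2d):
                bns.append(attr)
            elif isinstance(attr, Module):
                walk(attr)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        walk(item)

    walk(model)
    n_batches = max(1, int(np.ceil(len(X) / batch_size)))
    for k, lo in enumerate(range(0, len(X), batch_size)):
        for bn in bns:
            bn.momentum = 1.0 / (k + 1)  # cumulative mean of batch stats
        model.forward(X[lo:lo + batch_size], train=True)
    for bn in bns:
        bn.momentum = 0.1


def predict(model: SEResNet, records_or_patches, tta_flips: bool = False) -> np.ndarray:
    """Predict concentrations in original units; rows follow input order.

    ``tta_flips`` averages the four H/V flip variants of each plate view —
    the layout carries no orientation information, so this only reduces
    prediction variance.
    """
    if model.y_stats is None:
        raise RuntimeError("model has no target-standardization stats; train first")
    if isinstance(records_or_patches, np.ndarray):
        X = records_or_patches.astype(np.float32)
        if X.ndim == 3:
            X = X[None]
        if X.shape[-1] == model.spec.in_channels and X.shape[1] != model.spec.in_channels:
            X = X.transpose(0, 3, 1, 2)
    else:
        X = np.stack([
            np.asarray(r.patch, dtype=np.float32).transpose(2, 0, 1)
            for r in records_or_patches
        ])
    if model.x_stats is not None:
        X = _apply_input_norm(X, model.x_stats)
    variants = [X]
    if tta_flips:
        variants = [X, X[:, :, ::-1, :], X[:, :, :, ::-1], X[:, :, ::-1, ::-1]]
    Z = np.zeros((len(X), model.spec.n_outputs), dtype=np.float64)
    for V in variants:
        V = np.ascontiguousarray(V)
        for lo in range(0, len(V), 64):  # bounded memory
            Z[lo:lo + 64] += model.forward(V[lo:lo + 64], train=False)
    Z /= len(variants)
    return model.y_stats.inverse(Z)


class SEResNetRegressor:
    """fit/predict wrapper so the deep model slots into the shared
    model-agnostic evaluation contract.

    ``n_members > 1`` trains a small ensemble and averages predictions.
    Members differ in initialisation/shuffling seed and alternate their mixup
    strength through ``mixup_cycle`` — mixing regularized and unregularized
    members decorrelates their error modes, which plain seed ensembles do not.
    Predictions also average the four flip variants of the plate view
    (``tta_flips``).
    """

    def __init__(self, spec: ArchitectureSpec | None = None,
                 config: TrainConfig | None = None, seed: int = 0,
                 n_members: int = 1, tta_flips: bool = True,
                 mixup_cycle: tuple[float, ...] = (0.0, 1.0)):
        self.spec = spec or ArchitectureSpec.reduced()
        self.config = config or TrainConfig(seed=seed)
        self.seed = seed
        self.n_members = int(n_members)
        self.tta_flips = tta_flips
        self.mixup_cycle = tuple(mixup_cycle)
        self.models: list[SEResNet] = []
        self.histories_: list[list[float]] = []

    @property
    def model(self) -> SEResNet | None:
        return self.models[0] if self.models else None

    def fit_records(self, records: list[SampleRecord]) -> "SEResNetRegressor":
        from dataclasses import replace as _replace

        self.models, self.histories_ = [], []
        for k in range(self.n_members):
            member_seed = self.seed + k
            alpha = (self.mixup_cycle[k % len(self.mixup_cycle)]
                     if self.n_members > 1 and self.mixup_cycle
                     else self.config.mixup_alpha)
            cfg = _replace(self.config, seed=member_seed, mixup_alpha=alpha)
            model = build_model(self.spec, seed=member_seed)
            model, hist = train_model(model, records, cfg)
            self.models.append(model)
            self.histories_.append(hist)
        return self

    def predict_records(self, records: list[SampleRecord]) -> np.ndarray:
        if not self.models:
            raise RuntimeError("model is not fitted")
        preds = [predict(m, records, tta_flips=self.tta_flips) for m in self.models]
        return np.mean(preds, axis=0)
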