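"""Training recipe: k-fold partitioning, per-fold U-Net training, ensembles,
and encoder-frozen transfer learning.

The default configuration reproduces the published recipe — Adam at learning
rate 1e-4, binary cross-entropy loss with the Dice score monitored on the
validation fold, batch size 50, 30 epochs, 5 folds at an 80/20 split.  A
``scaled_profile`` (64x64 slices, base 8 filters, depth 3, 2 folds, 5 epochs,
lr 1e-3) keeps the full pipeline runnable in minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ArchitectureError
from .nn import Adam, UNet, is_encoder_param

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "FoldEnsemble",
    "make_folds",
    "train_fold",
    "train_kfold",
    "transfer_retrain",
    "scaled_profile",
]


@dataclass
class UNetConfig:
    """Architecture knobs.  The canonical layout: ``depth`` pooling levels,
    two 3x3 conv + ReLU per block, 2x2 max pooling, transposed-convolution
    upsampling, skip concatenation, 1x1 sigmoid head."""

    depth: int = 4
    base_filters: int = 32

    def build(self, dtype=np.float32) -> UNet:
        return UNet(self.depth, self.base_filters, dtype=dtype)

    @property
    def pad_multiple(self) -> int:
        return 2**self.depth


@dataclass
class TrainConfig:
    """Optimization recipe (Adam + binary cross-entropy, Dice monitored)."""

    learning_rate: float = 1e-4
    batch_size: int = 50
    epochs: int = 30
    n_folds: int = 5
    train_fraction: float = 0.8
    seed: int = 0
    keep: str = "best"  # weights kept per fold: 'best' validation DSC or 'last'

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.keep not in ("best", "last"):
            raise ValueError("keep must be 'best' or 'last'")


def scaled_profile() -> tuple[UNetConfig, TrainConfig]:
    """Reduced profile for CPU-scale runs: 64x64 slices, base 8 filters,
    depth 3, 2 folds, 5 epochs.  The small-batch (3), higher-rate (2e-3)
    optimizer setting compensates for the short epoch budget."""
    return (
        UNetConfig(depth=3, base_filters=8),
        TrainConfig(learning_rate=2e-3, batch_size=3, epochs=5, n_folds=2),
    )


def make_folds(subject_ids: list, n_folds: int = 5, seed: int = 0) -> list[tuple[list, list]]:
    """Subject-level k-fold partition.

    All slices of one scan stay on one side of every fold; each subject is in
    exactly one validation set across folds, and validation sizes differ by at
    most one.  Deterministic given the seed.
    """
    ids = list(subject_ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} subjects, got {len(ids)}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    parts = np.array_split(order, n_folds)
    folds = []
    for i in range(n_folds):
        val = [ids[j] for j in parts[i]]
        train = [ids[j] for k, part in enumerate(parts) if k != i for j in part]
        folds.append((train, val))
    return folds


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_batch(slices: np.ndarray) -> np.ndarray:
    """(n, H, W) -> (n, 1, H, W)."""
    return slices[:, None].astype(np.float32)


def _global_dice(pred: np.ndarray, target: np.ndarray) -> float:
    """Dice over all voxels of a slice collection (binarized at 0.5)."""
    a = pred >= 0.5
    b = target >= 0.5
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def train_fold(
    train_slices: np.ndarray,
    train_masks: np.ndarray,
    val_slices: np.ndarray,
    val_masks: np.ndarray,
    uc: UNetConfig,
    tc: TrainConfig,
    log=None,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Train one fold; returns (weights, per-epoch history).

    History entries carry the epoch's mean training loss and the validation
    loss/DSC.  The returned weights are the best-validation-DSC epoch by
    default (``tc.keep``).
    """
    from .nn import functional as F

    if train_slices.min() < -1e-6 or train_slices.max() > 1 + 1e-6:
        raise ValueError("training slices must be normalized to [0, 1]")
    net = uc.build()
    m = uc.pad_multiple
    if train_slices.shape[1] % m or train_slices.shape[2] % m:
        raise ArchitectureError(
            f"slice size {train_slices.shape[1:]} not divisible by 2**depth={m}"
        )
    rng = np.random.default_rng(tc.seed)
    params = net.init_params(seed=int(rng.integers(2**31)))
    # start the head at the logit of the foreground prevalence: with ~5-10%
    # lung pixels, unlearned regions then default to "not lung" instead of
    # 0.5, which stabilises early training and keeps uncertain background
    # from straddling the binarization threshold
    prev = float(np.clip(train_masks.mean(), 1e-4, 1 - 1e-4))
    params["head.b"] = np.full_like(params["head.b"], np.log(prev / (1 - prev)))
    opt = Adam(lr=tc.learning_rate)
    x = _as_batch(train_slices)
    y = _as_batch(train_masks)
    xv = _as_batch(val_slices)
    yv = val_masks
    history: list[dict] = []
    best = (-1.0, None)
    n = x.shape[0]
    if log:
        log(f"training: {n} slices, batch={tc.batch_size}, epochs={tc.epochs}, lr={tc.learning_rate}")
    for epoch in range(1, tc.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for k in range(0, n, tc.batch_size):
            sel = order[k : k + tc.batch_size]
            logits, cache = net.forward(params, x[sel])
            loss, dz = F.bce_loss_and_grad(logits, y[sel])
            grads = net.backward(params, cache, dz)
            opt.step(params, grads)
            losses.append(loss)
        vprob = np.clip(net.predict_proba(params, xv)[:, 0], 1e-7, 1 - 1e-7)
        vloss = float(-(yv * np.log(vprob) + (1 - yv) * np.log(1 - vprob)).mean())
        vdsc = _global_dice(vprob, yv)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_loss": vloss, "val_dsc": vdsc})
        if log:
            log(f"epoch {epoch}/{tc.epochs}: loss={np.mean(losses):.4f} val_dsc={vdsc:.4f}")
        if vdsc > best[0]:
            best = (vdsc, {k: v.copy() for k, v in params.items()})
    if tc.keep == "best" and best[1] is not None:
        params = best[1]
    return params, history


@dataclass
class FoldEnsemble:
    """Ordered collection of per-fold weight sets plus the configuration that
    produced them."""

    weights: list[dict[str, np.ndarray]]
    unet_config: UNetConfig
    train_config: TrainConfig
    histories: list[list[dict]] = field(default_factory=list)

    def __post_init__(self):
        for w in self.weights:
            self.unet_config.build().check_params(w)

    def __len__(self) -> int:
        return len(self.weights)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, w in enumerate(self.weights):
            np.savez(directory / f"fold{i}.npz", **w)
        sidecar = {
            "unet_config": asdict(self.unet_config),
            "train_config": asdict(self.train_config),
            "n_folds": len(self.weights),
            "histories": self.histories,
        }
        (directory / "ensemble.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "FoldEnsemble":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        weights = []
        for i in range(meta["n_folds"]):
            with np.load(directory / f"fold{i}.npz") as npz:
                weights.append({k: npz[k] for k in npz.files})
        return cls(
            weights,
            UNetConfig(**meta["unet_config"]),
            TrainConfig(**meta["train_config"]),
            meta.get("histories", []),
        )


def _gather(data: dict, ids: list) -> tuple[np.ndarray, np.ndarray]:
    xs = np.concatenate([data[i][0] for i in ids], axis=0)
    ys = np.concatenate([data[i][1] for i in ids], axis=0)
    return xs, ys


def train_kfold(
    data: dict[object, tuple[np.ndarray, np.ndarray]],
    uc: UNetConfig,
    tc: TrainConfig,
    log=None,
) -> FoldEnsemble:
    """Train the network once per fold of a subject-level k-fold split.

    ``data`` maps subject id -> (slices (n, H, W) in [0, 1], masks (n, H, W)
    binary).  Returns the ensemble of ``tc.n_folds`` weight sets.
    """
    folds = make_folds(sorted(data, key=str), tc.n_folds, tc.seed)
    weights, histories = [], []
    for f, (train_ids, val_ids) in enumerate(folds):
        if log:
            log(f"fold {f + 1}/{len(folds)}: {len(train_ids)} train / {len(val_ids)} val subjects")
        xt, yt = _gather(data, train_ids)
        xv, yv = _gather(data, val_ids)
        ftc = TrainConfig(**{**asdict(tc), "seed": tc.seed + f})
        w, h = train_fold(xt, yt, xv, yv, uc, ftc, log=log)
        weights.append(w)
        histories.append(h)
    return FoldEnsemble(weights, uc, tc, histories)


def transfer_retrain(
    base: dict[str, np.ndarray],
    new_data: dict[object, tuple[np.ndarray, np.ndarray]],
    uc: UNetConfig,
    tc: TrainConfig,
    freeze_encoder: bool = True,
    log=None,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Adapt trained weights to a new dataset (e.g. a different resolution).

    With ``freeze_encoder`` (the default) every encoder parameter — all
    blocks up to and including the bottleneck — is left bitwise unchanged and
    only the decoder is optimized.  A held-out split is carved from
    ``new_data`` (one fold of ``tc.n_folds``) for epoch monitoring.
    """
    from .nn import functional as F

    net = uc.build()
    net.check_params(base)
    params = {k: v.copy() for k, v in base.items()}
    ids = sorted(new_data, key=str)
    if len(ids) >= tc.n_folds:
        train_ids, val_ids = make_folds(ids, tc.n_folds, tc.seed)[0]
    else:
        train_ids = val_ids = ids
    xt, yt = _gather(new_data, train_ids)
    xv, yv = _gather(new_data, val_ids)
    trainable = (lambda name: not is_encoder_param(name)) if freeze_encoder else None
    opt = Adam(lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed)
    x, y = _as_batch(xt), _as_batch(yt)
    history = []
    for epoch in range(1, tc.epochs + 1):
        order = rng.permutation(x.shape[0])
        losses = []
        for k in range(0, x.shape[0], tc.batch_size):
            sel = order[k : k + tc.batch_size]
            logits, cache = net.forward(params, x[sel])
            loss, dz = F.bce_loss_and_grad(logits, y[sel])
            grads = net.backward(params, cache, dz)
            opt.step(params, grads, trainable=trainable)
            losses.append(loss)
        vprob = net.predict_proba(params, _as_batch(xv))[:, 0]
        vdsc = _global_dice(vprob, yv)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_dsc": vdsc})
        if log:
            log(f"transfer epoch {epoch}/{tc.epochs}: loss={np.mean(losses):.4f} val_dsc={vdsc:.4f}")
    return params, history
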