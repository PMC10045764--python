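"""Joint L1-L2 loss and the patch-based training loop.

The training objective is a linear combination of an L2 term (half the sum of
squared differences between denoised and reference patches) and an L1 term
(sum of absolute differences) weighted by ``lambda_l1``:

    L = sum_n 1/2 * ||d_n - r_n||_2^2 + lambda * sum_n ||d_n - r_n||_1

The L2 term favours aggressive noise removal at the cost of smoothing; the
L1 term preserves edges but leaves residual noise; the joint loss trades the
two off, with lambda = 4 the preset that balances denoising against rectal
wall delineation.  Per batch the sums are divided by the batch size so that
lambda keeps the same meaning at any batch size.

The network learns the *residual* (the noise): the loss is evaluated on
``denoised = noisy - predicted_residual`` against the reference, and its
gradient is backpropagated through the subtraction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .containers import PatchTriple
from .nn import Adam, NetConfig, ResidualDenoiser, build_network
from .pipeline import dihedral, extract_patches

__all__ = [
    "LossConfig",
    "TrainConfig",
    "TrainHistory",
    "TrainingDiverged",
    "joint_l1_l2_loss",
    "loss_gradient",
    "SplitDataset",
    "prepare_dataset",
    "train",
]

_MODES = ("l2_only", "l1_only", "joint")


@dataclass
class LossConfig:
    """Loss-mode selection: pure L2, pure L1, or the weighted combination."""

    mode: str = "joint"
    lambda_l1: float = 4.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")

    @property
    def effective_lambda(self) -> float:
        return 0.0 if self.mode == "l2_only" else self.lambda_l1


def joint_l1_l2_loss(d: np.ndarray, r: np.ndarray, config: LossConfig) -> float:
    """Scalar loss summed over all pixels of all batch items.

    joint:   1/2 * sum((d-r)^2) + lambda * sum(|d-r|)
    l2_only: 1/2 * sum((d-r)^2)
    l1_only: sum(|d-r|)
    """
    d = np.asarray(d)
    r = np.asarray(r)
    if d.shape != r.shape:
        raise ValueError(f"shape mismatch: {d.shape} vs {r.shape}")
    diff = (d - r).astype(np.float64)
    l2 = 0.5 * float(np.sum(diff * diff))
    l1 = float(np.sum(np.abs(diff)))
    if config.mode == "l2_only":
        return l2
    if config.mode == "l1_only":
        return l1
    return l2 + config.lambda_l1 * l1


def loss_gradient(d: np.ndarray, r: np.ndarray, config: LossConfig) -> np.ndarray:
    """dL/dd for the configured loss (sum reduction, no batch scaling)."""
    diff = d - r
    if config.mode == "l2_only":
        return diff
    if config.mode == "l1_only":
        return np.sign(diff)
    return diff + config.lambda_l1 * np.sign(diff)


@dataclass
class TrainConfig:
    """Optimization schedule.

    Defaults follow the published schedule (18 epochs, validation every 3rd
    epoch); batch size 32 and Adam at 1e-3 are this package's conventions.
    ``train_nex`` lists the noisy NEX levels whose patches are pooled into
    one training set, producing a single network applicable to all of them.
    """

    epochs: int = 18
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    validation_period: int = 3
    patch_size: int = 60
    patch_stride: int = 20
    train_nex: tuple[int, ...] = (1, 2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.validation_period < 1:
            raise ValueError("validation_period must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["train_nex"] = list(self.train_nex)
        return d


@dataclass
class TrainHistory:
    """Loss trajectory: per-epoch training loss, periodic validation loss."""

    train_loss: list[tuple[int, float]] = field(default_factory=list)
    val_loss: list[tuple[int, float]] = field(default_factory=list)
    checkpoint_path: str | None = None

    @property
    def final_val_loss(self) -> float | None:
        return self.val_loss[-1][1] if self.val_loss else None


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class SplitDataset:
    """(series, ground-truth) pairs split into training and validation sets.

    Series are expected in training normalization (reference max = 1); use
    :func:`prepare_dataset` to build one from :func:`phantom.make_dataset`
    output.
    """

    train: list
    val: list

    def __post_init__(self) -> None:
        if not self.train or not self.val:
            raise ValueError("dataset needs >= 1 training and >= 1 validation subject")


def prepare_dataset(pairs, n_val: int) -> SplitDataset:
    """Normalize every series and split the last ``n_val`` subjects off as validation."""
    from .pipeline import normalize_series

    norm = [(normalize_series(s), gt) for s, gt in pairs]
    if n_val < 1 or n_val >= len(norm):
        raise ValueError("n_val must leave at least one training subject")
    return SplitDataset(train=norm[:-n_val], val=norm[-n_val:])


def _collect_patches(series_list, cfg: TrainConfig) -> list[PatchTriple]:
    patches: list[PatchTriple] = []
    for series, _gt in series_list:
        for nex in cfg.train_nex:
            patches.extend(extract_patches(series, nex, cfg.patch_size, cfg.patch_stride))
    return patches


def _batch_arrays(patches, idx, rng, augment: bool, dtype):
    """Assemble (x, target_residual) batch arrays, with per-patch dihedral ops."""
    noisy = np.stack([patches[i].noisy_patch for i in idx])
    guide = np.stack([patches[i].guide_patch for i in idx])
    ref = np.stack([patches[i].reference_patch for i in idx])
    if augment:
        ops = rng.integers(0, 8, size=len(idx))
        noisy = np.stack([dihedral(n, o) for n, o in zip(noisy, ops)])
        guide = np.stack([dihedral(g, o) for g, o in zip(guide, ops)])
        ref = np.stack([dihedral(r, o) for r, o in zip(ref, ops)])
    x = np.stack([noisy, guide], axis=1).astype(dtype)
    return x, noisy.astype(dtype), ref.astype(dtype)


def _epoch_validation_loss(net, patches, loss_config, cfg, dtype) -> float:
    total = 0.0
    n_items = 0
    for start in range(0, len(patches), cfg.batch_size):
        idx = range(start, min(start + cfg.batch_size, len(patches)))
        x, noisy, ref = _batch_arrays(patches, list(idx), None, augment=False, dtype=dtype)
        residual = net.forward(x, training=False)[:, 0]
        denoised = noisy - residual
        total += joint_l1_l2_loss(denoised, ref, loss_config)
        n_items += len(list(idx))
    return total / max(n_items, 1)


def train(
    dataset: SplitDataset,
    net_config: NetConfig,
    loss_config: LossConfig,
    train_config: TrainConfig,
    log=None,
    epoch_callback=None,
) -> tuple[ResidualDenoiser, TrainHistory]:
    """Mini-batch training of the residual denoiser on patch triples.

    Fully seeded: network initialization from ``net_config.seed``, data order
    and augmentation from ``train_config.seed``.  Validation loss (per-patch
    average of the configured loss) is recorded at every
    ``validation_period``-th epoch.  Raises :class:`TrainingDiverged` on a
    non-finite loss.
    """
    cfg = train_config
    net = build_network(net_config)
    opt = Adam(net, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    dtype = np.dtype(net_config.dtype)

    train_patches = _collect_patches(dataset.train, cfg)
    val_patches = _collect_patches(dataset.val, cfg)
    if not train_patches:
        raise ValueError("no training patches")

    history = TrainHistory()
    n = len(train_patches)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, n - n % cfg.batch_size or n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) == 0:
                break
            x, noisy, ref = _batch_arrays(train_patches, idx, rng, augment=True, dtype=dtype)
            residual = net.forward(x, training=True)[:, 0]
            denoised = noisy - residual
            batch_loss = joint_l1_l2_loss(denoised, ref, loss_config) / len(idx)
            if not np.isfinite(batch_loss):
                raise TrainingDiverged(
                    f"non-finite loss {batch_loss} at epoch {epoch}, step {start // cfg.batch_size}"
                )
            # dL/d(residual) = -dL/d(denoised), scaled to batch-size invariance
            g = -(loss_gradient(denoised, ref, loss_config) / len(idx)).astype(dtype)
            net.backward(g[:, None, :, :])
            opt.step()
            epoch_loss += batch_loss * len(idx)
            n_seen += len(idx)
        history.train_loss.append((epoch, epoch_loss / max(n_seen, 1)))
        if log:
            log(f"epoch={epoch} train_loss={epoch_loss / max(n_seen, 1):.5f}")
        if epoch % cfg.validation_period == 0:
            vl = _epoch_validation_loss(net, val_patches, loss_config, cfg, dtype)
            history.val_loss.append((epoch, vl))
            if log:
                log(f"epoch={epoch} val_loss={vl:.5f}")
        if epoch_callback:
            epoch_callback(net, epoch, history)
    return net, history
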