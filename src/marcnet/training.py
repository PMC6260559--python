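"""Patch sampling, the residual loss, and the Adam training loop.

Training follows the denoising-CNN recipe: 50x50 patches are sampled
uniformly at random from the artifact-insert slices of the training split,
and the network is fit with Adam (lr 0.01, betas 0.9/0.999, weight decay
1e-5, batch 64) to minimize

    L(theta) = 1/(2N) sum_i || R(p_i_insert; theta) - target_i ||_F^2

where the target is the artifact residual ``p_insert - p_free`` in residual
mode, or the clean patch ``p_free`` directly in the ordinary-learning
ablation.  Images enter the network mapped from the HU display window onto
[0, 1]; metal saturates at the window top, which is itself the cue the
network uses to localize the implant.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .artifact_sim import Dataset, TripletSample
from .network import (
    NetworkSpec,
    TrainState,
    backward,
    forward,
    hu_to_unit,
    init_weights,
)

__all__ = [
    "PatchPair",
    "Patches",
    "TrainConfig",
    "TrainResult",
    "TrainingDiverged",
    "extract_patches",
    "loss",
    "loss_and_grad",
    "adam_step",
    "train",
]

ADAM_EPS = 1e-8


class TrainingDiverged(RuntimeError):
    """Raised when the loss or parameters become non-finite."""


@dataclass
class PatchPair:
    """One co-located (artifact-insert, artifact-free) patch pair, HU scale."""

    p_insert: np.ndarray
    p_free: np.ndarray

    def __post_init__(self) -> None:
        if self.p_insert.shape != self.p_free.shape:
            raise ValueError("patch pair must be co-located and equally sized")


@dataclass
class Patches:
    """A batch of patch pairs as dense arrays plus their source coordinates."""

    insert: np.ndarray  # (n, s, s) HU
    free: np.ndarray  # (n, s, s) HU
    coords: np.ndarray  # (n, 3): slice index, row, col

    def __len__(self) -> int:
        return len(self.insert)

    def pairs(self):
        for i in range(len(self)):
            yield PatchPair(self.insert[i], self.free[i])


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the reference protocol)."""

    patch_size: int = 50
    learning_rate: float = 0.01
    weight_decay: float = 1e-5
    adam_betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 64
    epochs: int = 100
    patches_per_slice: int = 100
    n_patches: int | None = None  # overrides patches_per_slice * n_slices
    val_patches: int = 512
    mode: str = "residual"  # residual | ordinary
    seed: int = 0
    # network
    depth: int = 17
    n_filters: int = 64
    kernel: int = 3
    bn_enabled: bool = True
    dtype: str = "float32"
    lr_decay_every: int | None = None  # optional step decay (epochs)
    lr_decay_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("residual", "ordinary"):
            raise ValueError("mode must be 'residual' or 'ordinary'")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if not all(0 < b < 1 for b in self.adam_betas):
            raise ValueError("adam betas must lie in (0, 1)")

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(self.depth, self.n_filters, self.kernel, self.bn_enabled)


@dataclass
class TrainResult:
    state: TrainState  # best-validation checkpoint
    final_state: TrainState
    history: dict


def extract_patches(
    triplets: list[TripletSample],
    patch_size: int,
    n_total: int,
    seed: int,
) -> Patches:
    """Sample ``n_total`` patch pairs with uniformly random top-left corners
    over all slices; fully inside the image and deterministic given seed."""
    if not triplets:
        raise ValueError("empty split")
    h, w = triplets[0].artifact_free.shape
    if patch_size > min(h, w):
        raise ValueError(f"patch size {patch_size} exceeds image size {h}x{w}")
    rng = np.random.default_rng(seed)
    s = patch_size
    idx = rng.integers(0, len(triplets), size=n_total)
    rows = rng.integers(0, h - s + 1, size=n_total)
    cols = rng.integers(0, w - s + 1, size=n_total)
    insert = np.empty((n_total, s, s))
    free = np.empty((n_total, s, s))
    for i, (t, r, c) in enumerate(zip(idx, rows, cols)):
        trip = triplets[t]
        insert[i] = trip.artifact_insert.values[r : r + s, c : c + s]
        free[i] = trip.artifact_free.values[r : r + s, c : c + s]
    return Patches(insert, free, np.stack([idx, rows, cols], axis=1))


def _targets(insert_unit: np.ndarray, free_unit: np.ndarray, mode: str) -> np.ndarray:
    if mode == "residual":
        return insert_unit - free_unit
    if mode == "ordinary":
        return free_unit
    raise ValueError("mode must be 'residual' or 'ordinary'")


def loss(
    state: TrainState,
    insert: np.ndarray,
    free: np.ndarray,
    mode: str = "residual",
    bn_mode: str = "eval",
) -> float:
    """Residual Frobenius loss 1/(2N) sum ||R(p_insert) - target||^2."""
    if len(insert) == 0:
        raise ValueError("empty batch")
    x = hu_to_unit(insert)
    t = _targets(x, hu_to_unit(free), mode)
    out = forward(state, x, mode=bn_mode)
    val = float(np.sum((out - np.asarray(t, dtype=out.dtype)) ** 2) / (2.0 * len(insert)))
    if not np.isfinite(val):
        raise TrainingDiverged("non-finite loss")
    return val


def loss_and_grad(
    state: TrainState,
    insert: np.ndarray,
    free: np.ndarray,
    mode: str = "residual",
    bn_mode: str = "train",
):
    """Loss plus analytic gradients w.r.t. every trainable parameter."""
    if len(insert) == 0:
        raise ValueError("empty batch")
    x = hu_to_unit(insert)
    t = _targets(x, hu_to_unit(free), mode)
    out, cache = forward(state, x, mode=bn_mode, want_cache=True)
    diff = out - np.asarray(t, dtype=out.dtype)
    n = len(insert)
    val = float(np.sum(diff**2) / (2.0 * n))
    if not np.isfinite(val):
        raise TrainingDiverged("non-finite loss in forward pass")
    grads = backward(state, cache, diff / n)
    return val, grads


def adam_step(
    state: TrainState,
    grads: dict[str, np.ndarray],
    config: TrainConfig,
    t: int,
    lr: float | None = None,
) -> TrainState:
    """One in-place Adam update with bias-corrected moments.

    L2 weight decay is added to the convolution-weight gradients only
    (biases and batch-norm affine parameters are not decayed).
    """
    if t < 1:
        raise ValueError("step index must be >= 1")
    b1, b2 = config.adam_betas
    lr = config.learning_rate if lr is None else lr
    for key, g in grads.items():
        p = state.params[key]
        if config.weight_decay and key.startswith("W"):
            g = g + config.weight_decay * p
        m = state.adam_m.get(key)
        v = state.adam_v.get(key)
        if m is None:
            m = np.zeros_like(p)
            v = np.zeros_like(p)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g**2
        state.adam_m[key] = m
        state.adam_v[key] = v
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        p -= (lr * mhat / (np.sqrt(vhat) + ADAM_EPS)).astype(p.dtype)
    state.adam_t = t
    return state


def train(config: TrainConfig, dataset: Dataset) -> TrainResult:
    """Train on the dataset's train split with per-epoch validation.

    Mini-batches are reshuffled each epoch; the best-validation state is
    checkpointed.  Divergence (non-finite loss/parameters) aborts with
    :class:`TrainingDiverged` rather than silently clipping.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(4)]
    init_seed, patch_seed, val_seed, shuffle_seed = seeds

    train_split = dataset.split("train")
    val_split = dataset.split("val")
    if not train_split or not val_split:
        raise ValueError("dataset must provide train and validation splits")

    n_patches = config.n_patches or config.patches_per_slice * len(train_split)
    patches = extract_patches(train_split, config.patch_size, n_patches, patch_seed)
    vp = extract_patches(val_split, config.patch_size, config.val_patches, val_seed)

    dtype = np.dtype(config.dtype).type
    state = init_weights(config.network_spec(), init_seed, dtype=dtype)
    state.mode = config.mode
    state.rng_seed = config.seed

    insert_u = hu_to_unit(patches.insert).astype(dtype)
    free_u = hu_to_unit(patches.free).astype(dtype)
    targets = _targets(insert_u, free_u, config.mode)
    val_insert = vp.insert
    val_free = vp.free

    shuffle_rng = np.random.default_rng(shuffle_seed)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    history["initial_val_loss"] = loss(state, val_insert, val_free, config.mode)
    best_val = np.inf
    best_state = None
    t = state.adam_t
    lr = config.learning_rate
    for epoch in range(1, config.epochs + 1):
        if config.lr_decay_every and epoch > 1 and (epoch - 1) % config.lr_decay_every == 0:
            lr *= config.lr_decay_factor
        order = shuffle_rng.permutation(n_patches)
        epoch_losses = []
        for start in range(0, n_patches, config.batch_size):
            sel = order[start : start + config.batch_size]
            x = insert_u[sel]
            tgt = targets[sel]
            out, cache = forward(state, x, mode="train", want_cache=True)
            diff = out - tgt
            lval = float(np.sum(diff**2) / (2.0 * len(sel)))
            if not np.isfinite(lval):
                raise TrainingDiverged(f"loss diverged at epoch {epoch}, step {t + 1}")
            grads = backward(state, cache, diff / len(sel))
            t += 1
            adam_step(state, grads, config, t, lr=lr)
            epoch_losses.append(lval)
        if not state.check_finite():
            raise TrainingDiverged(f"non-finite parameters after epoch {epoch}")
        state.epoch = epoch
        vloss = loss(state, val_insert, val_free, config.mode)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(vloss)
        history["lr"].append(lr)
        if vloss < best_val:
            best_val = vloss
            best_state = copy.deepcopy(state)
    assert best_state is not None
    return TrainResult(state=best_state, final_state=state, history=history)
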