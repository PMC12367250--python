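"""Training loop: composite soft-Dice + cross-entropy loss, SGD-Nesterov,
poly learning-rate decay, and optional deep supervision.

Reference schedule: 200 epochs of 250 minibatches at batch size 10, initial
learning rate 0.01 decayed as ``lr0 * (1 - epoch/epochs)**0.9``, Nesterov
momentum 0.99, He initialization.  Desk-scale runs shrink epochs/minibatches
through the same config.  Minibatches draw slices uniformly with replacement
so the minibatch count per epoch is independent of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .imgio import DualVolume, znormalize
from .phantom import PhantomCase
from .unet import SegmentationModel, predict_volume, softmax


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    minibatches_per_epoch: int = 250
    batch_size: int = 10
    lr0: float = 0.01
    momentum: float = 0.99
    poly_power: float = 0.9
    deep_supervision: bool = False
    ds_weights: Optional[Tuple[float, ...]] = None
    input_mode: str = "dual"  # dual | fat | water (ablation variants)
    val_every: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.minibatches_per_epoch < 1 or self.batch_size < 1:
            raise ValueError("epochs, minibatches and batch size must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.input_mode not in ("dual", "fat", "water"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.ds_weights is not None:
            w = np.asarray(self.ds_weights, dtype=float)
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("ds_weights must sum to 1")


def poly_lr(epoch: int, config: TrainConfig) -> float:
    """lr = lr0 * (1 - epoch/epochs)**poly_power; monotone to 0."""
    if not 0 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs}]")
    return config.lr0 * (1.0 - epoch / config.epochs) ** config.poly_power


def default_ds_weights(n_scales: int) -> Tuple[float, ...]:
    """Weights halving per coarser resolution, normalized to sum 1."""
    raw = np.array([0.5 ** i for i in range(n_scales)])
    return tuple(raw / raw.sum())


DICE_EPS = 1e-5


def _loss_and_grad(
    scores: np.ndarray, target: np.ndarray, eps: float = DICE_EPS,
) -> Tuple[float, np.ndarray]:
    """Composite loss and its gradient w.r.t. the unnormalized scores.

    Soft Dice is pooled over batch and space, averaged over foreground
    classes; cross-entropy is the mean over all voxels.  The two terms are
    equally weighted.
    """
    b, k, h, w = scores.shape
    if target.shape != (b, h, w):
        raise ValueError(f"target shape {target.shape} incompatible with scores")
    if int(target.max(initial=0)) >= k:
        raise ValueError("target contains class ids beyond the score channels")
    p = softmax(scores.astype(np.float64), axis=1)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, target[:, None].astype(np.int64), 1.0, axis=1)

    n_vox = b * h * w
    ce = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n_vox)
    d_p_ce = -onehot / np.clip(p, 1e-12, None) / n_vox

    inter = (p * onehot).sum(axis=(0, 2, 3))
    sums = p.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice_c = (2.0 * inter + eps) / (sums + eps)
    fg = slice(1, k)  # foreground classes only
    n_fg = k - 1
    dice_loss = float(1.0 - dice_c[fg].mean())

    d_p_dice = np.zeros_like(p)
    for c in range(1, k):
        num = 2.0 * onehot[:, c] * (sums[c] + eps) - (2.0 * inter[c] + eps)
        d_p_dice[:, c] = -(num / (sums[c] + eps) ** 2) / n_fg

    g = d_p_ce + d_p_dice
    # softmax Jacobian: dz = p * (g - sum_c g_c p_c)
    dz = p * (g - (g * p).sum(axis=1, keepdims=True))
    return dice_loss + ce, dz.astype(np.float32)


def composite_loss(scores: np.ndarray, target: np.ndarray,
                   eps: float = DICE_EPS) -> float:
    """Soft-Dice loss plus cross-entropy for one score map / label map pair."""
    loss, _ = _loss_and_grad(np.asarray(scores, dtype=np.float64),
                             np.asarray(target), eps)
    return loss


def _slice_stack(case: PhantomCase, input_mode: str) -> Tuple[np.ndarray, np.ndarray]:
    vol = znormalize(case.volume)
    if input_mode == "dual":
        x = np.stack([vol.fat, vol.water], axis=1)  # (slices, 2, H, W)
    elif input_mode == "fat":
        x = vol.fat[:, None]
    else:
        x = vol.water[:, None]
    return x.astype(np.float32), case.truth.labels.astype(np.int64)


def _downsample_target(t: np.ndarray, factor: int) -> np.ndarray:
    return t[:, ::factor, ::factor]


def validation_dsc(model: SegmentationModel, cases: Sequence[PhantomCase],
                   input_mode: str = "dual") -> float:
    """Mean foreground Dice over held-out cases (labels == channel ids)."""
    from .segmetrics import confusion_counts, dsc

    vals = []
    for case in cases:
        vol = znormalize(case.volume)
        if input_mode == "fat":
            vol = DualVolume(vol.fat, vol.fat, vol.spacing)
        elif input_mode == "water":
            vol = DualVolume(vol.water, vol.water, vol.spacing)
        pred = predict_volume(model, vol, case.truth.schema)
        for lid in case.truth.schema.label_ids:
            vals.append(dsc(confusion_counts(pred, case.truth, {lid})))
    return float(np.mean(vals))


def train_model(
    model: SegmentationModel,
    cohort: Sequence[PhantomCase],
    config: TrainConfig,
    val_cases: Sequence[PhantomCase] = (),
) -> Tuple[SegmentationModel, pd.DataFrame]:
    """Train in a slice-wise manner; returns the model and a per-epoch log.

    The log records epoch, learning rate, mean minibatch loss and (on
    validation epochs) mean foreground DSC over ``val_cases``.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    xs, ts = [], []
    for case in cohort:
        x, t = _slice_stack(case, config.input_mode)
        xs.append(x)
        ts.append(t)
    X = np.concatenate(xs)  # (n_slices, C, H, W)
    T = np.concatenate(ts)
    n_slices = X.shape[0]

    if model.config.out_channels <= int(T.max()):
        raise ValueError("model has fewer output channels than label ids")

    if config.deep_supervision and not model.aux_heads:
        raise ValueError("deep supervision requested but the model has no "
                         "auxiliary heads (build with deep_supervision=True)")
    n_scales = 1 + len(model.aux_heads) if config.deep_supervision else 1
    if config.deep_supervision:
        weights = (config.ds_weights if config.ds_weights is not None
                   else default_ds_weights(n_scales))
    else:
        weights = (1.0,)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    opt = model.optimizer(config.momentum)
    rows: List[Dict] = []
    for epoch in range(config.epochs):
        lr = poly_lr(epoch, config)
        losses = []
        for _ in range(config.minibatches_per_epoch):
            idx = rng.integers(0, n_slices, size=config.batch_size)
            xb = X[idx]
            tb = T[idx]
            outputs = model.forward(xb)
            total = 0.0
            d_outputs = []
            for r, (out, w_r) in enumerate(zip(outputs, weights)):
                t_r = _downsample_target(tb, 2 ** r) if r else tb
                loss_r, grad_r = _loss_and_grad(out, t_r)
                total += w_r * loss_r
                d_outputs.append(w_r * grad_r)
            # unweighted aux outputs (deep supervision off) get zero gradient
            for out in outputs[len(weights):]:
                d_outputs.append(np.zeros_like(out))
            model.backward(d_outputs)
            opt.step(lr)
            losses.append(total)
        row = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses)),
               "val_dsc": np.nan}
        is_val_epoch = (val_cases and config.val_every > 0
                       and ((epoch + 1) % config.val_every == 0
                            or epoch == config.epochs - 1))
        if is_val_epoch:
            row["val_dsc"] = validation_dsc(model, val_cases, config.input_mode)
        rows.append(row)
    return model, pd.DataFrame(rows)
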