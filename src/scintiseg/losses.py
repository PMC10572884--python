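"""Overlap losses for multi-class segmentation with background exclusion.

Two per-class losses are provided.  With ``y`` the one-hot truth and ``p``
the predicted class probabilities, and sums running over all pixels of one
class channel:

* Dice loss          ``DL = 1 - 2*sum(y p) / (sum(y) + sum(p))``
* focal Tversky loss ``FTL = (1 - TI)**gamma`` with
  ``TI = sum(y p) / (sum(y p) + alpha*sum((1-y) p) + beta*sum(y (1-p)))``

``alpha`` weights false positives, ``beta`` false negatives and ``gamma``
down-weights easy examples; the defaults (0.3 / 0.7 / 0.75) favour recall
under the extreme class imbalance of small lesions.  The air-background
class carries no information for lesion discrimination, so by default its
channel contributes no loss term and receives no gradient of its own (it is
still constrained implicitly through the SoftMax).

The functions accept ``(C, H, W)`` or ``(N, C, H, W)`` inputs and work on
plain numpy arrays as well as :class:`scintiseg.nn.Tensor` graphs, so the
same code path is differentiated during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor

__all__ = [
    "LossConfig",
    "dice_loss",
    "focal_tversky_loss",
    "masked_multiclass_loss",
]


class LossConfigError(ValueError):
    pass


class UndefinedLossError(ZeroDivisionError):
    """Both masks empty with no smoothing term: the loss is 0/0."""


@dataclass(frozen=True)
class LossConfig:
    """Tversky weights, focusing exponent and class-exclusion set."""

    alpha: float = 0.3
    beta: float = 0.7
    gamma: float = 0.75
    excluded_classes: frozenset[int] = field(default_factory=lambda: frozenset({0}))
    smooth: float = 1e-6

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0 or self.gamma <= 0:
            raise LossConfigError("alpha, beta, gamma must be positive")
        if self.smooth < 0:
            raise LossConfigError("smooth must be non-negative")


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _check_shapes(y, p) -> bool:
    yd, pd = _data(y), _data(p)
    if yd.shape != pd.shape:
        raise ValueError(f"shape mismatch: y {yd.shape} vs p {pd.shape}")
    if yd.ndim not in (3, 4):
        raise ValueError("expected (C, H, W) or (N, C, H, W) inputs")
    return yd.ndim == 4


def _channel(x, c: int, batched: bool):
    return x[:, c] if batched else x[c]


def _pixel_sum(x, batched: bool):
    """Sum over pixels; per image when batched (returns a length-N vector)."""
    return x.sum(axis=(1, 2)) if batched else x.sum()


def _batch_mean(x, batched: bool):
    if not batched:
        return x
    return x.mean() if isinstance(x, Tensor) else float(np.mean(x))


def _clamp_nonneg(x):
    """max(x, 0): guards the fractional power against float roundoff pushing
    1 - TI infinitesimally below zero."""
    if isinstance(x, Tensor):
        from .nn import relu

        return relu(x)
    return np.maximum(x, 0.0)


def dice_loss(y, p, config: LossConfig = LossConfig(), class_index: int | None = None):
    """Dice loss on one class channel (or averaged over non-excluded
    channels when ``class_index`` is None, via
    :func:`masked_multiclass_loss`)."""
    if class_index is None:
        return masked_multiclass_loss(y, p, config, base="dice")
    batched = _check_shapes(y, p)
    yc = _channel(y, class_index, batched)
    pc = _channel(p, class_index, batched)
    inter = _pixel_sum(yc * pc, batched)
    denom = _pixel_sum(yc, batched) + _pixel_sum(pc, batched)
    if config.smooth == 0 and np.any(_data(denom) == 0):
        raise UndefinedLossError("sum(y) + sum(p) = 0 with smooth = 0")
    loss = 1.0 - (2.0 * inter + config.smooth) / (denom + config.smooth)
    return _batch_mean(loss, batched)


def focal_tversky_loss(
    y, p, config: LossConfig = LossConfig(), class_index: int | None = None
):
    """Focal Tversky loss ``(1 - TI)**gamma`` on one class channel (or the
    non-excluded-channel average when ``class_index`` is None)."""
    if class_index is None:
        return masked_multiclass_loss(y, p, config, base="focal_tversky")
    batched = _check_shapes(y, p)
    yc = _channel(y, class_index, batched)
    pc = _channel(p, class_index, batched)
    tp = _pixel_sum(yc * pc, batched)
    fp = _pixel_sum((1.0 - yc) * pc, batched)
    fn = _pixel_sum(yc * (1.0 - pc), batched)
    denom = tp + config.alpha * fp + config.beta * fn
    if config.smooth == 0 and np.any(_data(denom) == 0):
        raise UndefinedLossError("empty Tversky denominator with smooth = 0")
    ti = (tp + config.smooth) / (denom + config.smooth)
    loss = _clamp_nonneg(1.0 - ti) ** config.gamma
    return _batch_mean(loss, batched)


_BASES = {"dice": dice_loss, "focal_tversky": focal_tversky_loss}


def masked_multiclass_loss(
    y, p, config: LossConfig = LossConfig(), base: str = "dice"
):
    """Mean of the base loss over the class channels not in
    ``config.excluded_classes``.

    Excluded channels contribute no term, so the loss gradient with respect
    to an excluded channel's probabilities is exactly zero.
    """
    if base not in _BASES:
        raise LossConfigError(f"unknown base loss {base!r}")
    batched = _check_shapes(y, p)
    n_classes = _data(y).shape[1 if batched else 0]
    included = [c for c in range(n_classes) if c not in config.excluded_classes]
    if not included:
        raise LossConfigError("all classes excluded from the loss")
    fn = _BASES[base]
    total = None
    for c in included:
        term = fn(y, p, config, class_index=c)
        total = term if total is None else total + term
    return total * (1.0 / len(included))
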