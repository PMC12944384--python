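"""Class-imbalance corrections and their compound-amplification accounting.

Three corrections are available — focal loss, per-class loss weights (alpha)
and weighted (replacement) sampling — together with the bookkeeping that
quantifies how much extra emphasis their *stack* places on the minority
class. Each correction alone multiplies the effective minority-class
gradient by a modest factor, but the factors multiply: e.g. a focal-loss
gain of 2.8, class weights of [0.18, 0.82] (4.6-fold) and prevalence-0.179
weighted sampling (another 4.6-fold) compound to roughly a 60-fold
minority emphasis — the overcorrection regime in which a detector learns to
predict the minority class indiscriminately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImbalanceConfig",
    "focal_loss",
    "class_weight_ratio",
    "sampling_amplification",
    "compound_amplification",
    "make_sample_weights",
    "amplification_audit",
]


@dataclass(frozen=True)
class ImbalanceConfig:
    """One training plan's imbalance-correction stack.

    ``class_weights`` is ``(alpha_negative, alpha_positive)`` and must sum
    to 1. ``focal_gain_constant`` is the reported effective gradient-gain of
    the focal term (for gamma = 1.5); it enters only the amplification
    accounting, never the loss itself, because its derivation is a measured
    quantity rather than a closed form.
    """

    focal_gamma: float = 1.0
    class_weights: tuple[float, float] = (0.5, 0.5)
    weighted_sampling: bool = False
    focal_gain_constant: float = 2.8

    def __post_init__(self) -> None:
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be nonnegative")
        if min(self.class_weights) <= 0:
            raise ValueError("class_weights must be positive")
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError(
                f"class_weights must sum to 1, got {sum(self.class_weights)}"
            )
        if self.focal_gain_constant <= 0:
            raise ValueError("focal_gain_constant must be positive")


def focal_loss(p_true: float, alpha_true: float, gamma: float) -> float:
    """Focal loss ``-alpha * (1 - p)**gamma * log(p)`` for one window.

    ``p_true`` is the predicted probability of the window's true class; at
    ``gamma = 0`` this is weighted cross-entropy. Callers must clamp
    probabilities away from zero (the trainer uses eps = 1e-7).
    """
    if not 0.0 < p_true <= 1.0:
        raise ValueError(f"p_true must be in (0, 1], got {p_true}")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return -alpha_true * (1.0 - p_true) ** gamma * math.log(p_true)


def class_weight_ratio(class_weights: tuple[float, float]) -> float:
    """Minority-class weight over majority-class weight, e.g. [0.18, 0.82] -> 4.6."""
    lo, hi = sorted(class_weights)
    if lo <= 0:
        raise ValueError("class weights must be positive")
    return hi / lo


def sampling_amplification(minority_prevalence: float) -> float:
    """Oversampling factor ``(1 - pi) / pi`` that balances expected batch counts."""
    if not 0.0 < minority_prevalence < 1.0:
        raise ValueError(
            f"minority prevalence must be in (0, 1), got {minority_prevalence}"
        )
    return (1.0 - minority_prevalence) / minority_prevalence


def compound_amplification(factors: list[float]) -> float:
    """Product of stacked emphasis factors (the compound-imbalance diagnostic)."""
    if not factors:
        raise ValueError("compound_amplification requires at least one factor")
    if min(factors) <= 0:
        raise ValueError("amplification factors must be positive")
    return float(np.prod(factors))


def round_to_1sf(x: float) -> float:
    """Round to one significant figure (60x-style headline numbers)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def make_sample_weights(window_labels: np.ndarray) -> np.ndarray:
    """Inverse-class-count weights; weighted draws are 50/50 in expectation."""
    y = np.asarray(window_labels)
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("make_sample_weights requires both classes present")
    return 1.0 / counts[y]


def amplification_audit(
    config: ImbalanceConfig, minority_prevalence: float
) -> dict:
    """Emphasis-factor accounting for one imbalance stack.

    Returns each active factor (focal gain, class-weight ratio, sampling
    factor), their product, and the product rounded to one significant
    figure. Inactive corrections contribute a factor of 1: a focal term with
    gamma < 1.5 has no measured gain constant and is counted as 1 unless the
    caller configured one.
    """
    focal = config.focal_gain_constant if config.focal_gamma >= 1.5 else 1.0
    weights = class_weight_ratio(config.class_weights)
    sampling = (
        sampling_amplification(minority_prevalence)
        if config.weighted_sampling
        else 1.0
    )
    total = compound_amplification([focal, weights, sampling])
    return {
        "focal_gain": focal,
        "class_weight_ratio": weights,
        "sampling_factor": sampling,
        "total": total,
        "total_1sf": round_to_1sf(total),
    }
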