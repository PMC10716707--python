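"""Asymmetric focal loss for multilabel chest X-ray classification.

The loss treats positive and negative targets asymmetrically.  For a
predicted per-label probability ``p`` and binary target ``y`` the
per-element contribution is

    L = - [ y * a+ * (1 - p)^g+ * log(p)
            + (1 - y) * a- * (p_m)^g- * log(1 - p_m) ],

with the shifted ("clipped") probability ``p_m = max(p - m, 0)``.  The
focusing exponents ``g+`` (positives) and ``g-`` (negatives) down-weight
easy examples; because findings are sparse, the negative exponent is set
much larger (defaults g- = 5, g+ = 1, margin m = 0.001), and the margin
zeroes the contribution of easy negatives outright.  The optional
balancing factor ``a+ = alpha``, ``a- = 1 - alpha`` is the focal-loss
class-balancing term; it ships disabled (a+ = a- = 1) so the default is
the pure asymmetric loss.

With g+ = g- = 0, m = 0 and balancing disabled the loss reduces exactly
to binary cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LossParams:
    gamma_pos: float = 1.0
    gamma_neg: float = 5.0
    margin: float = 0.001
    alpha: float | None = None     # None = balancing disabled
    epsilon: float = 1e-7
    reduction: str = "mean"        # "mean" over batch of per-sample label sums

    def __post_init__(self) -> None:
        if self.gamma_pos < 0 or self.gamma_neg < 0:
            raise ValueError("focusing exponents must be >= 0")
        if not 0.0 <= self.margin < 1.0:
            raise ValueError("margin must lie in [0, 1)")
        if self.alpha is not None and not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1) when enabled")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.reduction not in ("mean", "sum", "none"):
            raise ValueError("reduction must be mean, sum or none")

    # ``beta`` is the focal-loss name for the focusing exponent; the
    # asymmetric loss already carries it as the per-class gammas.
    @property
    def beta(self) -> tuple[float, float]:
        return (self.gamma_pos, self.gamma_neg)


def _check(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    vals = np.unique(y)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError(f"targets must be binary 0/1, found {vals}")
    return p, y.astype(float)


def _elementwise(p: np.ndarray, y: np.ndarray, prm: LossParams) -> np.ndarray:
    eps = prm.epsilon
    pc = np.clip(p, eps, 1.0 - eps)
    a_pos, a_neg = (1.0, 1.0)
    if prm.alpha is not None:
        a_pos, a_neg = prm.alpha, 1.0 - prm.alpha
    pos = a_pos * (1.0 - pc) ** prm.gamma_pos * np.log(pc)
    pm = np.maximum(pc - prm.margin, 0.0)
    # pm ** 0 == 1 even at pm == 0, which is the correct cross-entropy limit.
    neg = a_neg * pm ** prm.gamma_neg * np.log1p(-pm)
    return -(y * pos + (1.0 - y) * neg)


def _reduce(contrib: np.ndarray, reduction: str) -> float | np.ndarray:
    if reduction == "none":
        return contrib
    if contrib.ndim > 1:
        per_sample = contrib.reshape(contrib.shape[0], -1).sum(axis=1)
    else:
        per_sample = contrib
    if reduction == "sum":
        return float(per_sample.sum())
    return float(per_sample.mean())


def asl_focal_loss(p, y, params: LossParams | None = None):
    """Asymmetric focal loss of predicted probabilities against binary
    targets.  Default reduction: per-sample sum over labels, mean over the
    batch.  ``reduction='none'`` returns the per-element contributions."""
    prm = params or LossParams()
    p, y = _check(p, y)
    return _reduce(_elementwise(p, y, prm), prm.reduction)


def asl_focal_loss_grad(p, y, params: LossParams | None = None) -> np.ndarray:
    """d(loss)/dp, elementwise, under the default mean-over-batch reduction.

    Used by the training loop; the probability clamp makes the gradient
    zero outside [epsilon, 1 - epsilon], and the margin makes easy
    negatives (p <= m) contribute zero gradient.
    """
    prm = params or LossParams()
    p, y = _check(p, y)
    eps = prm.epsilon
    inside = (p > eps) & (p < 1.0 - eps)
    pc = np.clip(p, eps, 1.0 - eps)
    a_pos, a_neg = (1.0, 1.0)
    if prm.alpha is not None:
        a_pos, a_neg = prm.alpha, 1.0 - prm.alpha

    gp = prm.gamma_pos
    # d/dp [ (1-p)^gp * log p ] = -gp (1-p)^(gp-1) log p + (1-p)^gp / p
    one_m = 1.0 - pc
    if gp == 0:
        dpos = 1.0 / pc
    else:
        dpos = -gp * one_m ** (gp - 1.0) * np.log(pc) + one_m ** gp / pc

    gn = prm.gamma_neg
    pm = np.maximum(pc - prm.margin, 0.0)
    active = pm > 0
    dneg = np.zeros_like(pc)
    with np.errstate(divide="ignore", invalid="ignore"):
        if gn == 0:
            dneg = np.where(active, -1.0 / (1.0 - pm), 0.0)
        else:
            term = gn * pm ** (gn - 1.0) * np.log1p(-pm) - pm ** gn / (1.0 - pm)
            dneg = np.where(active, term, 0.0)

    grad = -(y * a_pos * dpos + (1.0 - y) * a_neg * dneg)
    grad = np.where(inside, grad, 0.0)
    if prm.reduction == "mean":
        grad = grad / p.shape[0]
    return grad
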