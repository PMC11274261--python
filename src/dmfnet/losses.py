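"""Composite training objective.

L = L_focal + lambda1 * L_comple + lambda2 * L_consist

* Focal loss handles the heavy class imbalance (difficult airways are ~1:8
  before augmentation): the (1 - p_t)^gamma factor down-weights easy examples
  and alpha_t re-balances the classes.
* The complementarity loss is a margin hinge on the squared Euclidean distance
  between the two paths' CPP embeddings: frontal and lateral views should
  carry view-private information, so their private embeddings are pushed
  apart until the margin tau.
* The consistency loss is the mirror penalty on the CSP embeddings: both view
  groups describe the same subject, so their shared embeddings are pulled
  together (squared-distance proximity).

All reductions are batch means.  The trailing exponent in the published hinge
and proximity forms is read as the squared Euclidean distance (the standard
contrastive form); ``distance="plain"`` switches to the unsquared norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor

_EPS = 1e-7


@dataclass
class LossWeights:
    lambda1: float = 0.25       # complementarity weight
    lambda2: float = 0.5        # consistency weight
    alpha: float = 0.25         # focal class balance
    gamma: float = 2.0          # focal focusing exponent
    tau: float = 1.0            # complementarity margin
    distance: str = "squared"   # "squared" | "plain"

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if min(self.lambda1, self.lambda2, self.gamma, self.tau) < 0:
            raise ValueError("loss hyperparameters must be non-negative")
        if self.distance not in ("squared", "plain"):
            raise ValueError("distance must be 'squared' or 'plain'")


def _pt_at(p: Tensor, y: np.ndarray, weights: LossWeights):
    y = np.asarray(y, dtype=p.data.dtype)
    if p.data.shape != y.shape:
        raise ValueError(f"probability/label shape mismatch: {p.data.shape} vs {y.shape}")
    p = ag.clamp(p, _EPS, 1.0 - _EPS)
    p_t = ag.add(ag.mul(p, y), ag.mul(ag.sub(1.0, p), 1.0 - y))
    alpha_t = weights.alpha * y + (1.0 - weights.alpha) * (1.0 - y)
    return p_t, alpha_t


def focal_loss(p, y, weights: LossWeights = LossWeights()) -> Tensor:
    """Mean of -alpha_t (1 - p_t)^gamma log p_t over the batch."""
    p = ag.as_tensor(p)
    if np.any(p.data < 0) or np.any(p.data > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    p_t, alpha_t = _pt_at(p, y, weights)
    focus = ag.pow_const(ag.sub(1.0, p_t), weights.gamma) if weights.gamma != 0 else 1.0
    per_sample = ag.mul(ag.mul(ag.neg(ag.log(p_t)), focus), alpha_t)
    return ag.tmean(per_sample)


def cross_entropy_loss(p, y) -> Tensor:
    """Plain binary cross-entropy (the ablation baseline objective)."""
    p = ag.as_tensor(p)
    if np.any(p.data < 0) or np.any(p.data > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    p_t, _ = _pt_at(p, y, LossWeights())
    return ag.tmean(ag.neg(ag.log(p_t)))


def _pair_distance(z1, z2, weights: LossWeights) -> Tensor:
    z1, z2 = ag.as_tensor(z1), ag.as_tensor(z2)
    if z1.shape != z2.shape:
        raise ValueError(f"embedding shape mismatch: {z1.shape} vs {z2.shape}")
    diff = ag.sub(z1, z2)
    sq = ag.tsum(ag.mul(diff, diff), axis=1)
    if weights.distance == "plain":
        return ag.pow_const(ag.clamp(sq, _EPS, None), 0.5)
    return sq


def complementarity_loss(z1, z2, weights: LossWeights = LossWeights()) -> Tensor:
    """Hinge pushing the paired CPP embeddings apart: mean max(0, tau - d)."""
    d = _pair_distance(z1, z2, weights)
    return ag.tmean(ag.relu(ag.sub(weights.tau, d)))


def consistency_loss(z1, z2, weights: LossWeights = LossWeights()) -> Tensor:
    """Proximity penalty pulling the paired CSP embeddings together: mean d."""
    return ag.tmean(_pair_distance(z1, z2, weights))


def total_loss(p, y, z_cpp: tuple, z_csp: tuple,
               weights: LossWeights = LossWeights(),
               use_focal: bool = True, use_comple: bool = True,
               use_consist: bool = True) -> tuple[Tensor, dict]:
    """Composite objective and its per-term breakdown (floats, for logging)."""
    cls = focal_loss(p, y, weights) if use_focal else cross_entropy_loss(p, y)
    total = cls
    parts = {"classification": float(cls.data)}
    if use_comple:
        lc = complementarity_loss(z_cpp[0], z_cpp[1], weights)
        total = ag.add(total, ag.mul(lc, weights.lambda1))
        parts["complementarity"] = float(lc.data)
    else:
        parts["complementarity"] = 0.0
    if use_consist:
        ls = consistency_loss(z_csp[0], z_csp[1], weights)
        total = ag.add(total, ag.mul(ls, weights.lambda2))
        parts["consistency"] = float(ls.data)
    else:
        parts["consistency"] = 0.0
    parts["total"] = float(total.data)
    return total, parts
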