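"""Mutual-information point-set similarity costs.

The contour alignment cost treats the two 2D point sets as the outcomes of
a joint random variable whose probability mass decays exponentially with
inter-point distance, p_ij = exp(-d_ij) / sum exp(-d_ij), and scores the
mutual information of that joint:

    C_p = sum_ij p_ij * ln( p_ij / (sum_k p_kj * sum_l p_il) ).

When the sets align, mass concentrates on a near-permutation joint and the
MI rises; the registration search therefore *maximises* these costs. The
gradient cost uses the same MI form with a joint built from gradient
magnitude and orientation differences, and the fine cost adds a
position-cost term evaluated in an auxiliary view related to the reference
frame by a known inter-frame transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .contours import Contour2D
from .geometry import RigidPose, compose


class EmptyContourError(ValueError):
    """Raised when a cost is requested for an empty point set."""


@dataclass(frozen=True)
class CostWeights:
    """Weights of the fine cost: position, gradient, auxiliary-view position."""

    w1: float = 0.4
    w2: float = 0.2
    w3: float = 0.4

    def __post_init__(self):
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("weights must be non-negative")
        if self.w1 + self.w2 + self.w3 <= 0:
            raise ValueError("at least one weight must be positive")


@dataclass
class CostBreakdown:
    c_pos: float
    c_grad: float
    c_pos_aux: float
    c_fine: float
    n_alpha: int
    n_G: int
    degenerate: bool = False


def _mi_of_joint(p: np.ndarray) -> float:
    """MI of a normalised joint probability table (natural log)."""
    row = p.sum(axis=1, keepdims=True)
    col = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (row * col))
    return float(np.nansum(terms))


def position_cost(alpha: Contour2D, g: Contour2D,
                  length_scale: float = 2.5) -> float:
    """Joint-probability position MI between two contours.

    Distances are divided by ``length_scale`` (px) before exponentiation so
    the exp(-d) kernel stays in a useful numeric range on image-sized
    distances.
    """
    if len(alpha) == 0 or len(g) == 0:
        raise EmptyContourError("position_cost requires non-empty contours")
    d = np.linalg.norm(alpha.points[:, None, :] - g.points[None, :, :], axis=2)
    d = d / length_scale
    w = np.exp(-(d - d.min()))   # common shift cancels in the normalisation
    p = w / w.sum()
    return _mi_of_joint(p)


def gradient_cost(alpha: Contour2D, g: Contour2D) -> float:
    """Gradient-attribute MI between two contours.

    m_ij = |magnitude difference| (both magnitudes already in [0,1]);
    o_ij = orientation difference folded to [0, pi/2] and normalised by
    pi/2; the joint is exp(-(m_ij + o_ij)), normalised.
    """
    if len(alpha) == 0 or len(g) == 0:
        raise EmptyContourError("gradient_cost requires non-empty contours")
    if not (alpha.has_gradients and g.has_gradients):
        raise ValueError("both contours must carry gradient attributes")
    m = np.abs(alpha.grad_mag[:, None] - g.grad_mag[None, :])
    do = np.abs(alpha.grad_ori[:, None] - g.grad_ori[None, :])
    do = np.minimum(do, np.pi - do)          # fold to [0, pi/2]
    o = do / (np.pi / 2)
    w = np.exp(-(m + o))
    p = w / w.sum()
    return _mi_of_joint(p)


def auxiliary_view_pose(t0: RigidPose, t0n: RigidPose) -> RigidPose:
    """Pose of the auxiliary frame implied by candidate ``t0``.

    ``t0n`` is the inter-frame camera transform (frame-0 camera space to
    frame-n camera space), so the model->camera pose of frame n is
    ``t0n o t0``. Rendering with the result reproduces frame n's viewpoint
    when ``t0`` is the true frame-0 pose.
    """
    return compose(t0n, t0)


def fine_cost(candidate: RigidPose,
              actual0: Contour2D,
              generated0: Contour2D,
              weights: CostWeights,
              length_scale: float = 2.5,
              actual_aux: Optional[Contour2D] = None,
              generated_aux: Optional[Contour2D] = None) -> CostBreakdown:
    """Weighted fine cost w1*C_p + w2*C_grad + w3*C_p(aux view).

    An empty generated contour (camera looking away from every salient
    point) yields the worst value 0 with ``degenerate=True`` instead of an
    exception, so a population-based optimiser can keep running.
    """
    n_a, n_g = len(actual0), len(generated0)
    if n_a == 0 or n_g == 0:
        return CostBreakdown(0.0, 0.0, 0.0, 0.0, n_a, n_g, degenerate=True)
    c_pos = position_cost(actual0, generated0, length_scale)
    c_grad = 0.0
    if weights.w2 > 0:
        if actual0.has_gradients and generated0.has_gradients:
            c_grad = gradient_cost(actual0, generated0)
    c_aux = 0.0
    if weights.w3 > 0 and actual_aux is not None and generated_aux is not None:
        if len(actual_aux) and len(generated_aux):
            c_aux = position_cost(actual_aux, generated_aux, length_scale)
    c = weights.w1 * c_pos + weights.w2 * c_grad + weights.w3 * c_aux
    return CostBreakdown(c_pos, c_grad, c_aux, c, n_a, n_g)
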