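"""Occlusion-aware detection loss terms as pure numpy functions.

The total detection loss is the per-positive-location average of four
terms: a focal classification loss, a DIoU box-regression loss, a binary
cross-entropy centerness loss, and an L1 loss on the predicted occlusion
ratio. No autograd — these are reference implementations for evaluation
and testing, not a training loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fusion import Box3D, iou3d

EPS = 1e-7

DEFAULT_FOCAL_ALPHA = 0.25
DEFAULT_FOCAL_GAMMA = 2.0


def _pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def focal_loss(
    p,
    p_hat,
    alpha: float = DEFAULT_FOCAL_ALPHA,
    gamma: float = DEFAULT_FOCAL_GAMMA,
) -> float:
    """Focal classification loss, summed over locations and classes.

    ``p`` are predicted probabilities, ``p_hat`` binary ground-truth
    indicators of the same shape. With gamma = 0 and alpha = 0.5 this is
    half the standard cross-entropy.
    """
    p, p_hat = _pair(p, p_hat)
    p = np.clip(p, EPS, 1.0 - EPS)
    pt = np.where(p_hat > 0.5, p, 1.0 - p)
    at = np.where(p_hat > 0.5, alpha, 1.0 - alpha)
    return float(np.sum(-at * (1.0 - pt) ** gamma * np.log(pt)))


def diou_loss(b: Box3D, b_hat: Box3D) -> float:
    """Distance-IoU regression loss: 1 - IoU + rho^2 / c^2.

    rho is the center distance and c the diagonal of the smallest
    axis-aligned box enclosing both; the result lies in [0, 2).
    """
    iou = iou3d(b, b_hat)
    rho2 = float(np.sum((b.center - b_hat.center) ** 2))
    amin, amax = b.corners_min_max()
    bmin, bmax = b_hat.corners_min_max()
    enclosing = np.maximum(amax, bmax) - np.minimum(amin, bmin)
    c2 = float(np.sum(enclosing**2))
    return 1.0 - iou + rho2 / c2


def centerness_bce(c, c_hat) -> float:
    """Mean binary cross-entropy between predicted and target centerness."""
    c, c_hat = _pair(c, c_hat)
    c = np.clip(c, EPS, 1.0 - EPS)
    return float(np.mean(-(c_hat * np.log(c) + (1.0 - c_hat) * np.log(1.0 - c))))


def occlusion_l1(O, O_hat) -> float:
    """Mean absolute error between predicted and true occlusion ratios."""
    O, O_hat = _pair(O, O_hat)
    if np.any((O < 0) | (O > 1) | (O_hat < 0) | (O_hat > 1)):
        raise ValueError("occlusion ratios must lie in [0, 1]")
    return float(np.mean(np.abs(O - O_hat)))


@dataclass
class DetectionBatch:
    """Predictions and targets for one batch of detector locations.

    ``pred_probs``/``gt_labels`` cover all locations; the box, centerness
    and occlusion pairs cover only the ``npos`` positive locations.
    """

    pred_probs: np.ndarray
    gt_labels: np.ndarray
    pred_boxes: Sequence[Box3D]
    gt_boxes: Sequence[Box3D]
    pred_centerness: np.ndarray
    gt_centerness: np.ndarray
    pred_occlusion: np.ndarray
    gt_occlusion: np.ndarray

    @property
    def npos(self) -> int:
        return len(self.pred_boxes)

    def __post_init__(self):
        if len(self.pred_boxes) != len(self.gt_boxes):
            raise ValueError("pred/gt box lists must pair up")


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    cls: float
    reg: float
    cntr: float
    occ: float
    npos: int
    empty_batch: bool = False

    def to_dict(self) -> dict:
        return {
            "total": self.total, "cls": self.cls, "reg": self.reg,
            "cntr": self.cntr, "occ": self.occ, "npos": self.npos,
            "empty_batch": self.empty_batch,
        }


def total_loss(
    batch: DetectionBatch,
    alpha: float = DEFAULT_FOCAL_ALPHA,
    gamma: float = DEFAULT_FOCAL_GAMMA,
    weights: Optional[dict] = None,
) -> LossBreakdown:
    """(L_cls + L_reg + L_cntr + L_occ) / max(npos, 1), with breakdown.

    The terms are unweighted by default; optional ``weights`` maps
    {"cls", "reg", "cntr", "occ"} to multipliers. An empty-positive batch
    yields 0 with ``empty_batch=True``.
    """
    w = {"cls": 1.0, "reg": 1.0, "cntr": 1.0, "occ": 1.0}
    if weights:
        w.update(weights)
    npos = batch.npos
    denom = max(npos, 1)

    l_cls = w["cls"] * focal_loss(batch.pred_probs, batch.gt_labels, alpha, gamma)
    if npos > 0:
        l_reg = w["reg"] * float(
            np.sum([diou_loss(b, bh) for b, bh in zip(batch.pred_boxes, batch.gt_boxes)])
        )
        l_cntr = w["cntr"] * centerness_bce(batch.pred_centerness, batch.gt_centerness) * npos
        l_occ = w["occ"] * occlusion_l1(batch.pred_occlusion, batch.gt_occlusion) * npos
    else:
        l_reg = l_cntr = l_occ = 0.0

    total = (l_cls + l_reg + l_cntr + l_occ) / denom
    return LossBreakdown(
        total=float(total),
        cls=float(l_cls / denom),
        reg=float(l_reg / denom),
        cntr=float(l_cntr / denom),
        occ=float(l_occ / denom),
        npos=npos,
        empty_batch=npos == 0,
    )
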