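"""Label assignment and box-regression losses for the detection head.

Implements the training machinery used by the miniature detector:

* the IoU family (plain IoU, generalized IoU, complete IoU),
* a hybrid regression loss ``1 - (lambda * CIoU + (1 - lambda) * GIoU)``,
* the task-alignment score ``p_cls**alpha * IoU**beta``,
* Gaussian soft-constrained centre sampling weights, and
* a top-k positive-sample assigner that combines alignment and centre
  weights multiplicatively.

Coordinates are continuous pixels, origin top-left, x right, y down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Box",
    "AssignerParams",
    "LossParams",
    "Assignment",
    "iou",
    "giou",
    "ciou",
    "hybrid_iou_loss",
    "task_alignment_score",
    "gaussian_center_weight",
    "assign_targets",
]


class Box(NamedTuple):
    """Axis-aligned box with strictly positive area."""

    x1: float
    y1: float
    x2: float
    y2: float

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))


def _validate(box: Box) -> None:
    if not (box.x1 < box.x2 and box.y1 < box.y2):
        raise ValueError(f"degenerate box: {box}")
    if not all(math.isfinite(v) for v in box):
        raise ValueError(f"non-finite box: {box}")


@dataclass(frozen=True)
class AssignerParams:
    """Hyperparameters of the task-aligned assigner.

    alpha, beta weight classification vs. localisation in the alignment
    score; sigma controls the reach of the Gaussian centre prior (in units
    of half the ground-truth diagonal); topk caps positives per target.
    """

    alpha: float = 1.0
    beta: float = 6.0
    sigma: float = 0.5
    topk: int = 10

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.topk < 1:
            raise ValueError("topk must be >= 1")


@dataclass(frozen=True)
class LossParams:
    """Mixing coefficient of the hybrid CIoU/GIoU regression loss."""

    lambda_mix: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must lie in [0, 1]")


@dataclass
class Assignment:
    """Result of positive-sample assignment.

    ``anchor_to_gt[i]`` is the matched ground-truth index for anchor ``i``
    or -1; the per-pair matrices have shape (n_anchors, n_gts).
    """

    anchor_to_gt: np.ndarray
    alignment: np.ndarray
    center_weight: np.ndarray
    metric: np.ndarray

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.anchor_to_gt >= 0))


def iou(a: Box, b: Box) -> float:
    """Intersection over union, in [0, 1]."""
    _validate(a)
    _validate(b)
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def _enclosing(a: Box, b: Box) -> Box:
    return Box(min(a.x1, b.x1), min(a.y1, b.y1), max(a.x2, b.x2), max(a.y2, b.y2))


def giou(a: Box, b: Box) -> float:
    """Generalized IoU: IoU minus the enclosing-box slack, in (-1, 1]."""
    u = iou(a, b)
    c = _enclosing(a, b)
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    union = a.area + b.area - ix * iy
    return u - (c.area - union) / c.area


def ciou(a: Box, b: Box) -> float:
    """Complete IoU: IoU minus centre-distance and aspect-ratio penalties.

    ``CIoU = IoU - rho^2/c^2 - alpha*v`` with ``c`` the enclosing-box
    diagonal, ``v = (4/pi^2) * (atan(wb/hb) - atan(wa/ha))^2`` and
    ``alpha = v / ((1 - IoU) + v)`` (zero when ``v`` is zero).
    """
    u = iou(a, b)
    c = _enclosing(a, b)
    c2 = c.width**2 + c.height**2
    (ax, ay), (bx, by) = a.center, b.center
    rho2 = (ax - bx) ** 2 + (ay - by) ** 2
    v = (4.0 / math.pi**2) * (
        math.atan(b.width / b.height) - math.atan(a.width / a.height)
    ) ** 2
    alpha = 0.0 if v == 0.0 else v / ((1.0 - u) + v)
    return u - rho2 / c2 - alpha * v


def hybrid_iou_loss(a: Box, b: Box, params: LossParams | None = None) -> float:
    """Minimized box-regression loss ``1 - (lam*CIoU + (1-lam)*GIoU)``.

    Zero iff the boxes coincide; reduces to ``1 - CIoU`` at ``lam = 1``
    and ``1 - GIoU`` at ``lam = 0``.
    """
    params = params or LossParams()
    lam = params.lambda_mix
    return 1.0 - (lam * ciou(a, b) + (1.0 - lam) * giou(a, b))


def task_alignment_score(
    p_cls: float, iou_val: float, params: AssignerParams | None = None
) -> float:
    """Joint classification/localisation score ``p**alpha * u**beta``."""
    if p_cls < 0 or iou_val < 0:
        raise ValueError("classification score and IoU must be non-negative")
    params = params or AssignerParams()
    return p_cls**params.alpha * iou_val**params.beta


def gaussian_center_weight(
    anchor_xy: tuple[float, float], gt: Box, params: AssignerParams | None = None
) -> float:
    """Soft centre prior ``exp(-d^2 / sigma^2)`` in (0, 1].

    ``d`` is the anchor-to-centre distance normalised by half the
    ground-truth box diagonal, so weights are comparable across scales.
    """
    params = params or AssignerParams()
    _validate(gt)
    cx, cy = gt.center
    half_diag = 0.5 * math.hypot(gt.width, gt.height)
    d = math.hypot(anchor_xy[0] - cx, anchor_xy[1] - cy) / half_diag
    return math.exp(-(d**2) / params.sigma**2)


def assign_targets(
    anchors: Sequence[tuple[float, float]],
    gts: Sequence[Box],
    cls_scores: np.ndarray,
    params: AssignerParams | None = None,
    pred_ious: np.ndarray | None = None,
) -> Assignment:
    """Assign anchors to ground-truth boxes by the combined metric.

    ``cls_scores[i, j]`` is the anchor's classification score for the
    category of gt ``j``; ``pred_ious[i, j]`` the IoU of the anchor's
    current predicted box with gt ``j`` (defaults to a point-in-box proxy:
    the centre weight itself is used when predictions are unavailable).

    For each gt the top-k anchors by ``m = A_ij * w_ij`` become candidate
    positives; an anchor claimed by several gts goes to the gt with the
    larger metric (ties: larger IoU, then lower gt index). Every gt with a
    positive-metric anchor keeps at least its argmax anchor.
    """
    params = params or AssignerParams()
    if len(anchors) == 0:
        raise ValueError("need at least one anchor")
    n_a, n_g = len(anchors), len(gts)
    align = np.zeros((n_a, n_g))
    cw = np.zeros((n_a, n_g))
    if n_g == 0:
        return Assignment(np.full(n_a, -1, dtype=int), align, cw, align.copy())

    cls_scores = np.asarray(cls_scores, dtype=float)
    if cls_scores.shape != (n_a, n_g):
        raise ValueError(f"cls_scores must be ({n_a}, {n_g})")
    if pred_ious is None:
        ious = None
    else:
        ious = np.asarray(pred_ious, dtype=float)
        if ious.shape != (n_a, n_g):
            raise ValueError(f"pred_ious must be ({n_a}, {n_g})")

    for j, gt in enumerate(gts):
        for i, pt in enumerate(anchors):
            u = ious[i, j] if ious is not None else 0.0
            align[i, j] = task_alignment_score(cls_scores[i, j], u, params)
            cw[i, j] = gaussian_center_weight(pt, gt, params)
    # without predicted boxes the centre prior stands in for localisation
    if ious is None:
        align = cls_scores**params.alpha * cw**params.beta
    metric = align * cw

    k = min(params.topk, n_a)
    candidate = np.zeros((n_a, n_g), dtype=bool)
    for j in range(n_g):
        order = np.argsort(-metric[:, j], kind="stable")[:k]
        for i in order:
            if metric[i, j] > 0:
                candidate[i, j] = True
        best = int(np.argmax(metric[:, j]))
        if metric[best, j] > 0:
            candidate[best, j] = True

    anchor_to_gt = np.full(n_a, -1, dtype=int)
    for i in range(n_a):
        js = np.nonzero(candidate[i])[0]
        if js.size == 0:
            continue
        if js.size == 1:
            anchor_to_gt[i] = js[0]
            continue
        u_row = ious[i, js] if ious is not None else cw[i, js]
        # larger metric wins; ties broken by larger IoU, then lower index
        keys = sorted(
            range(js.size),
            key=lambda t: (-metric[i, js[t]], -u_row[t], js[t]),
        )
        anchor_to_gt[i] = js[keys[0]]
    return Assignment(anchor_to_gt, align, cw, metric)
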