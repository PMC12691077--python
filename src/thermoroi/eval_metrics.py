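"""Detection evaluation: precision, recall, per-class AP and mAP50.

Matching is greedy in confidence order at a fixed IoU threshold; AP is the
area under the precision-recall curve with the all-point (continuous)
interpolation, i.e. the precision envelope made monotone non-increasing
and summed over recall increments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .training_strategy import Box, iou

__all__ = [
    "MatchResult",
    "match_detections",
    "precision_recall",
    "average_precision",
    "map50",
    "confidence",
    "evaluate_detections",
]


@dataclass
class MatchResult:
    """Per-detection TP/FP flags (confidence-ranked) and per-gt match flags."""

    det_is_tp: np.ndarray
    gt_matched: np.ndarray

    @property
    def tp(self) -> int:
        return int(np.sum(self.det_is_tp))

    @property
    def fp(self) -> int:
        return int(np.sum(~self.det_is_tp))

    @property
    def fn(self) -> int:
        return int(np.sum(~self.gt_matched))


def match_detections(
    dets: Sequence[tuple[Box, int, float]],
    gts: Sequence[tuple[Box, int]],
    iou_thr: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ordered matching of detections to ground truth.

    ``dets`` are (box, category, score); ``gts`` are (box, category). Each
    detection matches the unmatched same-category gt of highest IoU >=
    ``iou_thr``; unmatched detections are false positives, unmatched gts
    false negatives.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i][2])
    gt_matched = np.zeros(len(gts), dtype=bool)
    det_is_tp = np.zeros(len(dets), dtype=bool)
    flags_ranked = np.zeros(len(dets), dtype=bool)
    for rank, i in enumerate(order):
        box, cat, _score = dets[i]
        best_j, best_iou = -1, iou_thr
        for j, (gbox, gcat) in enumerate(gts):
            if gcat != cat or gt_matched[j]:
                continue
            u = iou(box, gbox)
            if u >= best_iou:
                best_j, best_iou = j, u
        if best_j >= 0:
            gt_matched[best_j] = True
            det_is_tp[i] = True
            flags_ranked[rank] = True
    return MatchResult(flags_ranked, gt_matched)


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """Precision and recall in percent; 0 when the denominator is 0."""
    tp, fp, fn = m.tp, m.fp, m.fn
    p = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    return p, r


def average_precision(tp_flags: Sequence[bool], n_gt: int) -> float:
    """All-point interpolated AP from confidence-ranked TP/FP flags."""
    if n_gt <= 0:
        raise ValueError("AP undefined for a class with no ground truth")
    flags = np.asarray(tp_flags, dtype=bool)
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope, then sum rectangle areas over recall increments
    r = np.concatenate(([0.0], recall, [recall[-1]]))
    p = np.concatenate(([0.0], precision, [0.0]))
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def map50(per_class_ap: Mapping[str, float] | Sequence[float]) -> float:
    """Mean AP over classes, in percent."""
    aps = list(per_class_ap.values()) if isinstance(per_class_ap, Mapping) else list(per_class_ap)
    if not aps:
        raise ValueError("no class with a defined AP")
    return 100.0 * float(np.mean(aps))


def confidence(class_scores: Sequence[float]) -> float:
    """Detection confidence: the maximum per-class score."""
    if len(class_scores) == 0:
        raise ValueError("need at least one class score")
    return float(np.max(class_scores))


def evaluate_detections(
    dets_per_image: Sequence[Sequence[tuple[Box, int, float]]],
    gts_per_image: Sequence[Sequence[tuple[Box, int]]],
    categories: Sequence[int],
    iou_thr: float = 0.5,
) -> dict:
    """Dataset-level P/R/mAP50 restricted to ``categories``.

    Classes with no ground truth anywhere are excluded from the mean.
    Returns {"P": %, "R": %, "mAP50": %, "per_class_AP": {cat: AP}}.
    """
    tp = fp = fn = 0
    flags_by_cat: dict[int, list[tuple[float, bool]]] = {c: [] for c in categories}
    ngt_by_cat: dict[int, int] = {c: 0 for c in categories}
    for dets, gts in zip(dets_per_image, gts_per_image, strict=True):
        dets = [d for d in dets if d[1] in flags_by_cat]
        gts = [g for g in gts if g[1] in ngt_by_cat]
        m = match_detections(dets, gts, iou_thr)
        tp += m.tp
        fp += m.fp
        fn += m.fn
        order = sorted(range(len(dets)), key=lambda i: -dets[i][2])
        for rank, i in enumerate(order):
            flags_by_cat[dets[i][1]].append((dets[i][2], bool(m.det_is_tp[rank])))
        for _gbox, gcat in gts:
            ngt_by_cat[gcat] += 1
    p = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    per_class = {}
    for c in categories:
        if ngt_by_cat[c] == 0:
            continue
        ranked = sorted(flags_by_cat[c], key=lambda t: -t[0])
        per_class[c] = average_precision([f for _s, f in ranked], ngt_by_cat[c])
    out = {"P": p, "R": r, "per_class_AP": per_class}
    out["mAP50"] = map50(per_class) if per_class else float("nan")
    return out
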