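"""IoU family, hybrid loss, alignment metric, centre prior, assigner."""

import math

import numpy as np
import pytest

from thermoroi.training_strategy import (
    AssignerParams,
    Box,
    LossParams,
    assign_targets,
    ciou,
    gaussian_center_weight,
    giou,
    hybrid_iou_loss,
    iou,
    task_alignment_score,
)


def _random_box(rng, lo=0.0, hi=100.0, min_side=0.5):
    x1, y1 = rng.uniform(lo, hi - min_side, size=2)
    w, h = rng.uniform(min_side, hi - max(x1, y1), size=2)
    return Box(x1, y1, x1 + w, y1 + h)


# independent vectorised re-derivations used as dual-implementation oracles
def _giou_oracle(a, b):
    inter_w = min(a[2], b[2]) - max(a[0], b[0])
    inter_h = min(a[3], b[3]) - max(a[1], b[1])
    inter = max(inter_w, 0.0) * max(inter_h, 0.0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    cw = max(a[2], b[2]) - min(a[0], b[0])
    ch = max(a[3], b[3]) - min(a[1], b[1])
    return inter / union - (cw * ch - union) / (cw * ch)


def _ciou_oracle(a, b):
    inter_w = min(a[2], b[2]) - max(a[0], b[0])
    inter_h = min(a[3], b[3]) - max(a[1], b[1])
    inter = max(inter_w, 0.0) * max(inter_h, 0.0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    u = inter / (area_a + area_b - inter)
    cw = max(a[2], b[2]) - min(a[0], b[0])
    ch = max(a[3], b[3]) - min(a[1], b[1])
    rho2 = ((a[0] + a[2]) / 2 - (b[0] + b[2]) / 2) ** 2 + (
        (a[1] + a[3]) / 2 - (b[1] + b[3]) / 2
    ) ** 2
    v = 4 / math.pi**2 * (
        math.atan((b[2] - b[0]) / (b[3] - b[1])) - math.atan((a[2] - a[0]) / (a[3] - a[1]))
    ) ** 2
    alpha = v / (1 - u + v) if v > 0 else 0.0
    return u - rho2 / (cw**2 + ch**2) - alpha * v


class TestIouFamily:
    def test_identical_boxes_score_one(self):
        b = Box(3.0, 4.0, 10.0, 12.0)
        assert iou(b, b) == 1.0
        assert giou(b, b) == 1.0
        assert ciou(b, b) == 1.0

    def test_printed_worked_cases(self):
        assert iou(Box(0, 0, 2, 2), Box(1, 0, 3, 2)) == pytest.approx(1 / 3)
        assert iou(Box(0, 0, 1, 1), Box(5, 5, 6, 6)) == 0.0
        assert giou(Box(0, 0, 1, 1), Box(2, 0, 3, 1)) == pytest.approx(-1 / 3)

    def test_concentric_equal_aspect_ciou_equals_iou(self):
        a = Box(0, 0, 4, 2)
        b = Box(1, 0.5, 3, 1.5)  # same centre, same 2:1 aspect
        assert ciou(a, b) == pytest.approx(iou(a, b), abs=1e-12)

    def test_agrees_with_independent_formulas(self, rng):
        for _ in range(2000):
            a, b = _random_box(rng), _random_box(rng)
            assert giou(a, b) == pytest.approx(_giou_oracle(a, b), abs=1e-9)
            assert ciou(a, b) == pytest.approx(_ciou_oracle(a, b), abs=1e-9)

    def test_family_ordering(self, rng):
        for _ in range(500):
            a, b = _random_box(rng), _random_box(rng)
            u = iou(a, b)
            assert giou(a, b) <= u + 1e-12
            assert ciou(a, b) <= u + 1e-12

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            iou(Box(0, 0, 0, 1), Box(0, 0, 1, 1))


class TestHybridLoss:
    def test_zero_iff_identical(self, rng):
        b = Box(1, 2, 5, 9)
        for lam in (0.0, 0.3, 1.0):
            assert hybrid_iou_loss(b, b, LossParams(lam)) == 0.0
        a, c = _random_box(rng), _random_box(rng)
        if a != c:
            assert hybrid_iou_loss(a, c) > 0.0

    def test_reduces_to_pure_components(self, rng):
        a, b = _random_box(rng), _random_box(rng)
        assert hybrid_iou_loss(a, b, LossParams(1.0)) == pytest.approx(1 - ciou(a, b))
        assert hybrid_iou_loss(a, b, LossParams(0.0)) == pytest.approx(1 - giou(a, b))

    def test_bounds(self, rng):
        for _ in range(500):
            a, b = _random_box(rng), _random_box(rng)
            lam = rng.uniform()
            loss = hybrid_iou_loss(a, b, LossParams(lam))
            assert 0.0 <= loss < 2.0

    def test_gradient_descent_recovers_target(self, rng):
        """Numeric gradient steps on a perturbed box reduce the loss."""
        improved = 0
        for _ in range(100):
            gt = _random_box(rng, 10, 90, 5.0)
            v = np.array(gt, dtype=float) + rng.normal(0, 2.0, size=4)
            v[2] = max(v[2], v[0] + 1.0)
            v[3] = max(v[3], v[1] + 1.0)

            def loss_of(vec):
                return hybrid_iou_loss(Box(*vec), gt)

            start = loss_of(v)
            for _step in range(20):
                g = np.zeros(4)
                for d in range(4):
                    vp, vm = v.copy(), v.copy()
                    vp[d] += 1e-3
                    vm[d] -= 1e-3
                    g[d] = (loss_of(vp) - loss_of(vm)) / 2e-3
                v2 = v - 2.0 * g
                if v2[0] < v2[2] - 0.5 and v2[1] < v2[3] - 0.5 and loss_of(v2) <= loss_of(v):
                    v = v2
            improved += loss_of(v) < start - 1e-6 or start < 1e-9
        assert improved == 100

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            LossParams(1.5)


class TestAlignmentAndCentrePrior:
    def test_alignment_anchor_values(self):
        p = AssignerParams(alpha=1.0, beta=1.0)
        assert task_alignment_score(1.0, 1.0, p) == 1.0
        assert task_alignment_score(0.5, 0.5, p) == pytest.approx(0.25)

    def test_alignment_monotone(self, rng):
        p = AssignerParams(alpha=0.7, beta=4.0)
        grid = np.linspace(0, 1, 11)
        for u in grid:
            vals = [task_alignment_score(x, u, p) for x in grid]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
        for x in grid:
            vals = [task_alignment_score(x, u, p) for u in grid]
            assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_centre_weight_anchor_values(self):
        gt = Box(0, 0, 6, 8)  # half-diagonal 5
        p = AssignerParams(sigma=0.5)
        assert gaussian_center_weight((3, 4), gt, p) == 1.0
        # distance such that d == sigma  ->  exp(-1)
        d_px = 0.5 * 5
        w = gaussian_center_weight((3 + d_px, 4), gt, p)
        assert w == pytest.approx(math.exp(-1), abs=1e-12)

    def test_centre_weight_strictly_decreasing(self):
        gt = Box(0, 0, 10, 10)
        p = AssignerParams(sigma=0.8)
        ws = [gaussian_center_weight((5 + d, 5), gt, p) for d in np.linspace(0, 10, 30)]
        assert all(a > b for a, b in zip(ws, ws[1:]))


def _brute_force_assign(anchors, gts, cls_scores, ious, params):
    """Independent re-derivation of the assignment rules by exhaustion."""
    n_a, n_g = len(anchors), len(gts)
    align = np.zeros((n_a, n_g))
    cw = np.zeros((n_a, n_g))
    for j, gt in enumerate(gts):
        cx, cy = (gt.x1 + gt.x2) / 2, (gt.y1 + gt.y2) / 2
        half_diag = 0.5 * math.hypot(gt.x2 - gt.x1, gt.y2 - gt.y1)
        for i, (ax, ay) in enumerate(anchors):
            d = math.hypot(ax - cx, ay - cy) / half_diag
            cw[i, j] = math.exp(-(d**2) / params.sigma**2)
            align[i, j] = cls_scores[i, j] ** params.alpha * ious[i, j] ** params.beta
    metric = align * cw
    candidates = set()
    for j in range(n_g):
        ranked = sorted(range(n_a), key=lambda i: -metric[i, j])
        for i in ranked[: min(params.topk, n_a)]:
            if metric[i, j] > 0:
                candidates.add((i, j))
        best = max(range(n_a), key=lambda i: metric[i, j])
        if metric[best, j] > 0:
            candidates.add((best, j))
    out = np.full(n_a, -1, dtype=int)
    for i in range(n_a):
        js = [j for (ii, j) in candidates if ii == i]
        if js:
            out[i] = min(js, key=lambda j: (-metric[i, j], -ious[i, j], j))
    return out


class TestAssigner:
    def test_perfect_anchor_assigned(self):
        gt = Box(10, 10, 30, 30)
        anchors = [(20.0, 20.0), (80.0, 80.0)]
        cls = np.array([[1.0], [0.1]])
        ious = np.array([[1.0], [0.0]])
        asg = assign_targets(anchors, [gt], cls, AssignerParams(), ious)
        assert asg.anchor_to_gt[0] == 0
        assert asg.anchor_to_gt[1] == -1

    def test_disjoint_gts_no_cross_assignment(self):
        g1, g2 = Box(0, 0, 10, 10), Box(80, 80, 95, 95)
        anchors = [(5.0, 5.0), (87.5, 87.5)]
        cls = np.full((2, 2), 0.9)
        ious = np.array([[0.9, 0.0], [0.0, 0.9]])
        asg = assign_targets(anchors, [g1, g2], cls, AssignerParams(), ious)
        assert list(asg.anchor_to_gt) == [0, 1]

    def test_empty_gts_valid(self):
        asg = assign_targets([(1.0, 1.0)], [], np.zeros((1, 0)))
        assert list(asg.anchor_to_gt) == [-1]

    def test_matches_brute_force_on_random_instances(self, rng):
        params = AssignerParams(alpha=1.0, beta=2.0, sigma=0.7, topk=3)
        for _ in range(300):
            n_a = int(rng.integers(1, 9))
            n_g = int(rng.integers(1, 4))
            anchors = [tuple(rng.uniform(0, 100, 2)) for _ in range(n_a)]
            gts = [_random_box(rng, 0, 100, 2.0) for _ in range(n_g)]
            cls = rng.uniform(0, 1, (n_a, n_g))
            ious = rng.uniform(0, 1, (n_a, n_g))
            asg = assign_targets(anchors, gts, cls, params, ious)
            expected = _brute_force_assign(anchors, gts, cls, ious, params)
            assert list(asg.anchor_to_gt) == list(expected)

    def test_deterministic(self, rng):
        anchors = [tuple(rng.uniform(0, 50, 2)) for _ in range(6)]
        gts = [_random_box(rng, 0, 50, 2.0) for _ in range(2)]
        cls = rng.uniform(0, 1, (6, 2))
        ious = rng.uniform(0, 1, (6, 2))
        a1 = assign_targets(anchors, gts, cls, AssignerParams(), ious)
        a2 = assign_targets(anchors, gts, cls, AssignerParams(), ious)
        assert np.array_equal(a1.anchor_to_gt, a2.anchor_to_gt)
        assert np.array_equal(a1.metric, a2.metric)
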