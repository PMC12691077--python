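"""Text-guided detection core: EDC modulation, weighted fusion, tiny head.

Three building blocks, each usable on its own:

* ``spatial_channel_attention`` / ``edc_modulate`` / ``edc_forward`` — the
  EDC block: attention refinement ``X' = X * A_S * A_C``, text-conditioned
  modulation ``X^ = X' * gs * cs + gb + cb`` whose four parameter groups
  come from an MLP over the pooled text embedding, then
  ``Y = X + GELU(LayerNorm(X^))``. With the MLP fully zero-initialised the
  block is the identity map exactly.
* ``db_fuse`` — fast-normalised weighted fusion of equally shaped feature
  maps, the learnable fusion node of a bidirectional feature pyramid.
* ``TinyDetector`` — a miniature CPU-trainable detector: a fixed two-scale
  statistics backbone, EDC conditioning per scale, weighted cross-scale
  fusion, and per-anchor box regression plus text-embedding classification
  (sigmoid of visual/text dot products). Training uses the task-aligned
  assigner and the hybrid CIoU/GIoU loss; gradients are hand-derived
  (finite differences only for the IoU loss w.r.t. the decoded box).

All tensors are ``(B, C, H, W)`` numpy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf
from skimage.transform import resize

from .text_prior import TextEntry, encode_bank
from .training_strategy import (
    AssignerParams,
    Box,
    LossParams,
    assign_targets,
    hybrid_iou_loss,
    iou,
)

__all__ = [
    "EdcParams",
    "FusionNode",
    "Detection",
    "sigmoid",
    "gelu",
    "spatial_channel_attention",
    "edc_modulate",
    "edc_forward",
    "db_fuse",
    "nms",
    "TinyDetector",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) GELU."""
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0))) + x * np.exp(-0.5 * x * x) / math.sqrt(
        2.0 * math.pi
    )


def _check_fmap(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 4 or min(x.shape) < 1:
        raise ValueError("feature map must be (B, C, H, W) with all dims >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map has non-finite values")
    return x


@dataclass
class EdcParams:
    """Text-to-modulation MLP: one GELU hidden layer of width D, final
    layer mapping to ``2 + 2C`` outputs ``(gs, gb, cs, cb)``.

    ``zeros`` initialisation makes ``edc_forward`` the identity map;
    ``identity`` initialises the output bias at (gs=1, cs=1, gb=cb=0) so
    modulation starts as a plain pass-through of the attended features,
    which avoids the dead gs*cs=0 gradient when training.
    """

    w_hidden: np.ndarray
    b_hidden: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    channels: int

    @classmethod
    def init(
        cls, text_dim: int, channels: int, seed: int = 0, mode: str = "zeros"
    ) -> "EdcParams":
        rng = np.random.default_rng(seed)
        w_h = rng.standard_normal((text_dim, text_dim)) / math.sqrt(text_dim)
        b_h = np.zeros(text_dim)
        w_o = np.zeros((2 + 2 * channels, text_dim))
        b_o = np.zeros(2 + 2 * channels)
        if mode == "identity":
            b_o[0] = 1.0  # gs
            b_o[2: 2 + channels] = 1.0  # cs
        elif mode != "zeros":
            raise ValueError("mode must be 'zeros' or 'identity'")
        return cls(w_h, b_h, w_o, b_o, channels)

    def modulation(self, pooled_text: np.ndarray):
        """(gs, gb, cs, cb) plus the hidden pre-activation for backprop."""
        pre = self.w_hidden @ pooled_text + self.b_hidden
        h = gelu(pre)
        out = self.w_out @ h + self.b_out
        c = self.channels
        return out[0], out[1], out[2: 2 + c], out[2 + c:], pre, h


@dataclass
class FusionNode:
    """Non-negative learnable weights, fast-normalised at fusion time."""

    raw_weights: np.ndarray
    epsilon: float = 1e-4

    def normalized(self) -> np.ndarray:
        w = np.maximum(np.asarray(self.raw_weights, dtype=float), 0.0)
        return w / (self.epsilon + w.sum())


@dataclass
class Detection:
    """A predicted box with per-class scores; confidence is their max."""

    box: Box
    class_scores: np.ndarray
    category: int

    @property
    def confidence(self) -> float:
        return float(np.max(self.class_scores))


def spatial_channel_attention(x: np.ndarray) -> np.ndarray:
    """``X' = X * A_S * A_C`` with sigmoid-squashed mean-pooled weights.

    ``A_S = sigmoid(mean over channels)`` (B,1,H,W) highlights locations;
    ``A_C = sigmoid(mean over space)`` (B,C,1,1) highlights channels.
    """
    x = _check_fmap(x)
    a_s = sigmoid(x.mean(axis=1, keepdims=True))
    a_c = sigmoid(x.mean(axis=(2, 3), keepdims=True))
    return x * a_s * a_c


def edc_modulate(
    xp: np.ndarray, pooled_text: np.ndarray, params: EdcParams
) -> np.ndarray:
    """``X^ = X' * gs * cs + gb + cb`` (scalars gs, gb; per-channel cs, cb)."""
    xp = _check_fmap(xp)
    if xp.shape[1] != params.channels:
        raise ValueError(
            f"channel mismatch: map has {xp.shape[1]}, params expect {params.channels}"
        )
    gs, gb, cs, cb, _, _ = params.modulation(np.asarray(pooled_text, dtype=float))
    return xp * gs * cs[None, :, None, None] + gb + cb[None, :, None, None]


def _layer_norm(x: np.ndarray, eps: float = 1e-6):
    """Normalise over the channel axis at each (b, h, w) position."""
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    return (x - mu) * inv, inv


def edc_forward(
    x: np.ndarray, pooled_text: np.ndarray, params: EdcParams
) -> np.ndarray:
    """Full EDC block: ``Y = X + GELU(LayerNorm(X^))`` with X^ as above."""
    x = _check_fmap(x)
    xp = spatial_channel_attention(x)
    xh = edc_modulate(xp, pooled_text, params)
    z, _ = _layer_norm(xh)
    return x + gelu(z)


def db_fuse(inputs: Sequence[np.ndarray], node: FusionNode) -> np.ndarray:
    """Fast-normalised fusion ``sum_i w_i I_i / (eps + sum_j w_j)``."""
    if len(inputs) < 2:
        raise ValueError("fusion needs at least two inputs")
    arrs = [_check_fmap(a) for a in inputs]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("fusion inputs must share one shape")
    w = node.normalized()
    if w.size != len(arrs):
        raise ValueError("one raw weight per input branch required")
    out = np.zeros(shape)
    for wi, a in zip(w, arrs):
        out += wi * a
    return out


def nms(
    detections: list[Detection], iou_thr: float = 0.5
) -> list[Detection]:
    """Class-wise greedy non-maximum suppression."""
    kept: list[Detection] = []
    by_cat: dict[int, list[Detection]] = {}
    for d in detections:
        by_cat.setdefault(d.category, []).append(d)
    for cat_dets in by_cat.values():
        cat_dets.sort(key=lambda d: -d.confidence)
        chosen: list[Detection] = []
        for d in cat_dets:
            if all(iou(d.box, c.box) < iou_thr for c in chosen):
                chosen.append(d)
        kept.extend(chosen)
    kept.sort(key=lambda d: -d.confidence)
    return kept


# ---------------------------------------------------------------------------
# Miniature detector
# ---------------------------------------------------------------------------

_INPUT_H, _INPUT_W = 144, 192
_CELL_FINE, _CELL_COARSE = 8, 16
_N_FEAT = 24  # fixed backbone channels


def _cell_features(img01: np.ndarray, cell: int) -> np.ndarray:
    """Fixed per-cell statistics backbone at one scale -> (1, C, H, W).

    Per cell: mean R/G/B, colour-opponent R-G and G-B, grayscale std and
    mean |dI/dx|, |dI/dy|; directional context (mean R/G/B of the cell
    above, below, left, right); normalised cell-centre x/y and a bias
    channel. The directional context is what lets a shallow head tell
    apart regions whose own appearance coincides.
    """
    h, w = img01.shape[0] // cell, img01.shape[1] // cell
    blocks = img01[: h * cell, : w * cell].reshape(h, cell, w, cell, 3)
    mean_rgb = blocks.mean(axis=(1, 3))  # (h, w, 3)
    gray = img01 @ np.array([0.299, 0.587, 0.114])
    gb = gray[: h * cell, : w * cell].reshape(h, cell, w, cell)
    std = gb.std(axis=(1, 3))
    gx = np.abs(np.diff(gray, axis=1, prepend=gray[:, :1]))
    gy = np.abs(np.diff(gray, axis=0, prepend=gray[:1]))
    gxb = gx[: h * cell, : w * cell].reshape(h, cell, w, cell).mean(axis=(1, 3))
    gyb = gy[: h * cell, : w * cell].reshape(h, cell, w, cell).mean(axis=(1, 3))
    pad = np.pad(mean_rgb, ((1, 1), (1, 1), (0, 0)), mode="edge")
    above = pad[:-2, 1:-1]
    below = pad[2:, 1:-1]
    left = pad[1:-1, :-2]
    right = pad[1:-1, 2:]
    xs = (np.arange(w) + 0.5) / w
    ys = (np.arange(h) + 0.5) / h
    posx = np.tile(xs, (h, 1))
    posy = np.tile(ys[:, None], (1, w))
    feats = np.stack(
        [
            mean_rgb[..., 0], mean_rgb[..., 1], mean_rgb[..., 2],
            mean_rgb[..., 0] - mean_rgb[..., 1],
            mean_rgb[..., 1] - mean_rgb[..., 2],
            std, gxb, gyb,
            above[..., 0], above[..., 1], above[..., 2],
            below[..., 0], below[..., 1], below[..., 2],
            left[..., 0], left[..., 1], left[..., 2],
            right[..., 0], right[..., 1], right[..., 2],
            posx, posy, np.ones((h, w)),
            mean_rgb.mean(axis=2),
        ]
    )
    return feats[None]


@dataclass
class TinyDetector:
    """Two-scale miniature text-conditioned detector (pure numpy).

    Categories are defined by the text bank: per-anchor class logits are
    scaled dot products between a learned visual embedding and the bank's
    pooled text embeddings, so swapping the bank changes class scores but
    never box geometry.
    """

    bank: list[TextEntry]
    text_dim: int = 64
    seed: int = 0
    base_size: float = 32.0
    score_thr: float = 0.25
    nms_iou: float = 0.5
    assigner: AssignerParams = field(default_factory=lambda: AssignerParams(topk=5))
    loss_params: LossParams = field(default_factory=LossParams)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        self.text_embeddings = encode_bank(self.bank, self.text_dim, seed=0)
        self.categories = [e.category for e in self.bank]
        c, d = _N_FEAT, self.text_dim
        self.edc = EdcParams.init(d, c, seed=self.seed, mode="identity")
        self.fusion = FusionNode(np.array([1.0, 1.0]))
        self.params = {
            "w_box": rng.standard_normal((4, c)) * 0.01,
            "b_box": np.zeros(4),
            "w_emb": rng.standard_normal((d, c)) * 0.1,
            "b_emb": np.zeros(d),
            "tau": np.array([1.0]),
            "bias_cls": np.array([-2.0]),
            "edc_w_hidden": self.edc.w_hidden,
            "edc_b_hidden": self.edc.b_hidden,
            "edc_w_out": self.edc.w_out,
            "edc_b_out": self.edc.b_out,
            "fusion_raw": self.fusion.raw_weights.astype(float),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def set_bank(self, bank: list[TextEntry]) -> None:
        """Swap the text bank (and hence the category set) in place."""
        self.bank = bank
        self.text_embeddings = encode_bank(bank, self.text_dim, seed=0)
        self.categories = [e.category for e in bank]

    @property
    def _pooled_text(self) -> np.ndarray:
        return self.text_embeddings.mean(axis=0)

    def _forward_features(self, img01: np.ndarray) -> dict:
        """Backbone -> EDC per scale -> fused map, with backprop caches."""
        self.edc.w_hidden = self.params["edc_w_hidden"]
        self.edc.b_hidden = self.params["edc_b_hidden"]
        self.edc.w_out = self.params["edc_w_out"]
        self.edc.b_out = self.params["edc_b_out"]
        self.fusion.raw_weights = self.params["fusion_raw"]
        t_bar = self._pooled_text
        gs, gb, cs, cb, pre_h, hid = self.edc.modulation(t_bar)
        cache = {"gs": gs, "gb": gb, "cs": cs, "cb": cb, "pre_h": pre_h,
                 "hid": hid, "t_bar": t_bar, "scales": []}
        outs = []
        for cell in (_CELL_FINE, _CELL_COARSE):
            x = _cell_features(img01, cell)
            xp = spatial_channel_attention(x)
            xh = xp * gs * cs[None, :, None, None] + gb + cb[None, :, None, None]
            z, inv = _layer_norm(xh)
            g = gelu(z)
            y = x + g
            cache["scales"].append({"x": x, "xp": xp, "z": z, "inv": inv})
            outs.append(y)
        fine, coarse = outs
        up = coarse.repeat(2, axis=2).repeat(2, axis=3)
        w = self.fusion.normalized()
        fused = w[0] * fine + w[1] * up
        cache.update(fine=fine, up=up, w_norm=w, fused=fused)
        return cache

    def _anchors(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = _INPUT_H // _CELL_FINE, _INPUT_W // _CELL_FINE
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        ax = (xs.ravel() + 0.5) * _CELL_FINE
        ay = (ys.ravel() + 0.5) * _CELL_FINE
        return ax, ay

    def _heads(self, fused: np.ndarray):
        """Per-anchor raw box params, decoded boxes and class scores."""
        c = fused.shape[1]
        feats = fused[0].reshape(c, -1).T  # (A, C)
        t = feats @ self.params["w_box"].T + self.params["b_box"]  # (A, 4)
        e = feats @ self.params["w_emb"].T + self.params["b_emb"]  # (A, D)
        logits = (e @ self.text_embeddings.T) * self.params["tau"][0] + self.params[
            "bias_cls"
        ][0]
        scores = sigmoid(logits)
        ax, ay = self._anchors()
        reach = 2.0 * _CELL_FINE  # offsets may reach two cells out
        cx = ax + np.tanh(t[:, 0]) * reach
        cy = ay + np.tanh(t[:, 1]) * reach
        bw = self.base_size * np.exp(np.clip(t[:, 2], -4, 4))
        bh = self.base_size * np.exp(np.clip(t[:, 3], -4, 4))
        return feats, t, e, logits, scores, np.stack([cx, cy, bw, bh], axis=1)

    @staticmethod
    def _decode_box(cxcywh: np.ndarray, img_w: float, img_h: float) -> Box | None:
        cx, cy, w, h = cxcywh
        x1, y1 = cx - w / 2, cy - h / 2
        x2, y2 = cx + w / 2, cy + h / 2
        x1, x2 = max(0.0, x1), min(img_w, x2)
        y1, y2 = max(0.0, y1), min(img_h, y2)
        if x2 - x1 <= 1e-6 or y2 - y1 <= 1e-6:
            return None
        return Box(x1, y1, x2, y2)

    def predict(self, img: np.ndarray) -> list[Detection]:
        """Run the detector on an 8-bit RGB image; boxes in input pixels."""
        img = np.asarray(img)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("expected an H x W x 3 image")
        h0, w0 = img.shape[:2]
        img01 = resize(
            img.astype(float) / 255.0, (_INPUT_H, _INPUT_W), anti_aliasing=True
        )
        cache = self._forward_features(img01)
        _, _, _, _, scores, boxes = self._heads(cache["fused"])
        sx, sy = w0 / _INPUT_W, h0 / _INPUT_H
        dets: list[Detection] = []
        for i in range(scores.shape[0]):
            conf = float(scores[i].max())
            if conf < self.score_thr:
                continue
            b = self._decode_box(boxes[i], _INPUT_W, _INPUT_H)
            if b is None:
                continue
            dets.append(
                Detection(
                    box=Box(b.x1 * sx, b.y1 * sy, b.x2 * sx, b.y2 * sy),
                    class_scores=scores[i].copy(),
                    category=int(np.argmax(scores[i])),
                )
            )
        return nms(dets, self.nms_iou)

    # -- training ----------------------------------------------------------

    def _compute_targets(
        self, scores: np.ndarray, boxes: np.ndarray, gts: list[tuple[Box, int]]
    ) -> tuple[np.ndarray, list[tuple[int, int]]]:
        """Run the task-aligned assigner; targets are detached from the
        parameters (standard stop-gradient treatment of label assignment)."""
        n_a, n_k = scores.shape
        pred_boxes = [self._decode_box(b, _INPUT_W, _INPUT_H) for b in boxes]
        gt_boxes = [b for b, _ in gts]
        targets = np.zeros((n_a, n_k))
        pos: list[tuple[int, int]] = []
        if gt_boxes:
            ious = np.zeros((n_a, len(gts)))
            cls_for_gt = np.zeros((n_a, len(gts)))
            for j, (gb, gcat) in enumerate(gts):
                for i in range(n_a):
                    if pred_boxes[i] is not None:
                        ious[i, j] = iou(pred_boxes[i], gb)
                cls_for_gt[:, j] = scores[:, gcat]
            ax, ay = self._anchors()
            anchors = list(zip(ax, ay))
            asg = assign_targets(anchors, gt_boxes, cls_for_gt, self.assigner, ious)
            # task-aligned soft labels: each positive's class target is its
            # alignment metric normalised by the per-gt maximum, so the
            # confidence ranking tracks localisation quality
            m_max = np.maximum(asg.metric.max(axis=0), 1e-12)
            for i, j in enumerate(asg.anchor_to_gt):
                if j >= 0:
                    targets[i, gts[j][1]] = asg.metric[i, j] / m_max[j]
                    pos.append((i, j))
        return targets, pos

    def _image_loss_and_grads(
        self,
        img01: np.ndarray,
        gts: list[tuple[Box, int]],
        frozen: tuple[np.ndarray, list[tuple[int, int]]] | None = None,
    ) -> tuple[float, dict]:
        cache = self._forward_features(img01)
        feats, t_raw, e, logits, scores, boxes = self._heads(cache["fused"])
        n_a, n_k = scores.shape
        gt_boxes = [b for b, _ in gts]
        targets, pos = frozen if frozen is not None else self._compute_targets(
            scores, boxes, gts
        )

        # classification: BCE with up-weighted positives
        pos_w = 5.0
        wmat = np.where(targets > 0, pos_w, 1.0)
        p = np.clip(scores, 1e-7, 1 - 1e-7)
        cls_loss = float(
            np.sum(wmat * -(targets * np.log(p) + (1 - targets) * np.log(1 - p)))
        ) / (n_a * n_k)
        dlogits = wmat * (p - targets) / (n_a * n_k)

        # box regression: hybrid IoU loss on positives, FD grads on (cx,cy,w,h)
        box_loss = 0.0
        dboxes = np.zeros((n_a, 4))
        if pos:
            h_fd = 0.01
            for i, j in pos:
                gb = gt_boxes[j]

                def loss_of(v: np.ndarray) -> float:
                    b = self._decode_box(v, _INPUT_W, _INPUT_H)
                    return 2.0 if b is None else hybrid_iou_loss(b, gb, self.loss_params)

                base = loss_of(boxes[i])
                box_loss += base
                for d in range(4):
                    vp, vm = boxes[i].copy(), boxes[i].copy()
                    vp[d] += h_fd
                    vm[d] -= h_fd
                    dboxes[i, d] = (loss_of(vp) - loss_of(vm)) / (2 * h_fd)
            box_loss /= len(pos)
            dboxes /= len(pos)

        # chain decode derivatives into the raw box outputs
        dt = np.zeros_like(t_raw)
        reach = 2.0 * _CELL_FINE
        dt[:, 0] = dboxes[:, 0] * (1 - np.tanh(t_raw[:, 0]) ** 2) * reach
        dt[:, 1] = dboxes[:, 1] * (1 - np.tanh(t_raw[:, 1]) ** 2) * reach
        in_range2 = np.abs(t_raw[:, 2]) < 4
        in_range3 = np.abs(t_raw[:, 3]) < 4
        dt[:, 2] = dboxes[:, 2] * boxes[:, 2] * in_range2
        dt[:, 3] = dboxes[:, 3] * boxes[:, 3] * in_range3

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        # heads
        de = (dlogits * self.params["tau"][0]) @ self.text_embeddings  # (A, D)
        grads["tau"][0] = float(np.sum(dlogits * (e @ self.text_embeddings.T)))
        grads["bias_cls"][0] = float(np.sum(dlogits))
        grads["w_emb"] = de.T @ feats
        grads["b_emb"] = de.sum(axis=0)
        grads["w_box"] = dt.T @ feats
        grads["b_box"] = dt.sum(axis=0)
        dfeats = de @ self.params["w_emb"] + dt @ self.params["w_box"]  # (A, C)
        c = feats.shape[1]
        hf, wf = _INPUT_H // _CELL_FINE, _INPUT_W // _CELL_FINE
        dfused = dfeats.T.reshape(1, c, hf, wf)

        # fusion node
        w_norm = cache["w_norm"]
        raw = np.maximum(self.params["fusion_raw"], 0.0)
        s = self.fusion.epsilon + raw.sum()
        branch = [cache["fine"], cache["up"]]
        dnorm = np.array([float(np.sum(dfused * b)) for b in branch])
        for a in range(2):
            for b in range(2):
                if self.params["fusion_raw"][b] <= 0:
                    continue
                jac = (1.0 if a == b else 0.0) / s - raw[a] / s**2
                grads["fusion_raw"][b] += dnorm[a] * jac
        dy_fine = w_norm[0] * dfused
        dy_up = w_norm[1] * dfused
        # sum-pool the upsampled gradient back to the coarse grid
        hc, wc = hf // 2, wf // 2
        dy_coarse = dy_up.reshape(1, c, hc, 2, wc, 2).sum(axis=(3, 5))

        # EDC parameter gradients (shared across scales)
        gs, cs = cache["gs"], cache["cs"]
        d_gs = d_gb = 0.0
        d_cs = np.zeros_like(cs)
        d_cb = np.zeros_like(cs)
        for dy, sc in zip((dy_fine, dy_coarse), cache["scales"]):
            dz = dy * _gelu_grad(sc["z"])
            z, inv = sc["z"], sc["inv"]
            nchan = z.shape[1]
            dxh = inv * (
                dz
                - dz.mean(axis=1, keepdims=True)
                - z * (dz * z).mean(axis=1, keepdims=True)
            )
            xp = sc["xp"]
            d_gs += float(np.sum(dxh * xp * cs[None, :, None, None]))
            d_cs += np.sum(dxh * xp, axis=(0, 2, 3)) * gs
            d_gb += float(np.sum(dxh))
            d_cb += np.sum(dxh, axis=(0, 2, 3))
        d_out = np.concatenate([[d_gs, d_gb], d_cs, d_cb])
        hid, pre_h, t_bar = cache["hid"], cache["pre_h"], cache["t_bar"]
        grads["edc_w_out"] = np.outer(d_out, hid)
        grads["edc_b_out"] = d_out
        dh = self.params["edc_w_out"].T @ d_out
        dpre = dh * _gelu_grad(pre_h)
        grads["edc_w_hidden"] = np.outer(dpre, t_bar)
        grads["edc_b_hidden"] = dpre

        return cls_loss + box_loss, grads

    def fit(
        self,
        images: Sequence[np.ndarray],
        annotations: Sequence[Sequence[tuple[Box, int]]],
        epochs: int = 100,
        lr: float = 0.02,
        batch_size: int = 8,
        seed: int | None = None,
        verbose: bool = False,
    ) -> list[float]:
        """Train with Adam on (image, [(box, category_index)]) pairs.

        Ground-truth boxes are given in original image pixels and are
        rescaled to the detector's working resolution internally. Returns
        the per-epoch mean loss trace.
        """
        rng = np.random.default_rng(self.seed if seed is None else seed)
        prepped = []
        for img, anns in zip(images, annotations, strict=True):
            h0, w0 = img.shape[:2]
            img01 = resize(
                np.asarray(img).astype(float) / 255.0,
                (_INPUT_H, _INPUT_W),
                anti_aliasing=True,
            )
            sx, sy = _INPUT_W / w0, _INPUT_H / h0
            gts = [
                (Box(b.x1 * sx, b.y1 * sy, b.x2 * sx, b.y2 * sy), cat)
                for b, cat in anns
            ]
            prepped.append((img01, gts))
        trace = []
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for epoch in range(epochs):
            # cosine decay to a tenth of the initial rate
            lr_t = lr * (0.55 + 0.45 * math.cos(math.pi * epoch / max(1, epochs - 1)))
            order = rng.permutation(len(prepped))
            losses = []
            for start in range(0, len(order), batch_size):
                idx = order[start: start + batch_size]
                agg = {k: np.zeros_like(v) for k, v in self.params.items()}
                batch_loss = 0.0
                for i in idx:
                    loss, grads = self._image_loss_and_grads(*prepped[i])
                    batch_loss += loss
                    for k in agg:
                        agg[k] += grads[k]
                for k in agg:
                    agg[k] /= len(idx)
                batch_loss /= len(idx)
                losses.append(batch_loss)
                self._adam_t += 1
                for k, g in agg.items():
                    m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
                    v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
                    mh = m / (1 - beta1**self._adam_t)
                    vh = v / (1 - beta2**self._adam_t)
                    self.params[k] -= lr_t * mh / (np.sqrt(vh) + eps)
            trace.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}  loss {trace[-1]:.4f}")
        return trace

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path,
            **self.params,
            text_dim=np.array([self.text_dim]),
            base_size=np.array([self.base_size]),
        )

    def load(self, path) -> None:
        with np.load(path) as ckpt:
            for k in self.params:
                self.params[k] = ckpt[k].copy()
            self.base_size = float(ckpt["base_size"][0])
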