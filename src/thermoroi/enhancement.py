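"""Illumination-adaptive image enhancement.

A grayscale gate classifies each frame into one of three regimes from its
mean luminance mu:

* ``low_light``   (mu < T_low, default 60)  -> Retinex enhancement,
* ``overexposed`` (mu >= T_high, default 150) -> CLAHE on the Lab L channel,
* ``normal_light`` otherwise -> identity.

The Retinex path decomposes the normalised image I into reflectance R and
illumination L with I = R * L, by alternating minimisation of the energy

    eps(P, Q, R, L) = ||I - P*R||_F^2 + alpha*phi(R) + beta*psi(L)
                      + gamma*||P - Q||_F^2 + lambda*||Q - L||_F^2

where P, Q are auxiliary illumination variables coupling the data term to
L, and phi/psi are quadratic finite-difference smoothness penalties.
P and Q have closed-form updates; R and L take projected gradient steps
with backtracking, so the energy is non-increasing by construction. The
enhanced image is R * L**omega (gamma-style brightening of illumination).

The CLAHE path is contrast-limited adaptive histogram equalisation of the
luminance channel in Lab space: per-tile histograms clipped at a limit,
the excess redistributed mass-exactly, per-tile CDF mappings to 0-255,
and bilinear blending of the four neighbouring tile mappings per pixel.
Chromaticity (a, b) passes through untouched.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from skimage import color

__all__ = [
    "Illumination",
    "IlluminationLabel",
    "RetinexParams",
    "RetinexDecomposition",
    "ClaheParams",
    "rgb_to_gray",
    "mean_luminance",
    "classify_illumination",
    "retinex_init",
    "retinex_energy",
    "retinex_unfold",
    "adjust_illumination",
    "enhance_lowlight",
    "clip_redistribute",
    "apply_clahe_lab",
    "enhance_overexposed",
    "enhance_auto",
]

GRAY_WEIGHTS = (0.299, 0.587, 0.114)
_EPS = 1e-4


class Illumination(enum.Enum):
    LOW_LIGHT = "low_light"
    NORMAL_LIGHT = "normal_light"
    OVEREXPOSED = "overexposed"


@dataclass(frozen=True)
class IlluminationLabel:
    label: Illumination
    mean_luminance: float


@dataclass(frozen=True)
class RetinexParams:
    """Hyperparameters of the Retinex decomposition.

    mu_init weights the structure term of the initialiser; alpha_reg and
    beta_reg weight reflectance/illumination smoothness; gamma_pen and
    lambda_pen couple the auxiliary illumination variables; stages is the
    number of unfolding iterations; omega in (0, 1] is the brightening
    exponent applied to the illumination map (smaller -> brighter).
    """

    mu_init: float = 0.05
    alpha_reg: float = 0.001
    beta_reg: float = 0.01
    gamma_pen: float = 0.1
    lambda_pen: float = 0.1
    stages: int = 3
    omega: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mu_init", "alpha_reg", "beta_reg", "gamma_pen", "lambda_pen"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.stages < 0:
            raise ValueError("stages must be >= 0")
        if not 0.0 < self.omega <= 1.0:
            raise ValueError("omega must lie in (0, 1]")


@dataclass
class RetinexDecomposition:
    """Reflectance (H, W, 3) in [0, 1] and illumination (H, W) in (0, 1]."""

    reflectance: np.ndarray
    illumination: np.ndarray


@dataclass(frozen=True)
class ClaheParams:
    clip_limit: float = 3.0
    grid_rows: int = 8
    grid_cols: int = 8
    bins: int = 256

    def __post_init__(self) -> None:
        if self.clip_limit < 1:
            raise ValueError("clip_limit must be >= 1")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dims must be >= 1")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("expected a non-empty H x W x 3 image")
    return img


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Luminance 0.299 R + 0.587 G + 0.114 B, kept real-valued."""
    img = _check_rgb(img).astype(float)
    r, g, b = GRAY_WEIGHTS
    return r * img[..., 0] + g * img[..., 1] + b * img[..., 2]


def mean_luminance(gray: np.ndarray) -> float:
    gray = np.asarray(gray, dtype=float)
    if gray.size == 0:
        raise ValueError("empty image")
    return float(gray.mean())


def classify_illumination(
    mu: float, t_low: float = 60.0, t_high: float = 150.0
) -> IlluminationLabel:
    """Threshold gate: low if mu < t_low, overexposed if mu >= t_high."""
    if t_low >= t_high:
        raise ValueError("t_low must be < t_high")
    if mu < t_low:
        lab = Illumination.LOW_LIGHT
    elif mu >= t_high:
        lab = Illumination.OVEREXPOSED
    else:
        lab = Illumination.NORMAL_LIGHT
    return IlluminationLabel(lab, float(mu))


# ---------------------------------------------------------------------------
# Retinex path
# ---------------------------------------------------------------------------


def retinex_init(
    img_norm: np.ndarray, params: RetinexParams | None = None
) -> RetinexDecomposition:
    """Closed-form initial decomposition.

    L0 is the per-pixel max over RGB (floored at a small epsilon), the
    structure term's minimiser; R0 = I / L0 clipped to [0, 1], so R0 * L0
    reconstructs the input wherever L0 exceeds the floor.
    """
    img_norm = _check_rgb(img_norm).astype(float)
    l0 = np.maximum(img_norm.max(axis=2), _EPS)
    r0 = np.clip(img_norm / l0[..., None], 0.0, 1.0)
    return RetinexDecomposition(reflectance=r0, illumination=l0)


def _grad_sq(a: np.ndarray) -> float:
    """Sum of squared forward differences over all axes of the first two dims."""
    s = float(np.sum(np.diff(a, axis=0) ** 2)) + float(np.sum(np.diff(a, axis=1) ** 2))
    return s


def _grad_sq_grad(a: np.ndarray) -> np.ndarray:
    """Gradient of ``_grad_sq`` with respect to ``a`` (works for 2-D or 3-D)."""
    g = np.zeros_like(a)
    dy = np.diff(a, axis=0)
    dx = np.diff(a, axis=1)
    g[1:, ...] += 2 * dy
    g[:-1, ...] -= 2 * dy
    g[:, 1:, ...] += 2 * dx
    g[:, :-1, ...] -= 2 * dx
    return g


def retinex_energy(
    img_norm: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    r: np.ndarray,
    l: np.ndarray,
    params: RetinexParams,
) -> float:
    """The alternating-minimisation objective (see module docstring)."""
    data = float(np.sum((img_norm - p[..., None] * r) ** 2))
    return (
        data
        + params.alpha_reg * _grad_sq(r)
        + params.beta_reg * _grad_sq(l)
        + params.gamma_pen * float(np.sum((p - q) ** 2))
        + params.lambda_pen * float(np.sum((q - l) ** 2))
    )


def _backtracked_step(
    var: np.ndarray,
    grad: np.ndarray,
    lo: float,
    hi: float,
    energy_of,
    e_now: float,
    step0: float = 0.5,
    max_halvings: int = 20,
) -> tuple[np.ndarray, float]:
    """Projected gradient step accepted only if the energy does not increase."""
    gmax = float(np.max(np.abs(grad)))
    if gmax == 0.0 or not math.isfinite(gmax):
        return var, e_now
    step = step0 / gmax
    for _ in range(max_halvings):
        cand = np.clip(var - step * grad, lo, hi)
        e_new = energy_of(cand)
        if e_new <= e_now:
            return cand, e_new
        step *= 0.5
    return var, e_now


def retinex_unfold(
    init: RetinexDecomposition,
    img_norm: np.ndarray,
    params: RetinexParams | None = None,
    return_energies: bool = False,
):
    """Alternating block minimisation of the decomposition energy.

    Each stage updates P and Q in closed form and R and L by projected
    backtracking gradient steps; the energy sequence is non-increasing.
    With ``stages == 0`` the initial decomposition is returned unchanged.
    """
    params = params or RetinexParams()
    img_norm = _check_rgb(img_norm).astype(float)
    r = init.reflectance.astype(float).copy()
    l = init.illumination.astype(float).copy()
    p = l.copy()
    q = l.copy()
    energies = [retinex_energy(img_norm, p, q, r, l, params)]
    for stage in range(params.stages):
        # P: exact minimiser of the data + gamma coupling terms
        num = np.sum(img_norm * r, axis=2) + params.gamma_pen * q
        den = np.sum(r**2, axis=2) + params.gamma_pen
        p = num / np.maximum(den, 1e-12)
        # Q: exact minimiser of the two quadratic couplings
        gl = params.gamma_pen + params.lambda_pen
        q = (params.gamma_pen * p + params.lambda_pen * l) / gl if gl > 0 else p
        e_now = retinex_energy(img_norm, p, q, r, l, params)
        # R: projected backtracking gradient step on [0, 1]
        resid = img_norm - p[..., None] * r
        grad_r = -2.0 * p[..., None] * resid + params.alpha_reg * _grad_sq_grad(r)
        r, e_now = _backtracked_step(
            r, grad_r, 0.0, 1.0,
            lambda c: retinex_energy(img_norm, p, q, c, l, params), e_now,
        )
        # L: projected backtracking gradient step on [eps, 1]
        grad_l = params.beta_reg * _grad_sq_grad(l) + 2.0 * params.lambda_pen * (l - q)
        l, e_now = _backtracked_step(
            l, grad_l, _EPS, 1.0,
            lambda c: retinex_energy(img_norm, p, q, r, c, params), e_now,
        )
        if not math.isfinite(e_now):
            raise ArithmeticError(f"non-finite Retinex energy at stage {stage}")
        energies.append(e_now)
    out = RetinexDecomposition(reflectance=r, illumination=l)
    return (out, energies) if return_energies else out


def adjust_illumination(l: np.ndarray, omega: float) -> np.ndarray:
    """Gamma-style brightening ``L**omega``; monotone, fixes L = 1."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    return np.asarray(l, dtype=float) ** omega


def enhance_lowlight(
    img: np.ndarray, params: RetinexParams | None = None
) -> np.ndarray:
    """Retinex low-light enhancement: decompose, brighten L, recompose.

    Returns an 8-bit image ``clip(R_T * L_T**omega * 255)``; since
    omega <= 1 the brightened illumination dominates the original wherever
    L < 1, raising mean luminance of dim frames.
    """
    params = params or RetinexParams()
    img = _check_rgb(img)
    img_norm = img.astype(float) / 255.0
    dec = retinex_unfold(retinex_init(img_norm, params), img_norm, params)
    l_adj = adjust_illumination(dec.illumination, params.omega)
    out = dec.reflectance * l_adj[..., None] * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# CLAHE path
# ---------------------------------------------------------------------------


def clip_redistribute(hist: np.ndarray, clip_count: int) -> np.ndarray:
    """Clip histogram bins at ``clip_count`` and redistribute the excess.

    The excess is spread uniformly across bins with headroom (integer
    shares; the remainder goes one count each to the lowest-index bins
    with headroom). Total mass is conserved exactly and no output bin
    exceeds ``clip_count`` provided ``clip_count * bins >= sum(hist)``.
    """
    if clip_count < 1:
        raise ValueError("clip_count must be >= 1")
    h = np.asarray(hist, dtype=np.int64).copy()
    if np.any(h < 0):
        raise ValueError("histogram entries must be >= 0")
    excess = int(np.sum(np.maximum(h - clip_count, 0)))
    if excess == 0:
        return h
    np.minimum(h, clip_count, out=h)
    while excess > 0:
        room = np.nonzero(h < clip_count)[0]
        if room.size == 0:
            # mass exceeds clip_count * bins: the cap is infeasible, so the
            # remainder is spread uniformly to keep conservation exact
            share, rem = divmod(excess, h.size)
            h += share
            h[:rem] += 1
            break
        share = excess // room.size
        if share == 0:
            h[room[:excess]] += 1
            excess = 0
        else:
            add = np.minimum(share, clip_count - h[room])
            h[room] += add
            excess -= int(add.sum())
    return h


def _tile_edges(n: int, tiles: int) -> np.ndarray:
    """Edges of ``tiles`` contiguous tiles; the last absorbs the remainder."""
    size = n // tiles
    edges = np.arange(tiles + 1) * size
    edges[-1] = n
    return edges


def _tile_mappings(l8: np.ndarray, params: ClaheParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-tile CDF mappings (gr, gc, bins) -> 0..255 and tile centres."""
    h, w = l8.shape
    gr, gc = params.grid_rows, params.grid_cols
    if h // gr == 0 or w // gc == 0:
        raise ValueError("tile grid larger than image")
    ye, xe = _tile_edges(h, gr), _tile_edges(w, gc)
    bins = params.bins
    bin_of = (l8.astype(np.int64) * bins) // 256
    maps = np.zeros((gr, gc, bins))
    for i in range(gr):
        for j in range(gc):
            tile = bin_of[ye[i]: ye[i + 1], xe[j]: xe[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=bins)
            clip_count = max(1, math.ceil(params.clip_limit * tile.size / bins))
            hist = clip_redistribute(hist, clip_count)
            cdf = np.cumsum(hist)
            maps[i, j] = 255.0 * cdf / cdf[-1]
    cy = 0.5 * (ye[:-1] + ye[1:] - 1)
    cx = 0.5 * (xe[:-1] + xe[1:] - 1)
    return maps, cy, cx


def _interp_axis(coords: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bracketing tile indices (i0, i1) and the weight on i0 per coordinate."""
    i1 = np.searchsorted(centers, coords, side="right")
    i0 = np.clip(i1 - 1, 0, centers.size - 1)
    i1 = np.clip(i1, 0, centers.size - 1)
    span = centers[i1] - centers[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(span > 0, (coords - centers[i0]) / np.where(span > 0, span, 1.0), 0.0)
    return i0, i1, 1.0 - frac


def apply_clahe_lab(lab: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """CLAHE on an 8-bit-scaled Lab array; a and b pass through bit-exact.

    ``lab[..., 0]`` is luminance on the 0-255 scale. Every pixel's output
    is the bilinear blend (weights >= 0, summing to 1) of the mappings of
    its 4 neighbouring tiles; border pixels fall back to 1 or 2 tiles.
    """
    params = params or ClaheParams()
    lab = np.asarray(lab, dtype=float)
    l8 = np.clip(np.rint(lab[..., 0]), 0, 255).astype(np.int64)
    maps, cy, cx = _tile_mappings(l8, params)
    h, w = l8.shape
    bins = params.bins
    bin_of = (l8 * bins) // 256
    ys, xs = np.arange(h, dtype=float), np.arange(w, dtype=float)
    r0, r1, wy = _interp_axis(ys, cy)
    c0, c1, wx = _interp_axis(xs, cx)
    r0g, c0g = np.meshgrid(r0, c0, indexing="ij")
    r1g, c1g = np.meshgrid(r1, c1, indexing="ij")
    wyg, wxg = np.meshgrid(wy, wx, indexing="ij")
    out = (
        wyg * wxg * maps[r0g, c0g, bin_of]
        + wyg * (1 - wxg) * maps[r0g, c1g, bin_of]
        + (1 - wyg) * wxg * maps[r1g, c0g, bin_of]
        + (1 - wyg) * (1 - wxg) * maps[r1g, c1g, bin_of]
    )
    result = lab.copy()
    result[..., 0] = out
    return result


def enhance_overexposed(
    img: np.ndarray, params: ClaheParams | None = None
) -> np.ndarray:
    """CLAHE on the Lab luminance channel of an overexposed 8-bit image."""
    params = params or ClaheParams()
    img = _check_rgb(img)
    lab = color.rgb2lab(img.astype(np.uint8))  # D65
    lab8 = lab.copy()
    lab8[..., 0] = lab[..., 0] * 255.0 / 100.0
    lab8 = apply_clahe_lab(lab8, params)
    lab[..., 0] = lab8[..., 0] * 100.0 / 255.0
    rgb = color.lab2rgb(lab)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def enhance_auto(
    img: np.ndarray,
    retinex: RetinexParams | None = None,
    clahe: ClaheParams | None = None,
    t_low: float = 60.0,
    t_high: float = 150.0,
) -> tuple[np.ndarray, IlluminationLabel]:
    """Gate on mean luminance and route to the matching enhancement path."""
    img = _check_rgb(img)
    label = classify_illumination(mean_luminance(rgb_to_gray(img)), t_low, t_high)
    if label.label is Illumination.LOW_LIGHT:
        return enhance_lowlight(img, retinex), label
    if label.label is Illumination.OVEREXPOSED:
        return enhance_overexposed(img, clahe), label
    return img, label
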