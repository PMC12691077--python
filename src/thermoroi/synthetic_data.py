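"""Seeded synthetic cow scenes: paired RGB + radiometric frames + boxes.

Each scene is a schematic Holstein cow body (an ellipse textured with
thresholded smoothed noise, giving irregular black/white patches) on a
barn-grey background, viewed from the side or the rear. The five
anatomical categories are laid out per their textual descriptions:

* rear view — the hind quarters box frames the rear; two hind legs flank
  the rear udder (RU); the anal area (AA) sits above the RU; the lower
  udder (LU) hangs below the RU at the lowest point.
* side view — the LU hangs under the belly adjacent to a hind leg; the RU
  is not visible.

The co-registered radiometric frame plants region temperatures tied to a
per-scene core (rectal) temperature RT, with AA = RT - dAA and
LU = RT - dLU, dLU > dAA > 0, so the physiological gradient
RT > AA > LU holds by construction. ROI pixels get the planted value plus
optional Gaussian noise; with zero noise, box extraction recovers the
planted temperature exactly.

RGB luminance is rescaled so the scene's mean grey lands in a requested
illumination band (low < 60, normal in [60, 150), overexposed >= 150).
Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy.ndimage import gaussian_filter

from .enhancement import Illumination, classify_illumination, mean_luminance, rgb_to_gray
from .text_prior import CATEGORIES
from .training_strategy import Box

__all__ = [
    "SceneParams",
    "SceneAnnotation",
    "generate_scene",
    "generate_dataset",
    "generate_temperature_table",
]

_REGIME_TARGET = {"low": 40.0, "normal": 105.0, "over": 180.0}

# render colours (RGB, pre-illumination-scaling)
_COL_BG = np.array([90.0, 95.0, 85.0])
_COL_WHITE = np.array([225.0, 222.0, 218.0])
_COL_BLACK = np.array([35.0, 32.0, 30.0])
_COL_LU = np.array([235.0, 175.0, 185.0])   # pale pink udder skin
_COL_RU = np.array([220.0, 150.0, 160.0])
_COL_AA = np.array([150.0, 80.0, 70.0])     # darker perianal skin


@dataclass(frozen=True)
class SceneParams:
    """Generator settings; temperature ranges in degC.

    ROI ranges default to the observed extremes for lactating Holsteins
    (LU 35.2-37.5, AA 36.9-38.5); background and body ranges sit well
    below so the animal is always the warmest surface.
    """

    width: int = 640
    height: int = 480
    regime: str = "normal"           # low | normal | over
    view: str | None = None          # side | rear | None -> random
    texture_scale: float = 12.0
    background_temp: tuple[float, float] = (15.0, 22.0)
    body_temp: tuple[float, float] = (28.0, 33.0)
    lu_range: tuple[float, float] = (35.2, 37.5)
    aa_range: tuple[float, float] = (36.9, 38.5)
    rt_mean: float = 38.7
    rt_sd: float = 0.3
    delta_aa: tuple[float, float] = (1.3, 0.15)  # mean, sd of RT - AA
    delta_lu: tuple[float, float] = (2.3, 0.25)  # mean, sd of RT - LU
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in _REGIME_TARGET:
            raise ValueError("regime must be low, normal or over")
        if self.view not in (None, "side", "rear"):
            raise ValueError("view must be side, rear or None")
        if not (
            self.background_temp[1] < self.body_temp[1] <= self.lu_range[0] + 3
            and self.lu_range[0] < self.aa_range[1]
        ):
            raise ValueError("temperature ranges must be ordered bg < body < LU < AA")


@dataclass
class SceneAnnotation:
    """Category boxes, viewpoint, and the planted region temperatures."""

    boxes: list[tuple[str, Box]]
    view: str
    planted_temps: dict[str, float] = field(default_factory=dict)
    rt: float = float("nan")

    def boxes_of(self, category: str) -> list[Box]:
        return [b for c, b in self.boxes if c == category]


def _jitter(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def _layout_rear(rng: np.random.Generator, w: int, h: int) -> list[tuple[str, Box]]:
    cx = w * _jitter(rng, 0.45, 0.55)
    hq_w = w * _jitter(rng, 0.46, 0.56)
    hq_top = h * _jitter(rng, 0.12, 0.2)
    hq_bot = h * _jitter(rng, 0.8, 0.9)
    hq = Box(cx - hq_w / 2, hq_top, cx + hq_w / 2, hq_bot)
    leg_w = hq_w * _jitter(rng, 0.16, 0.2)
    leg_top = hq_top + (hq_bot - hq_top) * _jitter(rng, 0.38, 0.46)
    leg_l = Box(hq.x1 + 0.02 * hq_w, leg_top, hq.x1 + 0.02 * hq_w + leg_w, hq_bot)
    leg_r = Box(hq.x2 - 0.02 * hq_w - leg_w, leg_top, hq.x2 - 0.02 * hq_w, hq_bot)
    ru_w = hq_w * _jitter(rng, 0.3, 0.38)
    ru_top = hq_top + (hq_bot - hq_top) * _jitter(rng, 0.5, 0.58)
    ru_h = (hq_bot - hq_top) * _jitter(rng, 0.2, 0.26)
    ru = Box(cx - ru_w / 2, ru_top, cx + ru_w / 2, ru_top + ru_h)
    aa_s = hq_w * _jitter(rng, 0.13, 0.18)
    aa_cy = hq_top + (hq_bot - hq_top) * _jitter(rng, 0.22, 0.3)
    aa = Box(cx - aa_s / 2, aa_cy - aa_s / 2, cx + aa_s / 2, aa_cy + aa_s / 2)
    lu_w = ru_w * _jitter(rng, 0.7, 0.9)
    lu_h = (hq_bot - ru.y2) * _jitter(rng, 0.5, 0.75)
    lu = Box(cx - lu_w / 2, ru.y2, cx + lu_w / 2, min(ru.y2 + lu_h, hq_bot - 1))
    return [
        ("hind_quarters", hq),
        ("hind_legs", leg_l),
        ("hind_legs", leg_r),
        ("RU", ru),
        ("AA", aa),
        ("LU", lu),
    ]


def _layout_side(rng: np.random.Generator, w: int, h: int) -> list[tuple[str, Box]]:
    body_top = h * _jitter(rng, 0.18, 0.26)
    body_bot = h * _jitter(rng, 0.58, 0.66)
    body_l = w * _jitter(rng, 0.08, 0.14)
    body_r = w * _jitter(rng, 0.86, 0.92)
    leg_w = w * _jitter(rng, 0.055, 0.075)
    leg_bot = h * _jitter(rng, 0.88, 0.95)
    hind_x = body_r - w * _jitter(rng, 0.16, 0.2)
    front_x = body_l + w * _jitter(rng, 0.1, 0.14)
    leg_hind = Box(hind_x - leg_w / 2, body_bot - 10, hind_x + leg_w / 2, leg_bot)
    leg_front = Box(front_x - leg_w / 2, body_bot - 10, front_x + leg_w / 2, leg_bot)
    lu_w = w * _jitter(rng, 0.1, 0.14)
    lu_h = h * _jitter(rng, 0.12, 0.17)
    lu_x2 = leg_hind.x1 - 2
    lu = Box(lu_x2 - lu_w, body_bot - lu_h * 0.3, lu_x2, body_bot - lu_h * 0.3 + lu_h)
    hq = Box(hind_x - w * 0.08, body_top, body_r, body_bot + h * 0.12)
    return [
        ("hind_quarters", hq),
        ("hind_legs", leg_hind),
        ("hind_legs", leg_front),
        ("LU", lu),
    ]


def _fill_ellipse(mask: np.ndarray, box: Box) -> None:
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w] + 0.5
    cx, cy = box.center
    rx, ry = box.width / 2, box.height / 2
    mask |= ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _fill_box(mask: np.ndarray, box: Box) -> None:
    h, w = mask.shape
    y0, y1 = max(0, int(box.y1)), min(h, int(np.ceil(box.y2)))
    x0, x1 = max(0, int(box.x1)), min(w, int(np.ceil(box.x2)))
    mask[y0:y1, x0:x1] = True


def _scale_to_regime(rgb: np.ndarray, regime: str) -> np.ndarray:
    """Bisect a global gain so the clipped mean grey hits the regime band."""
    target = _REGIME_TARGET[regime]

    def mean_at(s: float) -> float:
        return mean_luminance(rgb_to_gray(np.clip(rgb * s, 0, 255)))

    lo, hi = 0.01, 20.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < target:
            lo = mid
        else:
            hi = mid
    return np.clip(rgb * 0.5 * (lo + hi), 0, 255)


def generate_scene(params: SceneParams) -> tuple[np.ndarray, np.ndarray, SceneAnnotation]:
    """Render one scene; returns (rgb uint8, thermal degC float, annotation)."""
    rng = np.random.default_rng(params.seed)
    w, h = params.width, params.height
    view = params.view or ("rear" if rng.random() < 0.5 else "side")
    boxes = _layout_rear(rng, w, h) if view == "rear" else _layout_side(rng, w, h)
    by_cat: dict[str, list[Box]] = {}
    for c, b in boxes:
        by_cat.setdefault(c, []).append(b)

    body = np.zeros((h, w), dtype=bool)
    if view == "rear":
        _fill_ellipse(body, by_cat["hind_quarters"][0])
    else:
        hq = by_cat["hind_quarters"][0]
        torso = Box(hq.x1 - w * 0.55, hq.y1, hq.x2, hq.y2)
        _fill_ellipse(body, Box(max(0, torso.x1), torso.y1, torso.x2, torso.y2))
    for leg in by_cat["hind_legs"]:
        _fill_box(body, leg)

    # black/white patch texture from thresholded smoothed noise
    noise = gaussian_filter(rng.standard_normal((h, w)), params.texture_scale)
    white = noise >= 0
    rgb = np.empty((h, w, 3))
    rgb[:] = _COL_BG + rng.normal(0, 4, size=(h, w, 3))
    rgb[body & white] = _COL_WHITE
    rgb[body & ~white] = _COL_BLACK
    rgb[body] += rng.normal(0, 6, size=(int(body.sum()), 3))

    def paint(cat: str, col: np.ndarray) -> None:
        for b in by_cat.get(cat, []):
            m = np.zeros((h, w), dtype=bool)
            _fill_ellipse(m, b)
            rgb[m] = col + rng.normal(0, 5, size=(int(m.sum()), 3))

    paint("RU", _COL_RU)
    paint("LU", _COL_LU)
    paint("AA", _COL_AA)

    rgb = _scale_to_regime(rgb, params.regime)
    label = classify_illumination(mean_luminance(rgb_to_gray(rgb)))
    want = {
        "low": Illumination.LOW_LIGHT,
        "normal": Illumination.NORMAL_LIGHT,
        "over": Illumination.OVEREXPOSED,
    }[params.regime]
    if label.label is not want:
        raise RuntimeError(f"could not reach illumination regime {params.regime!r}")
    rgb8 = np.rint(rgb).astype(np.uint8)

    # radiometric frame tied to a per-scene core temperature
    rt = params.rt_mean + params.rt_sd * rng.standard_normal()
    t_aa = float(np.clip(rt - rng.normal(*params.delta_aa), *params.aa_range))
    t_lu = float(np.clip(rt - rng.normal(*params.delta_lu), *params.lu_range))
    thermal = np.full((h, w), rng.uniform(*params.background_temp))
    thermal[body] = rng.uniform(*params.body_temp)
    planted: dict[str, float] = {}
    for cat, temp in (("RU", t_lu + 0.2), ("LU", t_lu), ("AA", t_aa)):
        bs = by_cat.get(cat)
        if not bs:
            continue
        planted[cat] = temp
        for b in bs:
            m = np.zeros((h, w), dtype=bool)
            _fill_box(m, b)
            thermal[m] = temp
    if params.noise_sd > 0:
        thermal = thermal + rng.normal(0, params.noise_sd, size=(h, w))
    np.clip(thermal, -20.0, 250.0, out=thermal)

    ann = SceneAnnotation(boxes=boxes, view=view, planted_temps=planted, rt=float(rt))
    return rgb8, thermal, ann


def _split_counts(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    total = sum(ratios)
    n_train = int(round(n * ratios[0] / total))
    n_val = int(round(n * ratios[1] / total))
    return n_train, n_val, n - n_train - n_val


def generate_dataset(
    n: int,
    out_dir: str | Path,
    params: SceneParams | None = None,
    ratios: tuple[float, float, float] = (6, 2, 2),
    regime_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> dict:
    """Write n scenes (PNG + float32 TIFF + YOLO txt + COCO JSON) to disk.

    Scenes are split train/val/test (default 6:2:2) and their illumination
    regimes drawn from ``regime_mix`` (default all normal). Returns the
    manifest (also written as manifest.json) from which the dataset can be
    regenerated exactly.
    """
    if n < 5:
        raise ValueError("need n >= 5")
    params = params or SceneParams()
    regime_mix = regime_mix or {"normal": 1.0}
    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    regimes = list(regime_mix)
    probs = np.array([regime_mix[r] for r in regimes], dtype=float)
    probs /= probs.sum()
    counts = np.floor(probs * n).astype(int)
    for i in np.argsort(-(probs * n - counts))[: n - counts.sum()]:
        counts[i] += 1
    regime_list = [r for r, c in zip(regimes, counts) for _ in range(c)]
    rng.shuffle(regime_list)

    n_train, n_val, n_test = _split_counts(n, ratios)
    split_of = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    manifest = {"seed": seed, "n": n, "ratios": list(ratios), "scenes": []}
    coco: dict[str, dict] = {}
    for split in ("train", "val", "test"):
        for sub in ("images", "thermal", "labels"):
            (out / split / sub).mkdir(parents=True, exist_ok=True)
        coco[split] = {
            "images": [],
            "annotations": [],
            "categories": [{"id": i, "name": c} for i, c in enumerate(CATEGORIES)],
        }
    ann_id = 0
    for i in range(n):
        scene_seed = int(rng.integers(0, 2**31 - 1))
        sp = replace(params, regime=regime_list[i], seed=scene_seed)
        rgb, thermal, ann = generate_scene(sp)
        split = split_of[i]
        stem = f"scene_{i:04d}"
        Image.fromarray(rgb).save(out / split / "images" / f"{stem}.png")
        tifffile.imwrite(
            out / split / "thermal" / f"{stem}.tiff", thermal.astype(np.float32)
        )
        w, h = sp.width, sp.height
        lines = []
        for cat, b in ann.boxes:
            cx, cy = b.center
            lines.append(
                f"{cat_index[cat]} {cx / w:.9f} {cy / h:.9f} "
                f"{b.width / w:.9f} {b.height / h:.9f}"
            )
        (out / split / "labels" / f"{stem}.txt").write_text("\n".join(lines) + "\n")
        coco[split]["images"].append(
            {"id": i, "file_name": f"{stem}.png", "width": w, "height": h}
        )
        for cat, b in ann.boxes:
            coco[split]["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": i,
                    "category_id": cat_index[cat],
                    "bbox": [b.x1, b.y1, b.width, b.height],
                    "area": b.area,
                }
            )
            ann_id += 1
        manifest["scenes"].append(
            {
                "stem": stem,
                "split": split,
                "regime": regime_list[i],
                "seed": scene_seed,
                "view": ann.view,
                "planted_temps": ann.planted_temps,
                "rt": ann.rt,
            }
        )
    for split in ("train", "val", "test"):
        (out / split / "annotations.json").write_text(json.dumps(coco[split]))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def generate_temperature_table(
    n_cows: int,
    seed: int = 0,
    rt_mean: float = 38.7,
    rt_sd: float = 0.4,
    delta_aa: tuple[float, float] = (1.3, 0.15),
    delta_lu: tuple[float, float] = (2.3, 0.25),
    extra_sites: int = 0,
) -> pd.DataFrame:
    """Per-cow RT/LU/AA table with the planted RT > AA > LU gradient.

    ``extra_sites`` adds progressively weaker RT-correlated columns
    (site_1, site_2, ...) for exercising ROI selection.
    """
    if n_cows < 3:
        raise ValueError("need at least 3 cows")
    rng = np.random.default_rng(seed)
    rt = rt_mean + rt_sd * rng.standard_normal(n_cows)
    aa = rt - rng.normal(*delta_aa, size=n_cows)
    lu = rt - rng.normal(*delta_lu, size=n_cows)
    data = {
        "cow_id": [f"Cow {i + 1}" for i in range(n_cows)],
        "RT": np.round(rt, 1),
        "LU": np.round(lu, 1),
        "AA": np.round(aa, 1),
    }
    for s in range(extra_sites):
        strength = 0.5 / (s + 1)
        col = 30.0 + strength * (rt - rt_mean) + rng.normal(0, 0.8, size=n_cows)
        data[f"site_{s + 1}"] = np.round(col, 1)
    return pd.DataFrame(data)
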