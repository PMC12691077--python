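"""ROI temperature extraction and site-selection statistics.

Radiometric frames are 2-D float arrays of surface temperature in degC,
co-registered with the RGB frame. Temperatures inside a detection box are
summarised as TMax/TMin/Tavg; TMax is the temperature characteristic used
downstream because the animal is warmer than every background surface.

Site selection ranks body-surface sites by their Spearman rank correlation
with rectal temperature (RT) across animals; the lower udder (LU) and the
perianal area (AA) are the canonical picks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .training_strategy import Box

__all__ = [
    "INSTRUMENT_RANGE_C",
    "RoiTemperatures",
    "TempErrorStats",
    "extract_roi_temperatures",
    "temperature_errors",
    "spearman_matrix",
    "select_rois",
    "load_example_temperature_table",
]

#: Radiometric range of the thermal camera emulated here, degC.
INSTRUMENT_RANGE_C = (-20.0, 250.0)


@dataclass(frozen=True)
class RoiTemperatures:
    t_max: float
    t_min: float
    t_avg: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("ROI must contain at least one pixel")
        tol = 1e-9 * max(1.0, abs(self.t_max))  # mean can drift by an ulp
        if not self.t_min - tol <= self.t_avg <= self.t_max + tol:
            raise ValueError("expected t_min <= t_avg <= t_max")


@dataclass(frozen=True)
class TempErrorStats:
    """Absolute-error summary across animals; signed mean kept as context."""

    max_error: float
    min_error: float
    mean_error: float
    signed_mean_error: float = 0.0


def extract_roi_temperatures(thermal: np.ndarray, box: Box) -> RoiTemperatures:
    """Summarise temperatures of pixels whose centres fall inside ``box``.

    Pixel (row i, col j) has centre (j + 0.5, i + 0.5); membership uses
    half-open intervals [x1, x2) x [y1, y2).
    """
    thermal = np.asarray(thermal, dtype=float)
    if thermal.ndim != 2:
        raise ValueError("thermal map must be 2-D")
    h, w = thermal.shape
    j0 = max(0, int(math.ceil(box.x1 - 0.5)))
    j1 = min(w, int(math.ceil(box.x2 - 0.5)))
    i0 = max(0, int(math.ceil(box.y1 - 0.5)))
    i1 = min(h, int(math.ceil(box.y2 - 0.5)))
    if i1 <= i0 or j1 <= j0:
        raise ValueError("box does not cover any pixel centre")
    patch = thermal[i0:i1, j0:j1]
    return RoiTemperatures(
        t_max=float(patch.max()),
        t_min=float(patch.min()),
        t_avg=float(patch.mean()),
        n_pixels=patch.size,
    )


def temperature_errors(extracted, reference) -> TempErrorStats:
    """Max/min/mean absolute error between extracted and reference degC."""
    ext = np.asarray(extracted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if ext.shape != ref.shape or ext.ndim != 1 or ext.size == 0:
        raise ValueError("extracted and reference must be equal-length 1-D, n >= 1")
    signed = ext - ref
    err = np.abs(signed)
    return TempErrorStats(
        max_error=float(err.max()),
        min_error=float(err.min()),
        mean_error=float(err.mean()),
        signed_mean_error=float(signed.mean()),
    )


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho between temperature-site columns.

    ``table`` holds one row per animal and one numeric column per site
    (average-rank tie handling; non-numeric columns such as an ID are
    ignored). Constant columns give NaN for their pairs.
    """
    num = table.select_dtypes("number")
    if num.isna().any().any():
        raise ValueError("temperature table has missing cells")
    if len(num) < 3:
        raise ValueError("need at least 3 animals for a rank correlation")
    sites = list(num.columns)
    n = len(sites)
    rho = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            x, y = num.iloc[:, a], num.iloc[:, b]
            if x.nunique() < 2 or y.nunique() < 2:
                r = np.nan
            else:
                r = stats.spearmanr(x, y).statistic
            rho[a, b] = rho[b, a] = r
    return pd.DataFrame(rho, index=sites, columns=sites)


def select_rois(matrix: pd.DataFrame, target: str = "RT", k: int = 2) -> list[str]:
    """The ``k`` non-target sites most rank-correlated with ``target``.

    Ties are broken alphabetically.
    """
    if target not in matrix.columns:
        raise KeyError(f"target site {target!r} not in matrix")
    others = [s for s in matrix.columns if s != target]
    if k > len(others):
        raise ValueError(f"k={k} exceeds the {len(others)} available sites")
    ranked = sorted(others, key=lambda s: (-matrix.loc[target, s], s))
    return ranked[:k]


def load_example_temperature_table() -> pd.DataFrame:
    """Bundled example RT/LU/AA table for ten lactating Holstein cows."""
    with resources.files("thermoroi.data").joinpath("cow_temperatures.csv").open() as fh:
        return pd.read_csv(fh)
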