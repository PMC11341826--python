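"""Vegetation cooling efficiency by moving-window regression.

Cooling efficiency (CE) is the magnitude of land-surface-temperature
reduction per 1% increase in greenspace coverage. Within a small
moving window every pixel is assumed to share the same climate
background, so the local LST-vs-greenspace slope isolates the
vegetation effect: per center pixel we regress LST (degC) on
greenspace expressed in percent (0-100) over the window by ordinary
least squares and report CE = -slope, so positive CE means cooling.

Windows with too few valid pixels or with (nearly) constant greenspace
have an undefined slope and are masked, not raised. The default window
is 5x5 pixels; a sensitivity helper summarises CE across window sizes
(5-13), where locally linear coupling makes the estimate almost
window-invariant.

All window sums are computed with uniform filters, so the estimator is
vectorised over the whole raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .compositing import TemporalGrid
from .cube import GreenspaceCube

__all__ = ["CEMap", "match_lst_to_cube", "cooling_efficiency", "window_sensitivity"]


@dataclass
class CEMap:
    """Per-pixel cooling efficiency (degC per % greenspace) and fit."""

    ce: np.ndarray
    r2: np.ndarray
    n_used: np.ndarray
    window_size: int

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.ce)


def match_lst_to_cube(
    lst_doys, cube: GreenspaceCube | TemporalGrid | None = None
) -> list[tuple[int, int]]:
    """Pair each LST acquisition DOY with the nearest 10-day cube slot.

    Nearness is to the interval midpoint; ties take the earlier slot.
    Returns (lst_doy, slot_index) pairs with 1-based slots.
    """
    grid = cube if isinstance(cube, TemporalGrid) else TemporalGrid()
    doys = np.atleast_1d(np.asarray(lst_doys))
    if np.any((doys < 1) | (doys > 366)):
        raise ValueError("LST doys must lie in [1, 366]")
    mids = grid.midpoints
    out = []
    for d in doys:
        dist = np.abs(mids - d)
        slot = int(np.argmin(dist)) + 1  # argmin takes first on ties
        out.append((int(d), slot))
    return out


def _window_sums(arr: np.ndarray, window: int) -> np.ndarray:
    return uniform_filter(arr, size=window, mode="constant", cval=0.0) * window**2


def cooling_efficiency(
    lst: np.ndarray,
    green: np.ndarray,
    window: int = 5,
    min_valid: int = 10,
    min_green_sd: float = 0.05,
) -> CEMap:
    """Moving-window OLS of LST on greenspace percent; CE = -slope.

    Parameters
    ----------
    lst : (H, W) land surface temperature, degC; NaN = invalid.
    green : (H, W) greenspace coverage in [0, 1]; regressed in percent.
    window : odd window edge length in pixels.
    min_valid : minimum valid pixels per window.
    min_green_sd : minimum coverage standard deviation (fraction
        units) per window; below it the slope is undefined and masked.
    """
    lst = np.asarray(lst, dtype=float)
    green = np.asarray(green, dtype=float)
    if lst.shape != green.shape:
        raise ValueError("lst and green rasters must be co-registered")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")

    ok = np.isfinite(lst) & np.isfinite(green)
    x = np.where(ok, 100.0 * green, 0.0)
    y = np.where(ok, lst, 0.0)

    n = np.rint(_window_sums(ok.astype(float), window))
    sx = _window_sums(x, window)
    sy = _window_sums(y, window)
    sxx = _window_sums(x * x, window)
    sxy = _window_sums(x * y, window)
    syy = _window_sums(y * y, window)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov_xy = n * sxy - sx * sy
        var_x = n * sxx - sx * sx
        var_y = n * syy - sy * sy
        slope = cov_xy / var_x
        r2 = np.where(var_y > 0, cov_xy**2 / (var_x * var_y), np.nan)
        # sd of coverage (fraction units): var_x is in percent^2, x n^2
        sd_green = np.sqrt(np.maximum(var_x, 0.0)) / np.maximum(n, 1) / 100.0

    bad = (n < max(min_valid, 2)) | (sd_green < min_green_sd) | ~np.isfinite(slope)
    ce = np.where(bad, np.nan, -slope)
    r2 = np.where(bad, np.nan, r2)
    return CEMap(ce=ce, r2=r2, n_used=n.astype(int), window_size=window)


def window_sensitivity(
    lst: np.ndarray,
    green: np.ndarray,
    windows=(5, 7, 9, 11, 13),
    min_valid_frac: float = 0.4,
    min_green_sd: float = 0.05,
) -> pd.DataFrame:
    """Summarise CE across window sizes (mean, median, valid fraction).

    ``min_valid`` scales with the window area so the masking criterion
    stays comparable across sizes.
    """
    rows = []
    for w in windows:
        if w < 3 or w % 2 == 0:
            raise ValueError("window sizes must be odd integers >= 3")
        cem = cooling_efficiency(
            lst,
            green,
            window=w,
            min_valid=max(2, int(min_valid_frac * w * w)),
            min_green_sd=min_green_sd,
        )
        v = cem.ce[np.isfinite(cem.ce)]
        rows.append(
            {
                "window": w,
                "mean_ce": v.mean() if v.size else np.nan,
                "median_ce": np.median(v) if v.size else np.nan,
                "valid_fraction": v.size / cem.ce.size,
            }
        )
    return pd.DataFrame(rows)
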