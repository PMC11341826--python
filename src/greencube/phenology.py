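"""Per-pixel reconstruction of the 36-slot annual NDVI trajectory.

The reconstruction chain is order-fixed:

1. linear gap-filling of cloud-contaminated observations on the
   irregular DOY axis (nearest valid neighbours; leading/trailing gaps
   take the nearest valid value);
2. compositing into the 36 ten-day slots by within-window averaging
   (slots with no observation are then filled linearly on the
   slot-midpoint axis so the output is always complete);
3. RMMEH compound smoothing — each interior slot is replaced by the
   maximum of its own value, the 3-point running median, and the mean
   of its two neighbours. Because cloud contamination biases NDVI
   downward, this max-of-estimates rule acts as an upper envelope:
   output >= input pointwise, single downward spikes are lifted to the
   neighbour level, and clean peaks are preserved.

The annual maximum NDVI_max and its slot index are taken from the
smoothed series, so the greenspace-cube ratio NDVI_t / NDVI_max never
exceeds one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compositing import N_INTERVALS, TemporalGrid, composite_10day

__all__ = [
    "NdviPhenology",
    "gap_fill_linear",
    "rmmeh_smooth",
    "extract_ndvi_max",
    "build_ndvi_phenology",
]


@dataclass
class NdviPhenology:
    """36-slot smoothed NDVI series with annual maximum per pixel.

    ``slots`` is (36, H, W); ``peak_slot`` is 1-based (first slot wins
    ties); ``nodata`` marks pixels with no valid observation at all;
    ``empty_flags`` records which slots were empty before filling.
    """

    slots: np.ndarray
    ndvi_max: np.ndarray
    peak_slot: np.ndarray
    nodata: np.ndarray
    empty_flags: np.ndarray


def gap_fill_linear(
    times: np.ndarray, values: np.ndarray, valid: np.ndarray | None = None
) -> np.ndarray:
    """Linearly interpolate gaps in time-stamped series.

    ``values`` is (T,) or (T, ...) with NaN (or ``valid`` False)
    marking gaps. Interior gaps are linearly interpolated between the
    nearest valid neighbours in time; leading/trailing gaps are filled
    with the nearest valid value. Series with no valid value at all
    come back all-NaN (no-data), not an exception.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if valid is not None:
        ok = ok & np.asarray(valid, dtype=bool)
    if values.ndim == 1:
        if not ok.any():
            return np.full_like(values, np.nan)
        if ok.all():
            return values.copy()
        return np.interp(times, times[ok], values[ok])

    flat = values.reshape(values.shape[0], -1)
    okf = ok.reshape(ok.shape[0], -1)
    out = flat.copy()
    needs = ~okf.all(axis=0)
    for j in np.nonzero(needs)[0]:
        col_ok = okf[:, j]
        if not col_ok.any():
            out[:, j] = np.nan
        else:
            out[:, j] = np.interp(times, times[col_ok], flat[col_ok, j])
    return out.reshape(values.shape)


def rmmeh_smooth(slots: np.ndarray, passes: int = 2) -> np.ndarray:
    """RMMEH compound smoother: running-median / neighbour-mean / value
    maximum, applied ``passes`` times.

    Per pass, interior slot t of the pass input v becomes
    ``max(v_t, median(v_{t-1}, v_t, v_{t+1}), (v_{t-1}+v_{t+1})/2)``;
    endpoints are copied unchanged. Series shorter than 3 are returned
    unchanged. The first axis is the time axis.
    """
    s = np.asarray(slots, dtype=float)
    if s.shape[0] < 3:
        return s.copy()
    out = s.copy()
    for _ in range(passes):
        prev, cur, nxt = out[:-2], out[1:-1], out[2:]
        med = np.median(np.stack([prev, cur, nxt]), axis=0)
        mean = (prev + nxt) / 2.0
        new = out.copy()
        new[1:-1] = np.maximum(cur, np.maximum(med, mean))
        out = new
    return out


def extract_ndvi_max(smoothed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Annual maximum and its 1-based slot (earliest slot on ties).

    All-NaN pixels yield NaN maximum and slot 0.
    """
    s = np.asarray(smoothed, dtype=float)
    nodata = ~np.isfinite(s).all(axis=0)
    key = np.where(np.isfinite(s), s, -np.inf)
    peak = np.argmax(key, axis=0) + 1
    vmax = np.max(key, axis=0)
    vmax = np.where(nodata, np.nan, vmax)
    peak = np.where(nodata, 0, peak)
    if s.ndim == 1:
        return float(vmax), int(peak)
    return vmax, peak


def build_ndvi_phenology(
    doys: np.ndarray,
    ndvi: np.ndarray,
    valid: np.ndarray | None = None,
    grid: TemporalGrid | None = None,
    passes: int = 2,
) -> NdviPhenology:
    """Full reconstruction: gap-fill, 10-day composite, RMMEH smooth.

    Parameters
    ----------
    doys : (T,) observation days of year.
    ndvi : (T, H, W) or (T,) cloud-masked NDVI observations (NaN =
        invalid).
    valid : optional explicit validity, same shape as ``ndvi``.
    """
    grid = grid or TemporalGrid()
    ndvi = np.asarray(ndvi, dtype=float)
    squeeze = ndvi.ndim == 1
    if squeeze:
        ndvi = ndvi[:, None, None]
        if valid is not None:
            valid = np.asarray(valid)[:, None, None]

    filled = gap_fill_linear(doys, ndvi, valid)
    slots, empty = composite_10day(doys, filled, grid=grid)
    # observations may still leave whole 10-day windows empty; fill them
    # on the slot-midpoint axis before smoothing
    slots = gap_fill_linear(grid.midpoints, slots)
    nodata = ~np.isfinite(slots).all(axis=0)
    smoothed = rmmeh_smooth(slots, passes=passes)
    ndvi_max, peak_slot = extract_ndvi_max(smoothed)
    if squeeze:
        return NdviPhenology(
            slots=smoothed[:, 0, 0],
            ndvi_max=float(ndvi_max[0, 0]) if np.ndim(ndvi_max) else ndvi_max,
            peak_slot=int(peak_slot[0, 0]) if np.ndim(peak_slot) else peak_slot,
            nodata=bool(nodata[0, 0]),
            empty_flags=empty[:, 0, 0],
        )
    return NdviPhenology(
        slots=smoothed,
        ndvi_max=ndvi_max,
        peak_slot=peak_slot,
        nodata=nodata,
        empty_flags=empty,
    )
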