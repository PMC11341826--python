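"""Greenest-pixel compositing and the 36-slot ten-day temporal grid.

The annual axis is discretised into 36 ten-day intervals: intervals
1..35 cover DOY ``10(k-1)+1 .. 10k`` and interval 36 absorbs DOY 351 to
the end of the year (a long final slot), so every year maps to exactly
36 layers. The annual greenest composite is a quality mosaic: for each
pixel, *all six* feature bands are taken jointly from the single valid
observation with maximal NDVI, so downstream unmixing always sees a
physically consistent signature from one acquisition date.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureImage

__all__ = ["TemporalGrid", "interval_index", "greenest_composite", "composite_10day"]

N_INTERVALS = 36


@dataclass(frozen=True)
class TemporalGrid:
    """Ten-day interval grid over one year (365 or 366 days)."""

    year_length: int = 365

    def __post_init__(self):
        if self.year_length not in (365, 366):
            raise ValueError(f"year_length must be 365 or 366, got {self.year_length}")

    @property
    def n_intervals(self) -> int:
        return N_INTERVALS

    @property
    def bounds(self) -> np.ndarray:
        """(36, 2) inclusive DOY bounds of each interval."""
        lo = 10 * np.arange(N_INTERVALS) + 1
        hi = 10 * np.arange(1, N_INTERVALS + 1)
        hi[-1] = self.year_length
        return np.column_stack([lo, hi])

    @property
    def midpoints(self) -> np.ndarray:
        """Interval midpoints in fractional DOY, used for temporal matching."""
        b = self.bounds
        return (b[:, 0] + b[:, 1]) / 2.0


def interval_index(doy, year_length: int = 365):
    """Ten-day interval (1-based, clamped to 36) containing each DOY.

    ``k = min(ceil(doy/10), 36)``; e.g. DOY 41-50 (early February) fall
    in interval 5. Accepts scalars or arrays.
    """
    d = np.asarray(doy)
    if np.any((d < 1) | (d > year_length)):
        raise ValueError(f"doy out of range [1, {year_length}]")
    k = np.minimum(-(-d // 10), N_INTERVALS)
    return int(k) if np.isscalar(doy) else k.astype(int)


def greenest_composite(features: list[FeatureImage]) -> FeatureImage:
    """Per-pixel quality mosaic keyed on the NDVI band.

    For each pixel, selects the valid observation with maximal NDVI and
    copies all six bands from it; ties go to the earliest observation.
    Pixels valid in no observation come out invalid.
    """
    if len(features) == 0:
        raise ValueError("greenest_composite requires at least one observation")
    ndvi = np.stack([f.ndvi for f in features])  # (T, H, W)
    valid = np.stack([f.valid for f in features])
    key = np.where(valid, ndvi, -np.inf)
    best = np.argmax(key, axis=0)  # argmax takes first on ties
    any_valid = valid.any(axis=0)

    bands = np.stack([f.bands for f in features])  # (T, 6, H, W)
    rows, cols = np.indices(best.shape)
    out = bands[best, :, rows, cols].transpose(2, 0, 1).astype(float)
    out[:, ~any_valid] = np.nan
    first = features[0]
    return FeatureImage(
        bands=out, valid=any_valid, transform=first.transform, crs=first.crs
    )


def composite_10day(
    doys: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray | None = None,
    grid: TemporalGrid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average time-stamped values into the 36 ten-day slots.

    Parameters
    ----------
    doys : (T,) observation days of year.
    values : (T, ...) values; trailing dims are spatial.
    valid : optional (T, ...) boolean; NaNs are always treated invalid.

    Returns
    -------
    slots : (36, ...) per-slot arithmetic means (NaN where empty).
    empty : (36, ...) boolean flags for slots with no valid value.
    """
    grid = grid or TemporalGrid()
    doys = np.asarray(doys)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    k = interval_index(doys, grid.year_length) - 1  # (T,)

    tail = values.shape[1:]
    sums = np.zeros((N_INTERVALS, *tail))
    counts = np.zeros((N_INTERVALS, *tail))
    np.add.at(sums, k, np.where(ok, values, 0.0))
    np.add.at(counts, k, ok.astype(float))
    empty = counts == 0
    with np.errstate(invalid="ignore"):
        slots = np.where(empty, np.nan, sums / np.where(empty, 1.0, counts))
    return slots, empty
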