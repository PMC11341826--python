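"""Spectral indices, cloud masking and the six-band feature signature.

Every pixel signature used by compositing and unmixing is the six-band
vector (blue, green, red, NIR, NDVI, NDWI): the four 10-m surface
reflectance bands plus the two normalized-difference indices. NDWI uses
the McFeeters (green vs NIR) form, appropriate for open-water
detection. Division-by-zero pixels are marked invalid rather than
zeroed so that compositing never ranks on a fabricated index value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .raster import DEFAULT_TRANSFORM, Affine

__all__ = [
    "BAND_ORDER",
    "ReflectanceSeries",
    "FeatureImage",
    "compute_ndvi",
    "compute_ndwi",
    "apply_cloud_mask",
    "build_feature_stack",
]

#: band order contract for FeatureImage
BAND_ORDER = ("blue", "green", "red", "nir", "ndvi", "ndwi")


@dataclass
class ReflectanceSeries:
    """Time-stamped 4-band reflectance stack with cloud information.

    ``reflectance`` has shape (T, 4, H, W) in band order blue, green,
    red, NIR. ``cloud`` is either a per-observation cloud *probability*
    raster in percent (float, 0-100) or a boolean cloud mask, shape
    (T, H, W). ``valid`` (T, H, W) marks usable pixels; it is None
    until :func:`apply_cloud_mask` runs.
    """

    doys: np.ndarray
    reflectance: np.ndarray
    cloud: np.ndarray
    transform: Affine = DEFAULT_TRANSFORM
    crs: str = "EPSG:32614"
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.doys = np.asarray(self.doys)
        if self.reflectance.ndim != 4 or self.reflectance.shape[1] != 4:
            raise ValueError("reflectance must have shape (T, 4, rows, cols)")
        if self.cloud.shape != (len(self.doys), *self.reflectance.shape[2:]):
            raise ValueError("cloud raster not co-registered with reflectance")
        if np.any(np.diff(self.doys) < 0):
            raise ValueError("doys must be nondecreasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape[2:]

    def __len__(self) -> int:
        return len(self.doys)


@dataclass
class FeatureImage:
    """Six-band (B, G, R, NIR, NDVI, NDWI) signature image S_i."""

    bands: np.ndarray  # (6, H, W)
    valid: np.ndarray  # (H, W) bool
    transform: Affine = DEFAULT_TRANSFORM
    crs: str = "EPSG:32614"
    doy: int | None = None
    band_names: Sequence[str] = field(default=BAND_ORDER)

    @property
    def ndvi(self) -> np.ndarray:
        return self.bands[4]

    @property
    def ndwi(self) -> np.ndarray:
        return self.bands[5]


def _nd_index(num_minus: np.ndarray, num_plus: np.ndarray) -> np.ndarray:
    if num_minus.shape != num_plus.shape:
        raise ValueError("input rasters must be co-registered (same shape)")
    a = np.asarray(num_minus, dtype=float)
    b = np.asarray(num_plus, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / denom
    out[denom == 0] = np.nan
    return out


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """NDVI = (NIR - red) / (NIR + red); zero-sum pixels become NaN."""
    return _nd_index(np.asarray(nir), np.asarray(red))


def compute_ndwi(green: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """NDWI (McFeeters) = (green - NIR) / (green + NIR)."""
    return _nd_index(np.asarray(green), np.asarray(nir))


def apply_cloud_mask(
    series: ReflectanceSeries, prob_threshold: float = 50.0
) -> ReflectanceSeries:
    """Invalidate pixels at/above a cloud-probability threshold (percent).

    Boolean cloud masks invalidate wherever True, regardless of the
    threshold. Reflectance values are never altered — only the validity
    mask changes. Masking is monotone: lowering the threshold never
    re-validates a pixel.
    """
    if not 0.0 <= prob_threshold <= 100.0:
        raise ValueError("prob_threshold must be in [0, 100]")
    if series.cloud.dtype == bool:
        cloudy = series.cloud.copy()
        if prob_threshold == 0.0:
            cloudy[:] = True
    else:
        cloudy = series.cloud >= prob_threshold
    valid = ~cloudy & np.isfinite(series.reflectance).all(axis=1)
    return ReflectanceSeries(
        doys=series.doys,
        reflectance=series.reflectance,
        cloud=series.cloud,
        transform=series.transform,
        crs=series.crs,
        valid=valid,
    )


def build_feature_stack(series: ReflectanceSeries) -> list[FeatureImage]:
    """Per observation, stack (B, G, R, NIR, NDVI, NDWI) with validity.

    The series should already be cloud-masked; if not, all finite
    pixels are taken valid. Pixels invalid in the input are invalid in
    all six bands; index NaNs (zero denominators) also invalidate.
    """
    if len(series) == 0:
        raise ValueError("cannot build features from an empty series")
    if series.valid is None:
        valid = np.isfinite(series.reflectance).all(axis=1)
    else:
        valid = series.valid
    out = []
    for t in range(len(series)):
        blue, green, red, nir = series.reflectance[t]
        ndvi = compute_ndvi(red, nir)
        ndwi = compute_ndwi(green, nir)
        bands = np.stack([blue, green, red, nir, ndvi, ndwi]).astype(float)
        v = valid[t] & np.isfinite(ndvi) & np.isfinite(ndwi)
        bands[:, ~v] = np.nan
        out.append(
            FeatureImage(
                bands=bands,
                valid=v,
                transform=series.transform,
                crs=series.crs,
                doy=int(series.doys[t]),
            )
        )
    return out
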