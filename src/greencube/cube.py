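"""The 36-layer annual greenspace data cube and its file format.

Greenspace coverage at slot t is the annual-maximum coverage scaled by
the NDVI seasonality ratio::

    G_t = G_max * NDVI_t / NDVI_max

with NDVI_t clamped below at 0 (shadow/water artifacts can push NDVI
negative) and the ratio clamped so G_t never exceeds G_max. Pixels
whose smoothed NDVI_max falls below a small floor (default 0.05 —
barren or water pixels for which the ratio is ill-defined) get a
constant G_t = G_max and are flagged aseasonal.

On disk a cube is a 36-band GeoTIFF of int16 with scale factor 0.001
(stored value = round(G / 0.001), half away from zero) and nodata code
-1, matching the deposited data-record convention; physical coverage
round-trips within half a quantum (0.0005).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phenology import NdviPhenology
from .raster import DEFAULT_TRANSFORM, Affine, Raster, read_raster, write_raster

__all__ = ["GreenspaceCube", "assemble_cube", "write_cube", "read_cube", "CubeFormatError"]

SCALE_FACTOR = 0.001
NODATA_INT = -1
N_LAYERS = 36


class CubeFormatError(ValueError):
    """Raised when a file does not follow the 36-band cube format."""


@dataclass
class GreenspaceCube:
    """Annual greenspace coverage, (36, H, W), values in [0, 1]."""

    layers: np.ndarray
    year: int = 2020
    transform: Affine = DEFAULT_TRANSFORM
    crs: str = "EPSG:32614"
    scale_factor: float = SCALE_FACTOR
    aseasonal: np.ndarray | None = None
    peak_slot: np.ndarray | None = None

    def __post_init__(self):
        if self.layers.ndim != 3 or self.layers.shape[0] != N_LAYERS:
            raise ValueError(f"cube must have {N_LAYERS} layers")

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.layers).all(axis=0)

    @property
    def gmax(self) -> np.ndarray:
        """Per-pixel maximum coverage over the 36 slots."""
        key = np.where(np.isfinite(self.layers), self.layers, -np.inf)
        out = key.max(axis=0)
        return np.where(np.isinf(out), np.nan, out)


def assemble_cube(
    gmax: np.ndarray,
    phen: NdviPhenology,
    eps_floor: float = 0.05,
    year: int = 2020,
    transform: Affine = DEFAULT_TRANSFORM,
) -> GreenspaceCube:
    """Combine annual-maximum coverage with the NDVI seasonality ratio.

    Per pixel and slot: ``G_t = G_max * clip(NDVI_t, 0, inf) /
    NDVI_max`` clamped to [0, G_max]. Pixels with NDVI_max below
    ``eps_floor`` are aseasonal: every slot is set to G_max.
    """
    gmax = np.asarray(gmax, dtype=float)
    if gmax.shape != phen.slots.shape[1:]:
        raise ValueError("gmax and phenology rasters must be co-registered")
    ndvi_t = np.clip(phen.slots, 0.0, None)
    ndvi_max = np.asarray(phen.ndvi_max, dtype=float)
    aseasonal = np.isfinite(ndvi_max) & (ndvi_max < eps_floor)
    safe_max = np.where(aseasonal | ~np.isfinite(ndvi_max), 1.0, ndvi_max)
    with np.errstate(invalid="ignore"):
        ratio = np.clip(ndvi_t / safe_max, 0.0, 1.0)
    layers = gmax * ratio
    layers = np.where(aseasonal, gmax, layers)
    invalid = ~np.isfinite(gmax) | phen.nodata
    layers[:, invalid] = np.nan
    return GreenspaceCube(
        layers=layers,
        year=year,
        transform=transform,
        aseasonal=aseasonal,
        peak_slot=phen.peak_slot,
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def write_cube(cube: GreenspaceCube, path: str | Path) -> Path:
    """Write the cube as a 36-band int16 GeoTIFF, scale factor 0.001."""
    q = _round_half_away(cube.layers / cube.scale_factor)
    q = np.where(np.isfinite(cube.layers), q, NODATA_INT).astype(np.int16)
    raster = Raster(
        data=q,
        transform=cube.transform,
        crs=cube.crs,
        nodata=NODATA_INT,
        meta={"scale_factor": cube.scale_factor, "year": cube.year, "n_layers": N_LAYERS},
    )
    return write_raster(path, raster, dtype=np.int16)


def read_cube(path: str | Path) -> GreenspaceCube:
    """Read a cube file; integers x scale factor give physical coverage."""
    raster = read_raster(path)
    data = raster.data if raster.data.ndim == 3 else raster.data[None]
    if data.shape[0] != N_LAYERS:
        raise CubeFormatError(
            f"expected {N_LAYERS} bands in a greenspace cube, found {data.shape[0]}"
        )
    scale = float(raster.meta.get("scale_factor", SCALE_FACTOR))
    nodata = raster.nodata if raster.nodata is not None else NODATA_INT
    layers = data.astype(float) * scale
    layers[data == nodata] = np.nan
    return GreenspaceCube(
        layers=layers,
        year=int(raster.meta.get("year", 0)),
        transform=raster.transform,
        crs=raster.crs,
        scale_factor=scale,
    )
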