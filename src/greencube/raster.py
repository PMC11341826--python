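"""Minimal georeferenced raster container and GeoTIFF-style I/O.

Rasters are numpy arrays (``(rows, cols)`` or ``(bands, rows, cols)``)
paired with a north-up affine transform and a CRS tag. Files are written
as multi-page TIFFs carrying the GeoTIFF ``ModelPixelScale`` and
``ModelTiepoint`` tags plus a JSON metadata block in the
``ImageDescription`` tag, so they open in GIS software with correct
geolocation and round-trip losslessly here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, NamedTuple

import numpy as np
import tifffile

__all__ = ["Affine", "Raster", "write_raster", "read_raster", "mask_with_polygon"]

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


class Affine(NamedTuple):
    """Row-major 2D affine transform mapping (col, row) -> (x, y).

    ``x = a*col + b*row + c``; ``y = d*col + e*row + f``. Only north-up
    (b = d = 0, e < 0) transforms are produced by this package.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def north_up(cls, origin_x: float, origin_y: float, pixel_size: float) -> "Affine":
        return cls(pixel_size, 0.0, origin_x, 0.0, -pixel_size, origin_y)

    @property
    def pixel_width(self) -> float:
        return abs(self.a)

    @property
    def pixel_height(self) -> float:
        return abs(self.e)

    def xy(self, row: np.ndarray, col: np.ndarray, offset: float = 0.5):
        """Coordinates of pixel (row, col); offset 0.5 gives pixel centers."""
        c = np.asarray(col) + offset
        r = np.asarray(row) + offset
        return self.a * c + self.b * r + self.c, self.d * c + self.e * r + self.f


#: default transform: 10-m pixels, arbitrary local origin
DEFAULT_TRANSFORM = Affine.north_up(500000.0, 4000000.0, 10.0)


@dataclass
class Raster:
    """A georeferenced array; invalid cells are NaN in float data."""

    data: np.ndarray
    transform: Affine = DEFAULT_TRANSFORM
    crs: str = "EPSG:32614"
    nodata: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    def copy_with(self, data: np.ndarray, **kw) -> "Raster":
        return replace(self, data=data, **kw)


def write_raster(path: str | Path, raster: Raster, dtype=None) -> Path:
    """Write a Raster as a (multi-page) TIFF with geolocation tags."""
    path = Path(path)
    data = raster.data if raster.data.ndim == 3 else raster.data[None]
    if dtype is not None:
        data = data.astype(dtype)
    t = raster.transform
    desc = json.dumps(
        {
            "transform": list(t),
            "crs": raster.crs,
            "nodata": raster.nodata,
            **raster.meta,
        }
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (t.pixel_width, t.pixel_height, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
    ]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=desc,
        extratags=extratags,
        metadata=None,
    )
    return path


def read_raster(path: str | Path) -> Raster:
    """Read a raster written by :func:`write_raster`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta: dict[str, Any] = {}
    transform, crs, nodata = DEFAULT_TRANSFORM, "EPSG:32614", None
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        if "transform" in meta:
            transform = Affine(*meta.pop("transform"))
        crs = meta.pop("crs", crs)
        nodata = meta.pop("nodata", nodata)
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    return Raster(data=data, transform=transform, crs=crs, nodata=nodata, meta=meta)


def mask_with_polygon(raster: Raster, geojson_path: str | Path) -> Raster:
    """Set pixels whose centers fall outside a GeoJSON polygon to NaN.

    Mirrors cropping city rasters to a built-up-area boundary polygon.
    Accepts a GeoJSON file holding a Feature, FeatureCollection or bare
    geometry; multiple features are unioned.
    """
    import shapely
    from shapely.geometry import shape as shp_shape

    with open(geojson_path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shp_shape(f["geometry"]) for f in gj["features"]]
        geom = shapely.union_all(geoms)
    elif gj.get("type") == "Feature":
        geom = shp_shape(gj["geometry"])
    else:
        geom = shp_shape(gj)

    rows, cols = raster.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x, y = raster.transform.xy(rr, cc)
    inside = shapely.contains_xy(geom, x.ravel(), y.ravel()).reshape(rows, cols)
    data = raster.data.astype(float, copy=True)
    data[..., ~inside] = np.nan
    return raster.copy_with(data)
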