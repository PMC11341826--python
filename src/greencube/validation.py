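"""Block-level agreement protocol between greenspace rasters.

Cross-resolution comparison (e.g. a 10-m product against a 3-m
reference) is done by aggregating both rasters to a shared grid of
square blocks (default 200 m x 200 m) aligned to the raster transform,
then scoring block means with r-squared (squared Pearson correlation)
and RMSE. Aggregating both sides to blocks avoids pixel-to-pixel
resampling artifacts between products of different native resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster

__all__ = ["BlockMeans", "block_aggregate", "agreement_metrics"]


@dataclass
class BlockMeans:
    """Per-block means keyed by (block_row, block_col)."""

    means: dict[tuple[int, int], float]
    counts: dict[tuple[int, int], int]
    block_size_m: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"block_row": i, "block_col": j, "mean": m, "n_valid": self.counts[(i, j)]}
            for (i, j), m in sorted(self.means.items())
        ]
        return pd.DataFrame(rows)


def block_aggregate(
    raster: Raster,
    block_size_m: float = 200.0,
    min_valid_frac: float = 0.5,
) -> BlockMeans:
    """Mean coverage per block of ``block_size_m`` meters on a side.

    Blocks are aligned to the raster origin. Means are over valid
    (finite) pixels only; blocks whose valid-pixel fraction is below
    ``min_valid_frac`` are dropped.
    """
    if raster.transform is None:
        raise ValueError("block aggregation requires a georeferenced raster")
    data = np.asarray(raster.data, dtype=float)
    if data.ndim != 2:
        raise ValueError("block_aggregate expects a single-band raster")
    px_w = raster.transform.pixel_width
    px_h = raster.transform.pixel_height
    if px_w <= 0 or px_h <= 0:
        raise ValueError("raster pixel size must be positive meters")

    rows, cols = data.shape
    bi = np.floor(np.arange(rows) * px_h / block_size_m).astype(int)
    bj = np.floor(np.arange(cols) * px_w / block_size_m).astype(int)
    nbi, nbj = bi[-1] + 1, bj[-1] + 1

    ok = np.isfinite(data)
    sums = np.zeros((nbi, nbj))
    nval = np.zeros((nbi, nbj))
    ntot = np.zeros((nbi, nbj))
    np.add.at(sums, (bi[:, None], bj[None, :]), np.where(ok, data, 0.0))
    np.add.at(nval, (bi[:, None], bj[None, :]), ok.astype(float))
    np.add.at(ntot, (bi[:, None], bj[None, :]), 1.0)

    means: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for i in range(nbi):
        for j in range(nbj):
            if ntot[i, j] == 0 or nval[i, j] == 0:
                continue
            if nval[i, j] / ntot[i, j] < min_valid_frac:
                continue
            means[(i, j)] = sums[i, j] / nval[i, j]
            counts[(i, j)] = int(nval[i, j])
    return BlockMeans(means=means, counts=counts, block_size_m=block_size_m)


def agreement_metrics(
    a: BlockMeans | dict, b: BlockMeans | dict
) -> tuple[float, float, int]:
    """r-squared, RMSE and pair count between two sets of block means.

    Pairs are the intersection of block keys. r-squared is the squared
    Pearson correlation (invariant to affine rescaling of either
    side); RMSE is the root mean squared difference (not invariant).
    Fewer than 3 pairs, or zero variance on either side, flags the
    metrics undefined (NaN) rather than raising.
    """
    da = a.means if isinstance(a, BlockMeans) else dict(a)
    db = b.means if isinstance(b, BlockMeans) else dict(b)
    keys = sorted(set(da) & set(db))
    n = len(keys)
    if n == 0:
        return np.nan, np.nan, 0
    va = np.array([da[k] for k in keys], dtype=float)
    vb = np.array([db[k] for k in keys], dtype=float)
    rmse = float(np.sqrt(np.mean((va - vb) ** 2)))
    if n < 3 or va.std() == 0 or vb.std() == 0:
        return np.nan, rmse if n >= 1 else np.nan, n
    r = np.corrcoef(va, vb)[0, 1]
    return float(r**2), rmse, n
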