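"""Independent oracles shared by unit and acceptance tests."""

import numpy as np


def simplex_grid(step: float = 1e-3) -> np.ndarray:
    """All 3-vectors on the unit simplex with resolution ``step``."""
    f1 = np.arange(0.0, 1.0 + step / 2, step)
    g1, g2 = np.meshgrid(f1, f1, indexing="ij")
    ok = g1 + g2 <= 1.0 + 1e-12
    return np.column_stack([g1[ok], g2[ok], 1.0 - g1[ok] - g2[ok]])


def grid_search_unmix(signature: np.ndarray, C: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Brute-force constrained unmixing: exhaustive scan of the simplex grid."""
    pred = grid @ C
    i = int(np.argmin(((pred - signature) ** 2).sum(axis=1)))
    return grid[i]


def count_local_maxima(values: np.ndarray) -> int:
    """Strict interior local maxima by brute-force forward-difference scan."""
    d = np.diff(values)
    sign = np.sign(d)
    # drop zero segments (plateaus count once via surrounding signs)
    nz = sign[sign != 0]
    return int(np.sum((nz[:-1] > 0) & (nz[1:] < 0)))
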