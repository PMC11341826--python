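"""Greenspace-cube assembly identities and file-format round trips."""

import numpy as np
import pytest

import greencube as gc
from greencube.cube import CubeFormatError, GreenspaceCube
from greencube.phenology import NdviPhenology


def _phen(slots):
    slots = np.asarray(slots, float)
    ndvi_max, peak = gc.extract_ndvi_max(slots)
    return NdviPhenology(
        slots=slots, ndvi_max=ndvi_max, peak_slot=peak,
        nodata=~np.isfinite(slots).all(axis=0),
        empty_flags=np.zeros_like(slots, dtype=bool),
    )


class TestAssemble:
    def test_identity_at_peak_slot(self):
        slots = np.full((36, 1, 1), 0.3)
        slots[19] = 0.6
        cube = gc.assemble_cube(np.array([[0.8]]), _phen(slots))
        assert cube.layers[19, 0, 0] == pytest.approx(0.8)

    def test_zero_ndvi_gives_zero_coverage(self):
        slots = np.full((36, 1, 1), 0.5)
        slots[0] = 0.0
        cube = gc.assemble_cube(np.array([[0.7]]), _phen(slots))
        assert cube.layers[0, 0, 0] == pytest.approx(0.0)

    def test_worked_ratio_example(self):
        # G_max 0.8, NDVI_t 0.3, NDVI_max 0.6 -> coverage 0.4
        slots = np.full((36, 1, 1), 0.3)
        slots[25] = 0.6
        cube = gc.assemble_cube(np.array([[0.8]]), _phen(slots))
        assert cube.layers[0, 0, 0] == pytest.approx(0.4)

    def test_ratio_never_exceeds_one(self, noisy_result):
        _, res = noisy_result
        cube = res.cube
        ok = ~cube.nodata_mask
        assert np.nanmax(cube.layers[:, ok]) <= 1.0 + 1e-12
        gmax_layer = res.fractions.gmax
        assert np.all(cube.layers[:, ok] <= gmax_layer[ok] + 1e-12)

    def test_peak_layer_equals_gmax(self, noisy_result):
        _, res = noisy_result
        cube = res.cube
        ok = ~cube.nodata_mask
        assert np.abs(cube.gmax[ok] - res.fractions.gmax[ok]).max() < 1e-9

    def test_negative_ndvi_clamped(self):
        slots = np.full((36, 1, 1), -0.2)
        slots[10] = 0.5
        cube = gc.assemble_cube(np.array([[0.6]]), _phen(slots))
        assert cube.layers[0, 0, 0] == pytest.approx(0.0)

    def test_low_ndvi_max_pixel_is_aseasonal(self):
        slots = np.full((36, 1, 1), 0.01)
        cube = gc.assemble_cube(np.array([[0.02]]), _phen(slots), eps_floor=0.05)
        assert cube.aseasonal[0, 0]
        assert np.allclose(cube.layers[:, 0, 0], 0.02)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            gc.assemble_cube(np.zeros((2, 3)), _phen(np.zeros((36, 1, 1))))


class TestCubeFormat:
    def _cube(self):
        rng = np.random.default_rng(8)
        layers = rng.uniform(0, 1, (36, 5, 4))
        layers[:, 0, 0] = np.nan
        return GreenspaceCube(layers=layers, year=2020)

    def test_writer_emits_36_band_file_with_scale(self, tmp_path):
        path = tmp_path / "cube.tif"
        gc.write_cube(self._cube(), path)
        raster = gc.read_raster(path)
        assert raster.data.shape[0] == 36
        assert raster.meta["scale_factor"] == pytest.approx(0.001)
        assert raster.data.dtype == np.int16

    def test_round_trip_within_quantization(self, tmp_path):
        cube = self._cube()
        path = tmp_path / "cube.tif"
        gc.write_cube(cube, path)
        back = gc.read_cube(path)
        ok = np.isfinite(cube.layers)
        assert np.abs(back.layers[ok] - cube.layers[ok]).max() <= 0.0005
        assert back.scale_factor == pytest.approx(0.001)

    @pytest.mark.parametrize("g,stored", [(1.0, 1000), (0.0, 0), (0.4005, 401)])
    def test_integer_encoding(self, tmp_path, g, stored):
        cube = GreenspaceCube(layers=np.full((36, 1, 1), g))
        path = tmp_path / "c.tif"
        gc.write_cube(cube, path)
        raster = gc.read_raster(path)
        assert raster.data[0, 0, 0] == stored

    def test_nodata_cells_flagged_invalid_not_zero(self, tmp_path):
        cube = self._cube()
        path = tmp_path / "cube.tif"
        gc.write_cube(cube, path)
        back = gc.read_cube(path)
        assert np.isnan(back.layers[:, 0, 0]).all()
        assert back.nodata_mask[0, 0]

    def test_wrong_band_count_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.tif"
        gc.write_raster(path, gc.Raster(np.zeros((12, 3, 3), dtype=np.int16)))
        with pytest.raises(CubeFormatError, match="36"):
            gc.read_cube(path)


def test_full_noise_free_cube_matches_truth(clean_result):
    """Cube = truth fractions x truth seasonal NDVI ratio, RMSE < 0.02.

    The expected cube is rebuilt from generator truth by an
    independent re-implementation of the declared processing contract:
    per-pixel NDVI as the linear mixture of endmember indices at the
    observed dates, brute-force ten-day slot averaging, and the
    3-point max(value, median, neighbour-mean) envelope rule applied
    twice (the cube's seasonal term is the smoothed series by
    definition).
    """
    truth, res = clean_result
    doys = truth.doys
    em_idx = np.stack(
        [truth.endmembers.feature_signatures(int(d))[:, 4] for d in doys]
    )
    ndvi_obs = np.einsum("tk,khw->thw", em_idx, truth.fractions)

    # brute-force slot means
    slots = np.full((36, *ndvi_obs.shape[1:]), np.nan)
    for k in range(1, 37):
        lo, hi = 10 * (k - 1) + 1, (10 * k if k < 36 else 365)
        sel = (doys >= lo) & (doys <= hi)
        if sel.any():
            slots[k - 1] = ndvi_obs[sel].mean(axis=0)
    assert np.isfinite(slots).all()  # 5-day revisit fills every slot

    # hand-rolled envelope smoother, two passes
    for _ in range(2):
        new = slots.copy()
        for t in range(1, 35):
            trip = np.stack([slots[t - 1], slots[t], slots[t + 1]])
            new[t] = np.maximum(
                slots[t],
                np.maximum(np.median(trip, axis=0), (slots[t - 1] + slots[t + 1]) / 2),
            )
        slots = new

    ndvi_true = np.clip(slots, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.clip(ndvi_true / ndvi_true.max(axis=0), 0.0, 1.0)
    expected = truth.gmax_truth[None] * np.nan_to_num(ratio, nan=1.0)
    seasonal = ~res.cube.aseasonal
    rmse = np.sqrt(np.nanmean((res.cube.layers[:, seasonal] - expected[:, seasonal]) ** 2))
    assert rmse < 0.02
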