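"""Ground-truthed synthetic multispectral scenes for parameter recovery.

Every downstream stage (compositing, unmixing, phenology, cube,
cooling) is tested by recovering known truth from scenes built here:

* per-pixel convex mixtures of three endmember spectra (vegetation,
  bare surface, water) drawn patchwise on the unit simplex;
* a seasonal vegetation reflectance trajectory driven by a smooth
  unimodal or bimodal NDVI phenology curve (sum of logistic pulses);
* random patchy cloud occlusion and additive Gaussian sensor noise;
* a land-surface-temperature field linearly coupled to greenspace
  coverage with a known, spatially varying cooling slope.

A deliberate construction choice: the three endmember spectra share
identical red+NIR and green+NIR band sums at every date. Under that
constraint the NDVI and NDWI of any convex reflectance mixture are
*exactly* linear in the mixture fractions, so the six-band linear
mixing model holds without approximation and noise-free unmixing can
be required to recover truth to machine precision. The cost is some
spectral realism (the water endmember carries a high green band);
tests on these scenes therefore probe the pipeline's algebra and
plumbing, not its robustness to real spectra.

Randomness: each generator function takes an explicit integer seed and
consumes a single ``numpy`` Generator in a fixed, documented order, so
scenes are bit-reproducible. :func:`default_scene` derives sub-seeds by
fixed small offsets from the scene seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .features import ReflectanceSeries, compute_ndvi, compute_ndwi
from .raster import DEFAULT_TRANSFORM, Affine, Raster, read_raster, write_raster

__all__ = [
    "PhenologyParams",
    "SeasonalEndmembers",
    "SceneTruth",
    "vegetation_ndvi_curve",
    "make_fraction_maps",
    "make_cloud_schedule",
    "make_ce_field",
    "render_reflectance",
    "render_lst",
    "default_scene",
    "write_scene",
    "read_scene",
]


@dataclass(frozen=True)
class PhenologyParams:
    """Parameters of the seasonal vegetation NDVI trajectory.

    The curve is a baseline plus one (unimodal) or two (bimodal)
    logistic rise/fall pulses of the given amplitude, emulating e.g.
    tree-crown phenology with a single summer peak or grassland
    phenology with spring and autumn peaks.

    Parameters
    ----------
    baseline_ndvi : dormant-season NDVI, in [0, 1).
    amplitude : peak height above baseline; baseline + amplitude <= 1.
    peak_doys : one or two strictly increasing peak days of year.
    rise_rate, fall_rate : logistic steepness, 1/day.
    mode : "unimodal" or "bimodal".
    pulse_half_width : half-duration of each pulse plateau, days.
    """

    baseline_ndvi: float = 0.30
    amplitude: float = 0.62
    peak_doys: tuple[int, ...] = (200,)
    rise_rate: float = 0.15
    fall_rate: float = 0.15
    mode: str = "unimodal"
    pulse_half_width: float = 40.0

    def __post_init__(self):
        if not 0.0 <= self.baseline_ndvi < 1.0:
            raise ValueError("baseline_ndvi must be in [0, 1)")
        if self.amplitude < 0 or self.baseline_ndvi + self.amplitude > 1.0:
            raise ValueError("baseline_ndvi + amplitude must not exceed 1")
        if self.mode not in ("unimodal", "bimodal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        n_expected = 1 if self.mode == "unimodal" else 2
        if len(self.peak_doys) != n_expected:
            raise ValueError(f"{self.mode} phenology requires {n_expected} peak(s)")
        if any(not 1 <= p <= 366 for p in self.peak_doys):
            raise ValueError("peak_doys must lie in [1, 366]")
        if len(self.peak_doys) == 2 and self.peak_doys[1] <= self.peak_doys[0]:
            raise ValueError("peak_doys must be strictly increasing")
        if self.rise_rate <= 0 or self.fall_rate <= 0:
            raise ValueError("rates must be positive")


def vegetation_ndvi_curve(params: PhenologyParams, doy) -> np.ndarray | float:
    """Evaluate the vegetation NDVI phenology curve at one or more DOYs.

    Returns values in [baseline, baseline + amplitude]; the curve has
    exactly one local maximum per declared peak.
    """
    d = np.asarray(doy, dtype=float)
    if np.any((d < 1) | (d > 366)):
        raise ValueError("doy must lie in [1, 366]")
    total = np.zeros_like(d)
    hw = params.pulse_half_width
    for peak in params.peak_doys:
        up = 1.0 / (1.0 + np.exp(-params.rise_rate * (d - (peak - hw))))
        down = 1.0 / (1.0 + np.exp(-params.fall_rate * ((peak + hw) - d)))
        total += up * down
    val = params.baseline_ndvi + params.amplitude * np.minimum(total, 1.0)
    return float(val) if np.isscalar(doy) else val


@dataclass(frozen=True)
class SeasonalEndmembers:
    """Endmember reflectance spectra (vegetation, bare, water) vs DOY.

    Vegetation NIR and red co-vary so that the vegetation endmember's
    NDVI follows ``phenology`` exactly; bare and water spectra are
    static. All three endmembers share the band sums ``red + NIR =
    band_sum_rn`` and ``green + NIR = band_sum_gn`` (see module
    docstring for why).

    A consequence of the shared band sums is that every band except
    blue is an affine function of the endmember's NIR value, so the
    effective spectral space is the (blue, NIR) plane. The default
    values therefore spread the three endmembers widely in that plane
    (large band sums, strongly separated blue), keeping the linear
    unmixing problem well conditioned: the least-squares noise gain
    from reflectance noise to fraction error is ~1.5, versus >5 for a
    naive narrow-band choice.
    """

    phenology: PhenologyParams = field(default_factory=PhenologyParams)
    band_sum_rn: float = 0.80
    band_sum_gn: float = 0.85
    blue: tuple[float, float, float] = (0.03, 0.55, 0.06)  # veg, bare, water
    nir_bare: float = 0.42
    nir_water: float = 0.02

    names = ("vegetation", "bare", "water")

    def reflectance(self, doy: int) -> np.ndarray:
        """(3, 4) endmember reflectance (B, G, R, NIR) at one DOY."""
        n = vegetation_ndvi_curve(self.phenology, doy)
        nir_v = self.band_sum_rn * (1.0 + n) / 2.0
        rows = []
        for name, nir in zip(self.names, (nir_v, self.nir_bare, self.nir_water)):
            red = self.band_sum_rn - nir
            green = self.band_sum_gn - nir
            blue = self.blue[self.names.index(name)]
            rows.append([blue, green, red, nir])
        return np.array(rows)

    def feature_signatures(self, doy: int) -> np.ndarray:
        """(3, 6) endmember signatures (B, G, R, NIR, NDVI, NDWI)."""
        refl = self.reflectance(doy)
        ndvi = compute_ndvi(refl[:, 2], refl[:, 3])
        ndwi = compute_ndwi(refl[:, 1], refl[:, 3])
        return np.column_stack([refl, ndvi, ndwi])


@dataclass
class SceneTruth:
    """Everything needed to render a scene and to verify recovery.

    ``fractions`` is (3, H, W) vegetation/bare/water truth on the unit
    simplex; ``phenology`` applies scene-wide; ``cloud_schedule`` is a
    (T, H, W) boolean occlusion mask aligned with ``doys``; ``ce_truth``
    is the per-pixel cooling slope in degC per 1% greenspace.
    """

    fractions: np.ndarray
    phenology: PhenologyParams
    endmembers: SeasonalEndmembers
    doys: np.ndarray
    cloud_schedule: np.ndarray
    ce_truth: np.ndarray
    noise_sd: float = 0.01
    seed: int = 0
    transform: Affine = DEFAULT_TRANSFORM

    def __post_init__(self):
        f = self.fractions
        if f.ndim != 3 or f.shape[0] != 3:
            raise ValueError("fractions must have shape (3, rows, cols)")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if np.max(np.abs(f.sum(axis=0) - 1.0)) > 1e-12:
            raise ValueError("fractions must sum to 1 per pixel (within 1e-12)")
        if np.any(self.ce_truth < 0):
            raise ValueError("ce_truth must be nonnegative")
        if self.cloud_schedule.shape != (len(self.doys), *f.shape[1:]):
            raise ValueError("cloud_schedule not aligned with doys/fractions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fractions.shape[1:]

    @property
    def gmax_truth(self) -> np.ndarray:
        """True annual-maximum greenspace coverage (vegetation fraction)."""
        return self.fractions[0]


def make_fraction_maps(
    seed: int,
    shape: tuple[int, int],
    patch_scale: int,
    ensure_pure: bool = False,
) -> np.ndarray:
    """Patchwise-constant random fractions on the unit simplex.

    The grid is tiled into ``patch_scale`` x ``patch_scale`` patches,
    each assigned one flat-Dirichlet draw, giving spatially
    autocorrelated convex 3-vectors. With ``ensure_pure``, the first
    three patches are overwritten with the pure vegetation, bare and
    water vertices so endmember candidates always exist.
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("shape must be positive")
    if patch_scale < 1:
        raise ValueError("patch_scale must be >= 1")
    rng = np.random.default_rng(seed)
    pr = -(-rows // patch_scale)
    pc = -(-cols // patch_scale)
    patches = rng.dirichlet(np.ones(3), size=(pr, pc))  # (pr, pc, 3)
    if ensure_pure:
        flat = patches.reshape(-1, 3)
        for k in range(min(3, flat.shape[0])):
            flat[k] = np.eye(3)[k]
        patches = flat.reshape(pr, pc, 3)
    patches /= patches.sum(axis=-1, keepdims=True)
    full = np.repeat(np.repeat(patches, patch_scale, axis=0), patch_scale, axis=1)
    return np.moveaxis(full[:rows, :cols], -1, 0)


def make_cloud_schedule(
    seed: int,
    n_dates: int,
    shape: tuple[int, int],
    prob: float = 0.3,
    patch_scale: int = 8,
) -> np.ndarray:
    """Per-date Bernoulli cloud patches: (T, H, W) boolean, True = cloud."""
    rows, cols = shape
    rng = np.random.default_rng(seed)
    pr = -(-rows // patch_scale)
    pc = -(-cols // patch_scale)
    patchy = rng.random((n_dates, pr, pc)) < prob
    full = np.repeat(np.repeat(patchy, patch_scale, axis=1), patch_scale, axis=2)
    return full[:, :rows, :cols]


def make_ce_field(
    seed: int,
    shape: tuple[int, int],
    low: float = 0.01,
    high: float = 0.05,
    smooth_scale: float = 24.0,
) -> np.ndarray:
    """Smooth nonnegative cooling-slope field in [low, high] degC/%.

    A Gaussian-filtered white-noise field rescaled to the given range;
    the correlation length (``smooth_scale`` pixels) is chosen large
    relative to regression windows so the slope is locally constant.
    The default range brackets a summer urban scene (median ~0.03
    degC/%, the magnitude reported for peak-season cooling), matching
    the 40 degC base temperature of :func:`render_lst`.
    """
    rng = np.random.default_rng(seed)
    z = gaussian_filter(rng.standard_normal(shape), smooth_scale, mode="reflect")
    zmin, zmax = z.min(), z.max()
    if zmax - zmin < 1e-12:
        return np.full(shape, (low + high) / 2.0)
    return low + (high - low) * (z - zmin) / (zmax - zmin)


def render_reflectance(
    truth: SceneTruth, doys: np.ndarray | None = None
) -> ReflectanceSeries:
    """Render the 4-band reflectance time series from scene truth.

    Per pixel and date: reflectance = fractions . endmember spectra at
    that DOY, plus i.i.d. Gaussian noise of sd ``truth.noise_sd``.
    Clouded observations are flagged via the boolean cloud raster; the
    underlying reflectance is still rendered (masking is downstream's
    job). Noise stream: one Generator seeded ``truth.seed + 3``,
    consumed date by date.
    """
    doys = truth.doys if doys is None else np.asarray(doys)
    if len(doys) == 0:
        raise ValueError("doys must be nonempty")
    if np.any((doys < 1) | (doys > 366)):
        raise ValueError("doys must lie in [1, 366]")
    rng = np.random.default_rng(truth.seed + 3)
    frames = []
    for doy in doys:
        spectra = truth.endmembers.reflectance(int(doy))  # (3, 4)
        img = np.einsum("khw,kb->bhw", truth.fractions, spectra)
        if truth.noise_sd > 0:
            # physical reflectance bounds; keeps indices in [-1, 1]
            img = np.clip(img + rng.normal(0.0, truth.noise_sd, img.shape), 0.0, 1.0)
        frames.append(img)
    return ReflectanceSeries(
        doys=doys,
        reflectance=np.stack(frames),
        cloud=truth.cloud_schedule[: len(doys)].copy(),
        transform=truth.transform,
    )


def render_lst(
    greenspace: np.ndarray,
    ce_truth: np.ndarray,
    base_lst: float = 40.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """LST raster linearly coupled to greenspace coverage.

    ``LST = base_lst - ce_truth * (100 * greenspace) + noise`` so that
    ``ce_truth`` is the cooling slope in degC per 1% coverage.
    """
    greenspace = np.asarray(greenspace, dtype=float)
    ce_truth = np.asarray(ce_truth, dtype=float)
    if greenspace.shape != ce_truth.shape:
        raise ValueError("greenspace and ce_truth rasters must be co-registered")
    lst = base_lst - ce_truth * (100.0 * greenspace)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        lst = lst + rng.normal(0.0, noise_sd, lst.shape)
    return lst


def default_ce_scene(
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    base_lst: float = 40.0,
    lst_noise_sd: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard cooling-efficiency test scene at thermal-pixel scale.

    Returns ``(green, ce_truth, lst)``. The greenspace raster is a
    high-contrast urban mosaic — each pixel is either impervious
    (coverage ~ U(0, 0.2)) or vegetated (coverage ~ U(0.7, 1.0)) with
    equal probability — emulating a city at the coarse thermal-sensor
    resolution, where built-up and park pixels interleave at the
    window scale. That within-window coverage contrast is what makes
    the local LST-vs-greenspace slope identifiable. ``ce_truth`` is
    the smooth summer slope field of :func:`make_ce_field` and ``lst``
    its rendering with Gaussian noise of ``lst_noise_sd`` degC.

    Sub-seeds: mosaic ``seed``, slope field ``seed+2``, LST noise
    ``seed+4``.
    """
    rng = np.random.default_rng(seed)
    vegetated = rng.random(shape) < 0.5
    green = np.where(
        vegetated, rng.uniform(0.7, 1.0, shape), rng.uniform(0.0, 0.2, shape)
    )
    ce = make_ce_field(seed + 2, shape)
    lst = render_lst(green, ce, base_lst=base_lst, noise_sd=lst_noise_sd, seed=seed + 4)
    return green, ce, lst


def default_scene(
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    patch_scale: int = 16,
    noise_sd: float = 0.01,
    cloud_prob: float = 0.3,
    bimodal: bool = False,
    revisit_days: int = 5,
) -> SceneTruth:
    """The standard test scene: 128x128 pixels, 5-day revisit, patchy
    clouds at 30% per date, reflectance noise sd 0.01, pure patches
    guaranteed for all three endmember classes.

    Sub-seed derivation (fixed offsets from ``seed``): fractions
    ``seed``, clouds ``seed+1``, cooling field ``seed+2``, reflectance
    noise ``seed+3``.
    """
    doys = np.arange(3, 366, revisit_days)
    phen = (
        PhenologyParams(mode="bimodal", peak_doys=(120, 270), pulse_half_width=30.0)
        if bimodal
        else PhenologyParams()
    )
    fractions = make_fraction_maps(seed, shape, patch_scale, ensure_pure=True)
    clouds = make_cloud_schedule(seed + 1, len(doys), shape, prob=cloud_prob)
    ce = make_ce_field(seed + 2, shape)
    return SceneTruth(
        fractions=fractions,
        phenology=phen,
        endmembers=SeasonalEndmembers(phenology=phen),
        doys=doys,
        cloud_schedule=clouds,
        ce_truth=ce,
        noise_sd=noise_sd,
        seed=seed,
    )


def write_scene(truth: SceneTruth, series: ReflectanceSeries, outdir: str | Path) -> Path:
    """Persist a rendered scene: one 4-band reflectance GeoTIFF and one
    cloud-mask GeoTIFF per date, truth rasters, and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t, doy in enumerate(series.doys):
        tag = f"{int(doy):03d}"
        write_raster(
            outdir / f"reflectance_doy{tag}.tif",
            Raster(series.reflectance[t], truth.transform, meta={"doy": int(doy)}),
        )
        write_raster(
            outdir / f"cloud_doy{tag}.tif",
            Raster(
                series.cloud[t].astype(np.uint8),
                truth.transform,
                meta={"doy": int(doy), "kind": "cloud_mask"},
            ),
        )
    write_raster(outdir / "truth_fractions.tif", Raster(truth.fractions, truth.transform))
    write_raster(outdir / "truth_ce.tif", Raster(truth.ce_truth, truth.transform))
    manifest = {
        "doys": [int(d) for d in series.doys],
        "seed": truth.seed,
        "noise_sd": truth.noise_sd,
        "phenology": {
            "baseline_ndvi": truth.phenology.baseline_ndvi,
            "amplitude": truth.phenology.amplitude,
            "peak_doys": list(truth.phenology.peak_doys),
            "rise_rate": truth.phenology.rise_rate,
            "fall_rate": truth.phenology.fall_rate,
            "mode": truth.phenology.mode,
            "pulse_half_width": truth.phenology.pulse_half_width,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def read_scene(scenedir: str | Path) -> tuple[ReflectanceSeries, dict]:
    """Load a scene written by :func:`write_scene`."""
    scenedir = Path(scenedir)
    manifest = json.loads((scenedir / "manifest.json").read_text())
    doys = np.array(manifest["doys"])
    refl, cloud = [], []
    transform = DEFAULT_TRANSFORM
    for doy in doys:
        tag = f"{int(doy):03d}"
        r = read_raster(scenedir / f"reflectance_doy{tag}.tif")
        c = read_raster(scenedir / f"cloud_doy{tag}.tif")
        refl.append(r.data)
        cloud.append(c.data.astype(bool))
        transform = r.transform
    series = ReflectanceSeries(
        doys=doys,
        reflectance=np.stack(refl),
        cloud=np.stack(cloud),
        transform=transform,
    )
    return series, manifest
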