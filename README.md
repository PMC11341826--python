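# greencube

Phenology-informed sub-pixel greenspace mapping as a testable raster
pipeline: constrained spectral unmixing of greenest composites, NDVI
phenology reconstruction, assembly of 36-layer annual greenspace data
cubes, and moving-window estimation of vegetation cooling efficiency
against land-surface-temperature rasters.

## The problem

Urban greenspace is seasonal: a city's tree canopy and grassland wax
and wane through the year, so a single annual map misstates how much
green cover residents actually experience in, say, February. Mapping
that seasonality at fine resolution requires combining two signals
that are individually incomplete — sub-pixel *fractional* greenspace
(how much of each pixel is vegetated at its annual maximum) and the
NDVI *phenology* (how greenness scales through the year).

`greencube` implements that combination for multispectral
(blue/green/red/NIR) surface-reflectance time series, and ships a
fully ground-truthed synthetic-scene generator so every stage can be
verified by parameter recovery without any satellite archive.

## The model

**Greenspace coverage at 10-day slot t** scales the annual maximum by
the NDVI seasonality ratio:

```
G_t = G_max · NDVI_t / NDVI_max
```

**G_max** comes from fully constrained linear spectral unmixing of the
annual *greenest composite* (per pixel, all six feature bands — blue,
green, red, NIR, NDVI, NDWI — taken jointly from the valid observation
with maximal NDVI):

```
S_i = Σ_k f_ik · C_k + ε_i      subject to   Σ_k f_ik = 1,  f_ik ≥ 0
```

with three endmembers (vegetation, bare surface, water) whose
signatures are derived automatically from index-threshold candidates
(vegetation NDVI > 0.8, bare NDVI < 0.2, water NDWI > 0.3) on the
composite. G_max is the vegetation fraction.

**NDVI_t** is reconstructed in three fixed steps: linear gap-filling
of cloud-masked observations on the day-of-year axis, averaging into
36 ten-day slots, and RMMEH compound smoothing (each interior slot
becomes the maximum of its value, the 3-point running median, and the
neighbour mean — an upper envelope, because cloud contamination biases
NDVI downward). NDVI_max is the maximum of the smoothed series.

**Cooling efficiency (CE)** — the LST reduction per 1% increase in
greenspace coverage — is estimated per pixel by ordinary least squares
of LST on greenspace percent over a small moving window (default 5×5),
with CE = −slope so that cooling is positive.

Cubes are written as 36-band int16 GeoTIFFs with scale factor 0.001
and nodata −1; block-level validation (default 200 m × 200 m blocks)
scores two coverage rasters by r² and RMSE of block means.

## Worked example

```python
import numpy as np
import greencube as gc

truth = gc.default_scene(seed=7)            # 128x128 scene, 73 dates, clouds + noise
series = gc.render_reflectance(truth)
res = gc.run_pipeline(series)

rmse = np.sqrt(np.nanmean((res.fractions.fractions - truth.fractions) ** 2))
print(f"fraction RMSE vs truth:  {rmse:.4f}")
print(f"annual max coverage:     {np.nanmean(res.fractions.gmax):.3f} (truth {truth.gmax_truth.mean():.3f})")
print(f"cube shape:              {res.cube.layers.shape}")

from greencube.synthetic import default_ce_scene
green, ce_truth, lst = default_ce_scene(seed=7)
cem = gc.cooling_efficiency(lst, green, window=5)
m = np.isfinite(cem.ce)
print(f"median CE estimate:      {np.median(cem.ce[m]):.4f} degC/% "
      f"(truth median {np.median(ce_truth[m]):.4f})")
```

prints

```
fraction RMSE vs truth:  0.0153
annual max coverage:     0.251 (truth 0.257)
cube shape:              (36, 128, 128)
median CE estimate:      0.0255 degC/% (truth median 0.0257)
```

i.e. the pipeline recovers per-pixel endmember fractions to ~0.015 RMSE
under reflectance noise of 0.01 and 30% patchy cloud cover, produces
the 36-slot annual cube, and the moving-window regression recovers the
known cooling slope field to within a few percent at 0.5 °C LST noise.

The same stages are available from a shell:

```bash
greencube simulate scene/ --seed 7
greencube composite scene/ composite.tif
greencube unmix composite.tif fractions.tif
greencube phenology scene/ phen.tif
greencube cube fractions.tif phen.tif cube.tif
greencube cooling scene/lst.tif cube.tif ce.tif --lst-doy 199
greencube validate fractions.tif fractions.tif
```

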