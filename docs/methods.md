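# Methods

This note documents the models implemented in `greencube`, the
parameter choices that matter, what the synthetic scenes do and do not
emulate, and the numerical conventions.

## Pipeline overview

The annual mapping chain is order-fixed:

1. **Cloud masking.** Pixels at or above a cloud-probability threshold
   (default 50%, configurable; boolean masks are honoured directly)
   are invalidated. Reflectance values are never altered.
2. **Feature stacking.** Each observation becomes a six-band signature
   (blue, green, red, NIR, NDVI, NDWI). NDVI = (NIR−red)/(NIR+red);
   NDWI is the McFeeters green-vs-NIR form, appropriate for open-water
   detection. Zero-denominator pixels become invalid, not zero, so
   compositing never ranks on a fabricated index.
3. **Greenest compositing.** Per pixel, all six bands are taken
   jointly from the single valid observation with maximal NDVI (ties
   to the earliest date). A joint "quality mosaic" rather than
   per-band maxima is required so unmixing sees a physically
   consistent signature from one acquisition.
4. **Endmember derivation and unmixing** (below); the vegetation
   fraction of the composite is the annual maximum coverage G_max.
5. **Phenology reconstruction** (below) gives the 36-slot smoothed
   NDVI series and its maximum.
6. **Cube assembly.** G_t = G_max · clip(NDVI_t, 0, ∞)/NDVI_max,
   clamped to [0, G_max].

## Temporal grid

One year maps to exactly 36 ten-day slots: slots 1–35 cover DOY
10(k−1)+1..10k and slot 36 absorbs DOY 351 to year end (a long final
slot). The alternative — 37 short slots — would break the 36-band file
contract, so the final-slot clamp is the package's declared
convention. Slot midpoints drive temporal matching of LST scenes
(nearest midpoint, ties to the earlier slot).

## Constrained unmixing

Each signature is decomposed over three endmembers (vegetation, bare,
water) by least squares under the abundance constraints f ≥ 0,
Σf = 1. The sum-to-one constraint is embedded as a heavily weighted
augmented row (weight 1e4) on a nonnegative-least-squares core, and
the result is renormalised; constraint violations are below 1e-9 for
any conditioned endmember set, and on noise-free exact mixtures the
solver recovers fractions to ~1e-11 (verified against an exhaustive
simplex grid search at step 1e-3).

**Endmember candidates** come from index thresholds on the composite:
vegetation NDVI > 0.8, bare NDVI < 0.2, water NDWI > 0.3. The water
threshold is configurable because the number is not well established;
0.3 is a common operating point for the McFeeters index. Note the
thresholds overlap by construction — open water also has NDVI < 0.2 —
so water candidates are removed from the bare class before signature
derivation.

**Signature derivation** replaces interactive region-of-interest
drawing with a reproducible rule. The default ("percentile-purity")
averages the candidates whose purity score lies within a margin
(0.05) of the best candidate's. Two design points matter:

* *Scores are computed on the 3×3 center-excluded neighbourhood mean*
  of the composite. Ranking pixels by their own noisy index
  preferentially selects positive noise excursions and biases the
  averaged signature (the selection noise is exactly the noise being
  averaged); ranking by the neighbours keeps selection independent of
  each selected pixel's own noise.
* *Margin-of-the-maximum, not a fixed percentile.* When candidate sets
  are dominated by near-pure mixtures (common for water, whose NDWI
  threshold admits ~40%-water pixels), a top-decile cut keeps whole
  mixture patches; a margin below the best score adapts to the
  abundance distribution and resolves to the pure extreme.

Vegetation and water are scored by their own index; bare — an interior
vertex with no extreme index — is scored by distance from the
vegetation–water segment in feature space, which no convex mixture of
the other two classes can maximise.

## Phenology reconstruction

Gap-filling is linear on the irregular day-of-year axis between
nearest valid neighbours, with leading/trailing gaps taking the
nearest valid value; all-gap pixels become no-data. After ten-day
averaging, slots that received no observation at all are filled
linearly on the slot-midpoint axis, so every pixel with at least one
valid observation gets a complete 36-slot series.

The RMMEH compound smoother is implemented as: per pass, each interior
slot t of the pass input v becomes max(v_t, median(v_{t−1}, v_t,
v_{t+1}), (v_{t−1}+v_{t+1})/2), endpoints copied; default two passes.
This is an upper-envelope operator (output ≥ input pointwise): cloud
contamination biases NDVI downward, so single-slot dips are lifted to
the neighbour level while genuine peaks are preserved. Published
variants of this smoother differ in window size and pass count; any
variant satisfying the envelope contract can be substituted.

One consequence worth knowing: on a noise-free steep (logistic)
green-up the neighbour-mean term lifts the convex shoulders of the
curve by up to ~0.035 NDVI at the default slot width, so the smoothed
series is not identical to the raw curve even without noise. The
cube's seasonal term is *defined* on the smoothed series (NDVI_max is
taken from it too, which also guarantees the coverage ratio never
exceeds one).

**Aseasonal floor.** The coverage ratio is undefined for barren or
water pixels whose NDVI_max is near zero. Pixels with NDVI_max below
0.05 get constant G_t = G_max and an aseasonal flag rather than a
division by an arbitrary small number.

## Cube file format

36-band int16 GeoTIFF; stored value = round(G/0.001) with rounding
half away from zero; nodata code −1; the scale factor, year and band
count are recorded in the file metadata. Physical coverage round-trips
within half a quantum (0.0005). I/O is built on `tifffile`, writing
the GeoTIFF ModelPixelScale/ModelTiepoint tags plus a JSON metadata
block, and a minimal north-up affine transform type; polygon masking
(city boundaries as GeoJSON) evaluates pixel centers against the
geometry with `shapely`.

## Cooling efficiency

Per center pixel, ordinary least squares of LST (°C) on greenspace in
percent (0–100) over an odd moving window; CE = −slope so cooling is
positive. Default window 5×5; windows with fewer than 10 valid pixels
or with coverage standard deviation below 0.05 are masked (the slope
is undefined or hopelessly ill-posed there — these two criteria are
the package's choices). All window sums are uniform-filter based, so
the estimator is vectorised. A sensitivity helper summarises CE over
window sizes 5–13, scaling the minimum-count criterion with window
area.

The estimator is exact on noise-free linear scenes and achieves the
information bound on noisy ones: the slope standard error is
σ_LST/(σ_x·√n) with x in percent, so recovery precision is governed by
the within-window coverage contrast, not by algorithmic choices.

## Synthetic scenes

The generator emulates: per-pixel convex mixtures of three endmember
spectra drawn patchwise on the unit simplex (flat Dirichlet per patch,
default 16-pixel patches; one guaranteed pure patch per class so
candidate masks are never empty); a scene-wide seasonal vegetation
trajectory (baseline plus one or two logistic rise/fall pulses —
unimodal tree-crown or bimodal grassland phenology; defaults: baseline
0.30, amplitude 0.62, peak DOY 200, rates 0.15/day); per-date
Bernoulli cloud patches (default 30%); additive Gaussian reflectance
noise (default sd 0.01) clipped to physical [0, 1]; and a 5-day
revisit (73 dates). All randomness flows through one seed with
documented fixed offsets per stream.

**Exact index linearity.** The three endmember spectra share identical
red+NIR (0.80) and green+NIR (0.85) band sums at every date, which
makes the NDVI and NDWI of any convex reflectance mixture *exactly*
linear in the fractions. The six-band mixing model then holds without
approximation and noise-free unmixing can be required to recover truth
to machine precision. Under this constraint every band except blue is
affine in the endmember's NIR, so the effective spectral space is the
(blue, NIR) plane; the default spectra (blue 0.03/0.55/0.06 for
vegetation/bare/water, NIR 0.42 bare, 0.02 water) spread the
endmembers widely in that plane, keeping the least-squares noise gain
near 1.5. The cost is spectral realism — the water endmember carries a
physically implausible green band — so tests on these scenes probe the
pipeline's algebra, selection logic and formats, *not* robustness to
real spectra, nonlinear mixing, shadows or sensor artifacts.

**Cooling-efficiency scene.** A separate default scene at
thermal-pixel scale: a high-contrast urban mosaic (each pixel either
impervious, coverage ~ U(0, 0.2), or vegetated, ~ U(0.7, 1.0)),
because within-window coverage contrast is what makes the windowed
slope identifiable; the truth slope field is a smooth random field in
0.01–0.05 °C/% (median ≈ 0.03, a peak-season magnitude consistent with
the 40 °C base temperature), with correlation length 24 pixels so the
slope is locally constant over any tested window; LST noise sd 0.5 °C.

## Problem sizes

Default test and acceptance runs use a 128×128-pixel scene with 73
dates (and a 48×48 noise-free scene for exact-recovery checks), small
enough that the full suite completes in well under a minute while
every stage still operates on thousands of mixed pixels per class.

## Known limitations

* No radiative-transfer realism, sensor PSF, BRDF or orbit geometry in
  the generator; cloud statistics are Bernoulli patches, not real
  climatology.
* Shadow effects — a known cause of underestimated or negative NDVI in
  dense urban scenes — are not modelled; the cube clamps negative
  NDVI to zero but cannot recover shaded vegetation.
* Endmember signatures are derived per scene-year from that scene's
  composite; no cross-scene spectral library, no multiple-endmember
  (MESMA) or nonlinear mixing.
* The phenology module reconstructs the trajectory only; it does not
  extract green-up/senescence dates or fit curve models to
  observations.
* LST rasters are assumed co-registered with the greenspace grid;
  thermal retrieval and LST cloud screening are out of scope.
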