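"""End-to-end orchestration: reflectance series -> greenspace cube.

Chains the stage modules in the framework's fixed order: cloud
masking, six-band feature stacking, greenest compositing, endmember
selection and constrained unmixing (annual maximum coverage), NDVI
phenology reconstruction, and cube assembly. Each stage remains
independently usable; this module only wires defaults together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compositing import TemporalGrid, greenest_composite
from .cube import GreenspaceCube, assemble_cube
from .features import FeatureImage, ReflectanceSeries, apply_cloud_mask, build_feature_stack
from .phenology import NdviPhenology, build_ndvi_phenology
from .unmixing import (
    EndmemberSet,
    FractionMap,
    derive_endmember_signatures,
    select_endmember_candidates,
    unmix_image,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All intermediate products of one scene-year run."""

    composite: FeatureImage
    endmembers: EndmemberSet
    fractions: FractionMap
    phenology: NdviPhenology
    cube: GreenspaceCube


def run_pipeline(
    series: ReflectanceSeries,
    cloud_threshold: float = 50.0,
    ndvi_veg_min: float = 0.8,
    ndvi_bare_max: float = 0.2,
    ndwi_water_min: float = 0.3,
    endmember_strategy: str = "percentile-purity",
    rmmeh_passes: int = 2,
    eps_floor: float = 0.05,
    year: int = 2020,
    grid: TemporalGrid | None = None,
) -> PipelineResult:
    """Run the full annual mapping chain on one reflectance series."""
    grid = grid or TemporalGrid()
    masked = apply_cloud_mask(series, cloud_threshold)
    features = build_feature_stack(masked)
    composite = greenest_composite(features)

    masks = select_endmember_candidates(
        composite,
        ndvi_veg_min=ndvi_veg_min,
        ndvi_bare_max=ndvi_bare_max,
        ndwi_water_min=ndwi_water_min,
    )
    endmembers = derive_endmember_signatures(composite, masks, strategy=endmember_strategy)
    fractions = unmix_image(composite, endmembers)

    ndvi_obs = np.stack([f.ndvi for f in features])
    valid = np.stack([f.valid for f in features])
    phen = build_ndvi_phenology(masked.doys, ndvi_obs, valid, grid=grid, passes=rmmeh_passes)

    cube = assemble_cube(
        fractions.gmax, phen, eps_floor=eps_floor, year=year, transform=series.transform
    )
    return PipelineResult(
        composite=composite,
        endmembers=endmembers,
        fractions=fractions,
        phenology=phen,
        cube=cube,
    )
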