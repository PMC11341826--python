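"""Endmember selection and fully constrained linear spectral unmixing.

Each pixel's six-band signature S is modeled as a convex combination
of endmember signatures: S = sum_k f_k C_k + eps with the physical
abundance constraints f_k >= 0 and sum_k f_k = 1. The three-endmember
scheme (vegetation, bare surface, water) is the default; the
vegetation fraction of the annual greenest composite is the annual
maximum greenspace coverage G_max.

The solver embeds the sum-to-one constraint as a heavily weighted
augmented row on top of a nonnegativity-constrained least-squares core
(scipy's active-set NNLS), then renormalises, which enforces both
constraints to well below 1e-9 for any conditioned endmember set.

Endmember candidates come from index thresholds on the greenest
composite — vegetation NDVI > 0.8, bare NDVI < 0.2, water NDWI above a
configurable threshold (default 0.3) — and signatures are derived from
candidate pixels automatically (mean, or mean of the purest top
percentile ranked by the class index), replacing interactive
region-of-interest drawing for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import nnls

from .features import FeatureImage

__all__ = [
    "EndmemberSet",
    "FractionMap",
    "EndmemberNotFoundError",
    "select_endmember_candidates",
    "derive_endmember_signatures",
    "unmix_pixel",
    "unmix_image",
]

ENDMEMBER_NAMES = ("vegetation", "bare", "water")
_SUM_WEIGHT = 1e4  # weight of the augmented sum-to-one row


class EndmemberNotFoundError(ValueError):
    """Raised when a candidate class has no pixels to derive a signature."""


@dataclass
class EndmemberSet:
    """n endmember six-band signatures, rows ordered like ``names``."""

    signatures: np.ndarray  # (n, 6)
    names: tuple[str, ...] = ENDMEMBER_NAMES
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.signatures = np.asarray(self.signatures, dtype=float)
        if self.signatures.ndim != 2 or self.signatures.shape[0] < 2:
            raise ValueError("need a (n>=2, bands) signature matrix")
        if not np.all(np.isfinite(self.signatures)):
            raise ValueError("endmember signatures must be finite")
        for i in range(len(self.signatures)):
            for j in range(i + 1, len(self.signatures)):
                if np.allclose(self.signatures[i], self.signatures[j]):
                    raise ValueError("endmember signatures must be pairwise distinct")

    @property
    def n(self) -> int:
        return self.signatures.shape[0]


@dataclass
class FractionMap:
    """Per-pixel endmember fractions with residual norm and validity."""

    fractions: np.ndarray  # (n, H, W)
    residual: np.ndarray  # (H, W)
    valid: np.ndarray  # (H, W) bool
    names: tuple[str, ...] = ENDMEMBER_NAMES

    @property
    def gmax(self) -> np.ndarray:
        """Vegetation fraction layer — the annual maximum greenspace."""
        return self.fractions[self.names.index("vegetation")]


def select_endmember_candidates(
    composite: FeatureImage,
    ndvi_veg_min: float = 0.8,
    ndvi_bare_max: float = 0.2,
    ndwi_water_min: float = 0.3,
) -> dict[str, np.ndarray]:
    """Threshold the greenest composite into candidate masks per class.

    vegetation: NDVI > ndvi_veg_min; bare: NDVI < ndvi_bare_max;
    water: NDWI > ndwi_water_min. Restricted to valid pixels.
    """
    for thr in (ndvi_veg_min, ndvi_bare_max, ndwi_water_min):
        if not -1.0 <= thr <= 1.0:
            raise ValueError("index thresholds must lie in [-1, 1]")
    v = composite.valid
    with np.errstate(invalid="ignore"):
        return {
            "vegetation": v & (composite.ndvi > ndvi_veg_min),
            "bare": v & (composite.ndvi < ndvi_bare_max),
            "water": v & (composite.ndwi > ndwi_water_min),
        }


def _dist_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance of each row of ``points`` to the segment [a, b]."""
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(points - (a + t[:, None] * ab), axis=1)


def _annulus_mean(img: np.ndarray) -> np.ndarray:
    """3x3 neighbourhood mean excluding the center pixel.

    Used as the purity-ranking signal: ranking candidates by their
    *neighbours* keeps the ranking statistically independent of each
    candidate's own noise, so averaging the selected pixels carries no
    selection bias (ranking by a pixel's own noisy index would
    preferentially select positive noise excursions and bias the
    signature).
    """
    from scipy.ndimage import uniform_filter

    finite = np.isfinite(img)
    filled = np.where(finite, img, 0.0)
    s9 = uniform_filter(filled, size=3, mode="constant", cval=0.0) * 9.0
    n9 = uniform_filter(finite.astype(float), size=3, mode="constant", cval=0.0) * 9.0
    num = s9 - filled
    den = n9 - finite.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den <= 0] = np.nan
    return out


def derive_endmember_signatures(
    composite: FeatureImage,
    masks: dict[str, np.ndarray],
    strategy: str = "percentile-purity",
    purity_margin: float = 0.05,
) -> EndmemberSet:
    """Derive one six-band signature per class from its candidates.

    The NDVI/NDWI threshold masks overlap by construction (open water
    also has NDVI < 0.2), so water candidates are removed from the
    bare class first — the step a human performs implicitly when
    drawing regions of interest.

    strategy "mean": componentwise mean of the candidate pixels.
    strategy "percentile-purity" (default): mean over the purest
    candidates, where purity is scored by NDVI for vegetation and NDWI
    for water; bare (an interior vertex in index space, with no
    extreme index of its own) is scored by distance from the
    vegetation-water segment in feature space, which a convex mixture
    of the other two classes cannot have. Candidates are kept if their
    score lies within ``purity_margin`` of the best candidate's
    (index units for vegetation/water; relative for the bare
    distance): unlike a fixed percentile cut, the margin adapts to the
    unknown abundance distribution, so candidate sets dominated by
    near-pure mixtures still resolve to the pure extreme. All purity
    scores are evaluated on the 3x3 center-excluded neighbourhood mean
    of the composite so the selection is independent of each selected
    pixel's own noise (see :func:`_annulus_mean`).
    """
    if strategy not in ("mean", "percentile-purity"):
        raise ValueError(f"unknown strategy {strategy!r}")
    eff = dict(masks)
    eff["bare"] = masks["bare"] & ~masks["water"]
    counts: dict[str, int] = {}
    sig_by_name: dict[str, np.ndarray] = {}
    if strategy == "percentile-purity":
        smooth = np.stack([_annulus_mean(b) for b in composite.bands])
    else:
        smooth = composite.bands

    def _pixels(name: str) -> np.ndarray:
        mask = eff[name]
        n_cand = int(mask.sum())
        if n_cand == 0:
            raise EndmemberNotFoundError(f"no candidate pixels for endmember {name!r}")
        counts[name] = n_cand
        return composite.bands[:, mask].T  # (n_cand, 6)

    def _top(pix: np.ndarray, score: np.ndarray, cut: float) -> np.ndarray:
        score = np.where(np.isfinite(score), score, -np.inf)
        keep = score >= cut
        return pix[keep] if keep.any() else pix

    # vegetation and water have extreme-index purity scores; derive first
    for name, band in (("vegetation", 4), ("water", 5)):
        pix = _pixels(name)
        if strategy == "percentile-purity" and len(pix) > 1:
            score = smooth[band][eff[name]]
            smax = np.nanmax(score)
            pix = _top(pix, score, smax - purity_margin)
        sig_by_name[name] = pix.mean(axis=0)

    pix = _pixels("bare")
    if strategy == "percentile-purity" and len(pix) > 1:
        neigh = smooth[:, eff["bare"]].T
        score = _dist_to_segment(neigh, sig_by_name["vegetation"], sig_by_name["water"])
        smax = np.nanmax(score)
        pix = _top(pix, score, smax * (1.0 - purity_margin))
    sig_by_name["bare"] = pix.mean(axis=0)

    return EndmemberSet(
        signatures=np.array([sig_by_name[n] for n in ENDMEMBER_NAMES]),
        provenance={"strategy": strategy, "candidate_counts": counts},
    )


def unmix_pixel(
    signature: np.ndarray, endmembers: EndmemberSet
) -> tuple[np.ndarray, float]:
    """Solve one pixel's constrained unmixing problem.

    Minimises ||S - C^T f||_2 subject to f >= 0 and sum(f) = 1;
    returns (fractions, residual norm). A non-finite signature yields
    NaN fractions (invalid pixel), not an exception.
    """
    s = np.asarray(signature, dtype=float)
    n = endmembers.n
    if not np.all(np.isfinite(s)):
        return np.full(n, np.nan), np.nan
    A = np.vstack([endmembers.signatures.T, np.full(n, _SUM_WEIGHT)])
    b = np.concatenate([s, [_SUM_WEIGHT]])
    f, _ = nnls(A, b)
    total = f.sum()
    if total > 0:
        f = f / total
    resid = float(np.linalg.norm(s - endmembers.signatures.T @ f))
    return f, resid


def unmix_image(composite: FeatureImage, endmembers: EndmemberSet) -> FractionMap:
    """Per-pixel constrained unmixing of a six-band composite.

    Invalid composite pixels stay invalid; the vegetation layer of the
    result is the annual maximum greenspace coverage G_max.
    """
    h, w = composite.valid.shape
    n = endmembers.n
    fractions = np.full((n, h, w), np.nan)
    residual = np.full((h, w), np.nan)
    valid = composite.valid & np.isfinite(composite.bands).all(axis=0)
    sigs = composite.bands[:, valid].T  # (m, 6)
    out = np.empty((sigs.shape[0], n))
    res = np.empty(sigs.shape[0])
    for i, s in enumerate(sigs):
        out[i], res[i] = unmix_pixel(s, endmembers)
    fractions[:, valid] = out.T
    residual[valid] = res
    return FractionMap(
        fractions=fractions,
        residual=residual,
        valid=valid,
        names=tuple(endmembers.names),
    )
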