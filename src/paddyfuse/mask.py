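"""Phenology decision-tree mask.

Before machine-learning classification, pixels that cannot be cropland are
removed with three sequential threshold rules on the monthly NDVI composite,
evaluated in fixed first-match order:

1. November NDVI > 0.4            -> forest/meadow
2. annual maximum NDVI < 0.1      -> water
3. May-October maximum NDVI < 0.6 -> built-up / bare soil
4. otherwise                      -> candidate cropland

The order matters: a curve that satisfies both the water and the built/bare
predicate (e.g. constant 0.05) is water. Pixels lacking the required months
(November, or all of May-October, or the whole year undefined) cannot be
ruled on and are labelled unclassifiable and excluded, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Integer legend of the mask raster.
MASK_CODES = {
    "candidate": 0,
    "forest_meadow": 1,
    "water": 2,
    "built_bare": 3,
    "unclassifiable": 255,
}
MASK_LABELS = {v: k for k, v in MASK_CODES.items()}


@dataclass(frozen=True)
class MaskThresholds:
    """Decision-tree thresholds; defaults are the operational values."""

    forest_november: float = 0.4
    water_annual_max: float = 0.1
    built_summer_max: float = 0.6
    november_month: int = 11
    summer_months: tuple[int, ...] = (5, 6, 7, 8, 9, 10)


DEFAULT_THRESHOLDS = MaskThresholds()


def apply_mask_rules(
    series, thresholds: MaskThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Label one pixel's 12-month series with the decision tree.

    ``series`` is a length-12 sequence (January-December) with NaN for
    missing months. Returns one of ``candidate``, ``forest_meadow``,
    ``water``, ``built_bare`` or ``unclassifiable``.
    """
    s = np.asarray(series, dtype=float)
    if s.shape != (12,):
        raise ValueError("series must have 12 monthly values")
    return MASK_LABELS[int(mask_raster(s.reshape(12, 1, 1), thresholds)[0][0, 0])]


def mask_raster(
    composite: np.ndarray, thresholds: MaskThresholds = DEFAULT_THRESHOLDS
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the decision tree to a ``(12, H, W)`` composite.

    Returns ``(codes, candidate_index)``: the uint8 mask raster using
    ``MASK_CODES``, and a boolean ``(H, W)`` array marking candidate pixels
    passed on to the classifiers.
    """
    comp = np.asarray(composite, dtype=float)
    if comp.ndim != 3 or comp.shape[0] != 12:
        raise ValueError("composite must have shape (12, H, W)")
    t = thresholds
    nov = comp[t.november_month - 1]
    summer = comp[[m - 1 for m in t.summer_months]]
    with np.errstate(invalid="ignore"):
        annual_max = np.nanmax(
            np.where(np.isnan(comp), -np.inf, comp), axis=0)
        summer_max = np.nanmax(
            np.where(np.isnan(summer), -np.inf, summer), axis=0)
    # data sufficiency: November defined, at least one summer month defined,
    # at least one month defined at all
    ok = np.isfinite(nov) & np.isfinite(summer_max) & np.isfinite(annual_max)

    codes = np.full(comp.shape[1:], MASK_CODES["candidate"], dtype=np.uint8)
    rule1 = nov > t.forest_november
    rule2 = ~rule1 & (annual_max < t.water_annual_max)
    rule3 = ~rule1 & ~rule2 & (summer_max < t.built_summer_max)
    codes[rule1] = MASK_CODES["forest_meadow"]
    codes[rule2] = MASK_CODES["water"]
    codes[rule3] = MASK_CODES["built_bare"]
    codes[~ok] = MASK_CODES["unclassifiable"]
    candidate = codes == MASK_CODES["candidate"]
    return codes, candidate
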