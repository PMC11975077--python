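"""Post-classification tabulation and trend/driver statistics.

Turns classified rasters into per-region area tables (pixel count times pixel
area), fits ordinary least-squares time trends to yearly series, and
correlates rice-class planting proportions with socio-economic and climate
driver variables (Pearson r with two-sided t-test p-values). No
multiple-testing correction is applied; p-values are reported raw with
significance stars at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Default pixel area: a 10 m x 10 m grid cell in hectares.
DEFAULT_PIXEL_AREA_HA = 0.01

RICE_CLASSES = ("single", "double", "regenerated")


def tabulate_areas(
    classified: np.ndarray,
    legend: dict[str, int],
    regions: np.ndarray | None = None,
    pixel_area_ha: float = DEFAULT_PIXEL_AREA_HA,
    proportion_over: str = "rice",
) -> pd.DataFrame:
    """Per-region class areas (ha) and proportions (%).

    ``classified`` is an (H, W) raster of ``legend`` codes; ``regions`` an
    optional co-registered integer raster of region ids (None treats the
    scene as one region). Proportions are over the total rice area by
    default (``proportion_over="rice"``) or over all classified pixels
    (``"classified"``).
    """
    if pixel_area_ha <= 0:
        raise ValueError("pixel area must be positive")
    classified = np.asarray(classified)
    if regions is None:
        regions = np.zeros(classified.shape, dtype=int)
    regions = np.asarray(regions)
    if regions.shape != classified.shape:
        raise ValueError("regions raster shape mismatch")
    if proportion_over not in ("rice", "classified"):
        raise ValueError("proportion_over must be 'rice' or 'classified'")

    rows = []
    for rid in np.unique(regions):
        sel = regions == rid
        areas = {c: float(np.count_nonzero(sel & (classified == code))
                          * pixel_area_ha)
                 for c, code in legend.items()}
        total = sum(areas.values())
        denom_classes = (RICE_CLASSES if proportion_over == "rice"
                         else tuple(legend))
        denom = sum(areas.get(c, 0.0) for c in denom_classes)
        row = {"region": rid, **{f"area_{c}_ha": a for c, a in areas.items()},
               "area_total_ha": total}
        for c in denom_classes:
            row[f"prop_{c}_pct"] = (
                100.0 * areas.get(c, 0.0) / denom if denom > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of value against year."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float


def trend_fit(years, values) -> TrendFit:
    """Least-squares linear trend of a yearly series (slope per year)."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size != values.size:
        raise ValueError("years and values must have equal length")
    if years.size < 3:
        raise ValueError("need at least 3 years")
    if np.ptp(years) == 0:
        raise ValueError("years are constant; trend undefined")
    res = stats.linregress(years, values)
    return TrendFit(slope=float(res.slope), intercept=float(res.intercept),
                    r_squared=float(res.rvalue) ** 2,
                    p_value=float(res.pvalue))


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def driver_correlation(
    proportions: pd.DataFrame, drivers: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of class proportions against driver variables.

    Both inputs are indexed by year; each (proportion column, driver column)
    pair is correlated over the common years. Pairs with fewer than 3 common
    years or zero variance yield NaN. Returns a long-format table with
    columns ``class``, ``driver``, ``r``, ``p``, ``stars``, ``n``.
    """
    common = proportions.index.intersection(drivers.index)
    rows = []
    for cls in proportions.columns:
        for drv in drivers.columns:
            x = proportions.loc[common, cls].astype(float)
            y = drivers.loc[common, drv].astype(float)
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                r = p = float("nan")
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"class": cls, "driver": drv, "r": float(r),
                         "p": float(p), "stars": significance_stars(float(p)),
                         "n": n})
    return pd.DataFrame(rows)
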