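"""NDVI computation and monthly maximum-value compositing.

NDVI = (NIR - RED) / (NIR + RED), a unitless greenness index in [-1, 1].
The monthly composite takes, per pixel and calendar month, the maximum NDVI
over all scenes acquired in that month — the standard maximum-value composite
that suppresses cloud contamination. Missing data is carried as NaN.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SceneNdvi:
    """A single-date NDVI raster: acquisition date plus a 2-D grid.

    Nodata cells are NaN; all valid values lie in [-1, 1].
    """

    date: _dt.date
    ndvi: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.ndvi, dtype=float)
        object.__setattr__(self, "ndvi", arr)
        if arr.ndim != 2:
            raise ValueError("ndvi raster must be 2-D")
        valid = arr[np.isfinite(arr)]
        if valid.size and (valid.min() < -1 or valid.max() > 1):
            raise ValueError("NDVI values outside [-1, 1]")


def compute_ndvi(nir, red):
    """Compute NDVI from near-infrared and red reflectance.

    Accepts scalars or arrays of non-negative reflectance. Where
    ``nir + red == 0`` the quotient is undefined and the result is NaN
    (logged, not raised).
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if not (np.all(np.isfinite(nir)) and np.all(np.isfinite(red))):
        raise ValueError("reflectance must be finite")
    if np.any(nir < 0) or np.any(red < 0):
        raise ValueError("reflectance must be >= 0")
    denom = nir + red
    zero = denom == 0
    if np.any(zero):
        logger.info("compute_ndvi: %d zero-denominator pixels set to nodata",
                    int(np.count_nonzero(zero)))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(zero, np.nan, (nir - red) / np.where(zero, 1.0, denom))
    return out if out.ndim else float(out)


def monthly_max_composite(scenes: list[SceneNdvi]) -> np.ndarray:
    """Build the per-pixel 12-month maximum-value composite.

    Returns a ``(12, H, W)`` array; band k is calendar month k+1. A month with
    no valid observation for a pixel is NaN. Raises on an empty scene list or
    mismatched grids.
    """
    if not scenes:
        raise ValueError("at least one scene required")
    shape = scenes[0].ndvi.shape
    for s in scenes:
        if s.ndvi.shape != shape:
            raise ValueError(
                f"grid shape mismatch: {s.ndvi.shape} != {shape}")
    out = np.full((12,) + shape, np.nan)
    for s in scenes:
        m = s.date.month - 1
        out[m] = np.fmax(out[m], s.ndvi)  # fmax ignores NaN
    n_gap = int(np.count_nonzero(np.all(np.isnan(out), axis=0)))
    if n_gap:
        logger.info("monthly_max_composite: %d pixels with no valid month", n_gap)
    return out


def composite_series(series_by_month: dict[int, list[float]]) -> np.ndarray:
    """Composite a single pixel given observations grouped by month (1-12)."""
    out = np.full(12, np.nan)
    for month, vals in series_by_month.items():
        if not 1 <= month <= 12:
            raise ValueError("month must be in 1..12")
        v = np.asarray(vals, dtype=float)
        if v.size and not np.all(np.isnan(v)):
            out[month - 1] = np.nanmax(v)
    return out
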