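"""TIFF raster and tabular I/O helpers.

Rasters travel as multi-band float32 or single-band uint8 TIFFs via
tifffile; monthly composites are written with 12 bands (band k = month k).
Sample tables are CSV with columns ``pixel_id, m01..m12, label`` (plus
``split`` once partitioned). Georeferencing tags, if present in inputs, are
not interpreted; all operations are on the pixel grid.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import SceneNdvi

_DATE_RE = re.compile(r"(\d{4})[-_]?(\d{2})[-_]?(\d{2})")


def parse_scene_date(name: str) -> _dt.date:
    """Extract a YYYYMMDD / YYYY-MM-DD date from a scene file name."""
    m = _DATE_RE.search(name)
    if not m:
        raise ValueError(f"no acquisition date found in {name!r}")
    return _dt.date(*map(int, m.groups()))


def read_scene(path: str | Path, date: _dt.date | None = None) -> SceneNdvi:
    """Read a single-band NDVI TIFF; date defaults to one in the file name."""
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    return SceneNdvi(date or parse_scene_date(path.name), arr)


def write_raster(path: str | Path, array: np.ndarray) -> None:
    arr = np.asarray(array)
    dtype = np.uint8 if arr.dtype.kind == "u" else np.float32
    tifffile.imwrite(Path(path), arr.astype(dtype))


def read_raster(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))


def write_composite(path: str | Path, composite: np.ndarray) -> None:
    if composite.ndim != 3 or composite.shape[0] != 12:
        raise ValueError("composite must have shape (12, H, W)")
    write_raster(path, composite)


def sample_columns() -> list[str]:
    return ["pixel_id"] + [f"m{m:02d}" for m in range(1, 13)] + ["label"]


def write_samples(path: str | Path, samples: pd.DataFrame) -> None:
    cols = [c for c in sample_columns() + ["split"] if c in samples.columns]
    samples[cols].to_csv(Path(path), index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = [c for c in sample_columns() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_weights(path: str | Path, weights: dict[str, float]) -> None:
    Path(path).write_text(json.dumps(weights, indent=2, sort_keys=True) + "\n")


def read_weights(path: str | Path) -> dict[str, float]:
    return {str(k): float(v) for k, v in json.loads(Path(path).read_text()).items()}


def rasterize_regions(
    geojson: dict, shape: tuple[int, int], background: int = 0
) -> np.ndarray:
    """Rasterize GeoJSON polygon features onto a pixel grid.

    Pixel (row, col) centres are tested at coordinates (col + 0.5, row + 0.5);
    features are burned in order using their ``region_id`` property (or
    1-based feature index). Intended for small scenes; coordinates must
    already be in pixel units.
    """
    from shapely.geometry import Point, shape as _shape

    h, w = shape
    out = np.full((h, w), background, dtype=int)
    xs, ys = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    for k, feat in enumerate(geojson.get("features", [])):
        geom = _shape(feat["geometry"])
        rid = int(feat.get("properties", {}).get("region_id", k + 1))
        for i in range(h):
            for j in range(w):
                if geom.covers(Point(xs[i, j], ys[i, j])):
                    out[i, j] = rid
    return out
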