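"""Synthetic NDVI phenology simulator.

Generates labelled 12-month NDVI time series and small raster scenes whose
noiseless curves reproduce the qualitative phenology of the land-cover classes
in the Poyang Lake cropping system:

* double-cropping rice — double-peak curve with maxima in June and September
  and a harvest/transplant trough in July;
* regenerated (ratoon) rice — double-peak curve with maxima in July and
  September and a trough in August;
* single-cropping rice — single-peak curve (mid-season sub-type peaking in
  August, late sub-type in September) declining after the peak, NDVI below
  0.3 by November;
* other cropland vegetation — single spring peak, survives the phenology mask;
* forest/meadow — high NDVI year-round (November above 0.5);
* water — NDVI below 0.1 in every month;
* built-up land and bare soil — NDVI below 0.25 in every month.

The curve model is a sum of Gaussian bumps over month index on a constant
baseline, with an optional narrow negative bump forcing the inter-crop trough.
All numeric amplitudes are module defaults chosen to satisfy the qualitative
constraints above; they are not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MONTHS = np.arange(1, 13)

#: Classifier target classes.
RICE_CLASSES = ("single", "double", "regenerated", "other")

#: Background classes removed by the phenology mask.
BACKGROUND_CLASSES = ("forest_meadow", "water", "built_bare")

#: Per-class sample counts of the reference dataset the simulator emulates
#: (single / double / regenerated / other land cover), totalling 5404.
DEFAULT_CLASS_COUNTS = {
    "single": 2110,
    "double": 1057,
    "regenerated": 522,
    "other": 1715,
}

#: Provenance of the reference counts: ground points collected in an August
#: field survey, plus samples labelled by visual interpretation of
#: high-resolution imagery. Per class, field + interpretation equals
#: ``DEFAULT_CLASS_COUNTS``.
FIELD_SURVEY_COUNTS = {
    "single": 316, "double": 179, "regenerated": 115, "other": 162,
}
INTERPRETATION_COUNTS = {
    "single": 1794, "double": 878, "regenerated": 407, "other": 1553,
}

#: Width (months) of the Gaussian bumps of the default curves.
_PEAK_SIGMA = 0.8
#: Width of the narrow negative bump that carves the inter-crop trough.
_TROUGH_SIGMA = 0.5


@dataclass(frozen=True)
class PhenoClassParams:
    """Phenological curve parameters for one land-cover class.

    All NDVI quantities are unitless and must lie in [-1, 1]; for vegetated
    classes ``peak_ndvi > trough_ndvi > baseline_ndvi``.
    """

    class_id: str
    peak_months: tuple[int, ...]
    peak_ndvi: float
    baseline_ndvi: float
    trough_month: int | None = None
    trough_ndvi: float | None = None
    noise_sd: float = 0.03
    peak_sigma: float = _PEAK_SIGMA
    #: Classifier label this curve maps to ("single", ..., or a background id).
    label: str | None = None

    def __post_init__(self) -> None:
        for name, v in (
            ("peak_ndvi", self.peak_ndvi),
            ("baseline_ndvi", self.baseline_ndvi),
            ("trough_ndvi", self.trough_ndvi),
        ):
            if v is not None and not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(not 1 <= m <= 12 for m in self.peak_months):
            raise ValueError("peak months must be in 1..12")
        if (self.trough_month is None) != (self.trough_ndvi is None):
            raise ValueError("trough_month and trough_ndvi must be given together")

    def noiseless_curve(self) -> np.ndarray:
        """Return the 12-value noiseless monthly NDVI curve (January-December)."""
        curve = np.full(12, self.baseline_ndvi, dtype=float)
        amp = self.peak_ndvi - self.baseline_ndvi
        for p in self.peak_months:
            curve += amp * np.exp(-((MONTHS - p) ** 2) / (2 * self.peak_sigma**2))
        if self.trough_month is not None:
            dip = curve[self.trough_month - 1] - self.trough_ndvi
            curve -= dip * np.exp(
                -((MONTHS - self.trough_month) ** 2) / (2 * _TROUGH_SIGMA**2)
            )
        return np.clip(curve, -1.0, 1.0)


@dataclass(frozen=True)
class SyntheticDataset:
    """Labelled synthetic NDVI samples.

    ``samples`` is a DataFrame with columns ``pixel_id``, ``m01`` .. ``m12``
    and ``label``; reproducible for a fixed seed and parameter set.
    """

    samples: pd.DataFrame
    seed: int
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def features(self) -> np.ndarray:
        return self.samples[[f"m{m:02d}" for m in range(1, 13)]].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.samples["label"].to_numpy()


def default_pheno_params() -> dict[str, PhenoClassParams]:
    """Default curve parameters for every simulated class.

    The returned curves, evaluated without noise, satisfy the threshold
    constraints the phenology decision tree relies on: rice November NDVI
    below 0.3, forest/meadow November NDVI above 0.5, water below 0.1 in all
    months, built/bare below 0.25 in all months, and the stated peak/trough
    months of the three rice patterns.
    """
    return {
        "double": PhenoClassParams(
            "double", (6, 9), 0.85, 0.15, trough_month=7, trough_ndvi=0.45,
            label="double",
        ),
        "regenerated": PhenoClassParams(
            "regenerated", (7, 9), 0.80, 0.15, trough_month=8, trough_ndvi=0.45,
            label="regenerated",
        ),
        "single_mid": PhenoClassParams(
            "single_mid", (8,), 0.85, 0.15, label="single",
        ),
        "single_late": PhenoClassParams(
            "single_late", (9,), 0.85, 0.15, label="single",
        ),
        "other_crop": PhenoClassParams(
            "other_crop", (5,), 0.75, 0.20, peak_sigma=1.2, label="other",
        ),
        "forest_meadow": PhenoClassParams(
            "forest_meadow", (7,), 0.85, 0.55, peak_sigma=2.5,
            label="forest_meadow",
        ),
        "water": PhenoClassParams("water", (), 0.05, 0.05, label="water"),
        "built_bare": PhenoClassParams(
            "built_bare", (), 0.18, 0.18, label="built_bare",
        ),
    }


# Sub-type mixture used when a classifier label is requested rather than a
# curve id: single-cropping rice is an equal mixture of its mid-season and
# late sub-types.
_LABEL_TO_CURVES = {
    "single": ("single_mid", "single_late"),
    "double": ("double",),
    "regenerated": ("regenerated",),
    "other": ("other_crop",),
    "forest_meadow": ("forest_meadow",),
    "water": ("water",),
    "built_bare": ("built_bare",),
}


def curves_for_label(label: str) -> tuple[str, ...]:
    """Curve ids generated for a classifier/background label."""
    try:
        return _LABEL_TO_CURVES[label]
    except KeyError:
        raise ValueError(f"unknown class label: {label!r}") from None


def simulate_samples(
    n_per_class: dict[str, int] | None = None,
    params: dict[str, PhenoClassParams] | None = None,
    noise_sd: float | None = None,
    seed: int = 1,
) -> SyntheticDataset:
    """Draw labelled 12-month NDVI samples.

    Parameters
    ----------
    n_per_class
        Samples per classifier label (keys from ``RICE_CLASSES`` or
        ``BACKGROUND_CLASSES``). Defaults to the reference-dataset counts
        ``DEFAULT_CLASS_COUNTS``.
    params
        Curve parameters per curve id; defaults to ``default_pheno_params``.
    noise_sd
        Overrides every class's Gaussian noise standard deviation when given.
    seed
        Seed for the random generator; fixed seed gives identical output.
    """
    if n_per_class is None:
        n_per_class = dict(DEFAULT_CLASS_COUNTS)
    if params is None:
        params = default_pheno_params()
    if any(n < 0 for n in n_per_class.values()):
        raise ValueError("sample counts must be >= 0")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    labels: list[str] = []
    for label in sorted(n_per_class):
        n = n_per_class[label]
        curve_ids = curves_for_label(label)
        for cid in curve_ids:
            if cid not in params:
                raise ValueError(f"no parameters for curve {cid!r}")
        # deterministic near-equal split across sub-types
        sizes = [n // len(curve_ids)] * len(curve_ids)
        sizes[0] += n - sum(sizes)
        for cid, size in zip(curve_ids, sizes):
            p = params[cid]
            sd = p.noise_sd if noise_sd is None else noise_sd
            base = p.noiseless_curve()
            noise = (rng.normal(0.0, sd, size=(size, 12)) if sd > 0
                     else np.zeros((size, 12)))
            rows.append(np.clip(base + noise, -1.0, 1.0))
            labels.extend([label] * size)
    feats = np.vstack(rows) if rows else np.empty((0, 12))
    df = pd.DataFrame(feats, columns=[f"m{m:02d}" for m in range(1, 13)])
    df.insert(0, "pixel_id", np.arange(len(df)))
    df["label"] = labels
    return SyntheticDataset(samples=df, seed=seed, class_counts=dict(n_per_class))


def block_layout(width: int, height: int, class_ids: list[str]) -> np.ndarray:
    """Split a height x width grid into horizontal bands, one per class."""
    if width <= 0 or height <= 0:
        raise ValueError("scene dimensions must be positive")
    if not class_ids:
        raise ValueError("at least one class required")
    edges = np.linspace(0, height, len(class_ids) + 1).astype(int)
    layout = np.empty((height, width), dtype=object)
    for cid, lo, hi in zip(class_ids, edges[:-1], edges[1:]):
        layout[lo:hi, :] = cid
    return layout


def simulate_scene(
    layout: np.ndarray,
    params: dict[str, PhenoClassParams] | None = None,
    noise_sd: float | None = None,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a 12-month NDVI raster stack plus a ground-truth label raster.

    ``layout`` is a 2-D array of classifier/background labels assigning one
    class to each pixel. Returns ``(stack, truth)`` where ``stack`` has shape
    ``(12, H, W)`` and ``truth`` is the ``(H, W)`` label array (object dtype).
    """
    layout = np.asarray(layout, dtype=object)
    if layout.ndim != 2 or layout.size == 0:
        raise ValueError("layout must be a non-empty 2-D array")
    h, w = layout.shape
    uniq = sorted({str(v) for v in layout.ravel()})
    counts = {lab: int(np.sum(layout == lab)) for lab in uniq}
    ds = simulate_samples(counts, params=params, noise_sd=noise_sd, seed=seed)
    stack = np.empty((12, h, w), dtype=float)
    by_label = {lab: ds.features[ds.labels == lab] for lab in uniq}
    cursor = {lab: 0 for lab in uniq}
    flat = layout.ravel()
    series = np.empty((h * w, 12), dtype=float)
    for i, lab in enumerate(flat):
        k = cursor[lab]
        series[i] = by_label[lab][k]
        cursor[lab] = k + 1
    stack[:] = series.T.reshape(12, h, w)
    return stack, layout.copy()
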