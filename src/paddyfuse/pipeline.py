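"""End-to-end pipeline: composite -> mask -> train -> classify -> fuse -> evaluate.

`run_pipeline` wires every stage together under one validated configuration
and writes all artifacts (composite, mask raster, per-model maps, fused map,
metric report, area table) plus a manifest recording inputs, seeds and
package version. When no real scene or sample inputs are configured, the
synthetic phenology simulator supplies both, which makes the full chain
runnable and reproducible with no external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, phenosim, raster
from .classify import (
    CLASS_CODES,
    CLASS_ORDER,
    MODEL_ORDER,
    BaseModelSpec,
    predict,
    predict_raster,
    split_samples,
    train_model,
    validate_model,
)
from .fuse import fuse_map
from .mask import MASK_CODES, MaskThresholds, mask_raster
from .metrics import build_confusion, improvement_range, metric_report
from .analysis import tabulate_areas

logger = logging.getLogger(__name__)

#: Legend of the final fused map: masked background classes are reported
#: under "other", candidate pixels under their rice class.
FINAL_LEGEND = dict(CLASS_CODES)


class StageError(RuntimeError):
    """Failure tagged with the pipeline stage it occurred in."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, seeds included."""

    out_dir: str = "artifacts"
    samples_csv: str | None = None       # None -> simulate
    scene_stack: str | None = None       # 12-band composite TIFF; None -> simulate
    seed: int = 1
    split_ratio: float = 0.7
    split_seed: int = 1
    stratify: bool = False
    models: tuple[str, ...] = MODEL_ORDER
    hyperparameters: dict = field(default_factory=dict)
    mask_thresholds: dict = field(default_factory=dict)
    apply_mask: bool = True
    n_per_class: dict = field(default_factory=lambda: dict(phenosim.DEFAULT_CLASS_COUNTS))
    noise_sd: float | None = None
    scene_size: tuple[int, int] = (24, 24)
    pixel_area_ha: float = 0.01
    weights_file: str | None = None      # precomputed fusion weights (JSON)

    def validate(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise StageError("config", "split_ratio must be in (0, 1)")
        bad = [m for m in self.models if m not in MODEL_ORDER]
        if bad:
            raise StageError("config", f"unknown models {bad}")
        if not self.models:
            raise StageError("config", "at least one model required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise StageError("config", f"unknown config keys {sorted(bad)}")
        cfg = cls(**raw)
        cfg.models = tuple(cfg.models)
        cfg.scene_size = tuple(cfg.scene_size)
        cfg.validate()
        return cfg


def _load_samples(cfg: PipelineConfig) -> pd.DataFrame:
    if cfg.samples_csv:
        try:
            return raster.read_samples(cfg.samples_csv)
        except (OSError, ValueError) as e:
            raise StageError("samples", str(e)) from e
    ds = phenosim.simulate_samples(
        cfg.n_per_class, noise_sd=cfg.noise_sd, seed=cfg.seed)
    return ds.samples


def _load_stack(cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray | None]:
    if cfg.scene_stack:
        try:
            stack = raster.read_raster(cfg.scene_stack).astype(float)
        except (OSError, ValueError) as e:
            raise StageError("composite", str(e)) from e
        if stack.ndim != 3 or stack.shape[0] != 12:
            raise StageError("composite", "scene stack must be (12, H, W)")
        return stack, None
    h, w = cfg.scene_size
    layout = phenosim.block_layout(
        w, h, ["single", "double", "regenerated", "other",
               "forest_meadow", "water", "built_bare"])
    stack, truth = phenosim.simulate_scene(
        layout, noise_sd=cfg.noise_sd, seed=cfg.seed + 1)
    return stack, truth


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full mapping chain; returns a result summary dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "stages": [],
    }

    # --- samples, split, train, validate -----------------------------------
    samples = _load_samples(cfg)
    train, val = split_samples(samples, cfg.split_ratio, cfg.split_seed,
                               cfg.stratify)
    labelled = samples.copy()
    labelled["split"] = np.where(labelled.index.isin(train.index),
                                 "train", "validation")
    raster.write_samples(out / "samples.csv", labelled)
    manifest["stages"].append({"stage": "split",
                               "n_train": len(train), "n_val": len(val)})

    fitted, weights, reports = {}, {}, {}
    for mid in cfg.models:
        try:
            spec = BaseModelSpec(mid, cfg.hyperparameters.get(mid, {}))
            model = validate_model(train_model(spec, train), val, CLASS_ORDER)
        except Exception as e:
            raise StageError("train", f"{mid}: {e}") from e
        fitted[mid] = model
        weights[mid] = model.validation_oa
        reports[mid] = metric_report(model.validation_confusion)
    if cfg.weights_file:
        weights = raster.read_weights(cfg.weights_file)
    raster.write_weights(out / "weights.json", weights)

    # --- fused validation predictions --------------------------------------
    feats = val[[f"m{m:02d}" for m in range(1, 13)]].to_numpy(dtype=float)
    votes = {mid: predict(fitted[mid], feats) for mid in cfg.models}
    from .fuse import fuse_pixel
    fused_pred = np.array([
        fuse_pixel({m: str(votes[m][i]) for m in cfg.models}, weights,
                   classes=CLASS_ORDER, model_order=tuple(cfg.models))[0]
        for i in range(len(val))
    ], dtype=object)
    fused_cm = build_confusion(val["label"].to_numpy(), fused_pred, CLASS_ORDER)
    reports["fused"] = metric_report(fused_cm)

    report_rows = []
    for name, rep in reports.items():
        row = {"method": name, "oa_pct": round(rep.oa, 2),
               "kappa": round(rep.kappa, 3)}
        row.update({f"ua_{c}_pct": round(rep.ua[c], 2) for c in CLASS_ORDER})
        row.update({f"ma_{c}_pct": round(rep.ma[c], 2) for c in CLASS_ORDER})
        report_rows.append(row)
    report_df = pd.DataFrame(report_rows)
    report_df.to_csv(out / "metrics.csv", index=False)
    individual = {m: reports[m] for m in cfg.models}
    summary_improvement = {
        "oa": improvement_range(reports["fused"].oa,
                                {m: r.oa for m, r in individual.items()}),
        "kappa": improvement_range(reports["fused"].kappa,
                                   {m: r.kappa for m, r in individual.items()}),
        "ua": improvement_range(reports["fused"].ua,
                                {m: r.ua for m, r in individual.items()},
                                paired_by_class=True),
        "ma": improvement_range(reports["fused"].ma,
                                {m: r.ma for m, r in individual.items()},
                                paired_by_class=True),
    }
    manifest["stages"].append({"stage": "evaluate",
                               "weights": weights,
                               "fused_oa": reports["fused"].oa})

    # --- raster chain: composite -> mask -> classify -> fuse ---------------
    stack, truth = _load_stack(cfg)
    raster.write_composite(out / "composite.tif", stack)
    if cfg.apply_mask:
        thresholds = MaskThresholds(**cfg.mask_thresholds)
        codes, candidate = mask_raster(stack, thresholds)
    else:
        codes = np.zeros(stack.shape[1:], dtype=np.uint8)
        candidate = np.ones(stack.shape[1:], dtype=bool)
    raster.write_raster(out / "mask.tif", codes)

    model_maps = {}
    for mid in cfg.models:
        amap = predict_raster(fitted[mid], stack, candidate)
        model_maps[mid] = amap
        raster.write_raster(out / f"map_{mid}.tif", amap)
    fused_raster = fuse_map(model_maps, weights, CLASS_CODES,
                            model_order=tuple(cfg.models))
    raster.write_raster(out / "map_fused.tif", fused_raster)
    # final legend folds every masked background class into "other"
    final = fused_raster.copy()
    final[(codes != MASK_CODES["candidate"])
          & (codes != MASK_CODES["unclassifiable"])] = FINAL_LEGEND["other"]
    raster.write_raster(out / "map_final.tif", final)

    areas = tabulate_areas(final, FINAL_LEGEND, pixel_area_ha=cfg.pixel_area_ha)
    areas.to_csv(out / "areas.csv", index=False)
    manifest["stages"].append(
        {"stage": "map", "shape": list(stack.shape[1:]),
         "n_candidate": int(candidate.sum())})

    result = {
        "weights": weights,
        "reports": {k: asdict(v) for k, v in reports.items()},
        "improvement": summary_improvement,
        "out_dir": str(out),
    }
    if truth is not None:
        truth_codes = np.array(
            [[FINAL_LEGEND.get(str(t), FINAL_LEGEND["other"])
              for t in row] for row in truth])
        result["map_accuracy_vs_truth"] = float(
            100.0 * np.mean(final == truth_codes))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "summary.json").write_text(
        json.dumps(result, indent=2, default=float) + "\n")
    return result
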