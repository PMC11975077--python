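"""Base classifiers on 12-month NDVI feature vectors.

Four learners are trained on the monthly NDVI series of labelled samples:
k-nearest neighbours (KNN), random forest (RF), a support-vector machine with
RBF kernel (SVM), and gradient-boosted decision trees (GBDT). Hyperparameters
default to the tuned operating points used for the Poyang Lake mapping; they
are plain keyword arguments and can be overridden. Distance- and kernel-based
learners (KNN, SVM) receive standardized features through a pipeline; tree
ensembles use the raw NDVI values.

Samples are split 7:3 into training and validation sets; each fitted model
records its validation Overall Accuracy, which downstream fusion uses as the
model's vote weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import ConfusionMatrix, build_confusion, overall_accuracy

CLASS_ORDER = ("single", "double", "regenerated", "other")
MODEL_ORDER = ("knn", "rf", "svm", "gbdt")

#: Integer legend of classified rasters.
CLASS_CODES = {"single": 1, "double": 2, "regenerated": 3, "other": 4}

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "knn": dict(n_neighbors=7, weights="uniform", metric="minkowski", p=2,
                algorithm="auto", leaf_size=50),
    "rf": dict(n_estimators=500, max_depth=5, max_features=None,
               random_state=1),
    "svm": dict(kernel="rbf", gamma=0.8, C=0.95,
                decision_function_shape="ovr"),
    "gbdt": dict(n_estimators=500, learning_rate=0.1, max_depth=3,
                 random_state=1),
}

_SCALED_MODELS = {"knn", "svm"}


@dataclass(frozen=True)
class BaseModelSpec:
    """One base classifier: its id and hyperparameters."""

    model_id: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(
                f"unknown model_id {self.model_id!r}; "
                f"expected one of {MODEL_ORDER}")

    def resolved(self) -> dict:
        hp = dict(DEFAULT_HYPERPARAMETERS[self.model_id])
        hp.update(self.hyperparameters)
        return hp


@dataclass
class FittedModel:
    """A trained base classifier plus its validation scorecard."""

    model_id: str
    estimator: Pipeline
    classes_seen: tuple[str, ...]
    validation_oa: float | None = None
    validation_confusion: ConfusionMatrix | None = None


def default_model_specs(models: tuple[str, ...] = MODEL_ORDER) -> list[BaseModelSpec]:
    return [BaseModelSpec(m) for m in models]


def split_samples(
    samples: pd.DataFrame,
    ratio: float = 0.7,
    seed: int = 1,
    stratify: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly partition samples into training and validation sets.

    The training set holds ``floor(ratio * N)`` samples (7:3 by default).
    Simple random by default; ``stratify=True`` splits each class
    independently at the same ratio. Deterministic for a fixed seed.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list[np.ndarray] = []
        for _, grp in samples.groupby("label", sort=True):
            perm = grp.index.to_numpy()[rng.permutation(len(grp))]
            train_idx.append(perm[: int(np.floor(ratio * len(grp)))])
        tr = np.concatenate(train_idx)
        train = samples.loc[np.sort(tr)]
        val = samples.drop(index=tr).sort_index()
    else:
        perm = samples.index.to_numpy()[rng.permutation(n)]
        n_train = int(np.floor(ratio * n))
        train = samples.loc[np.sort(perm[:n_train])]
        val = samples.loc[np.sort(perm[n_train:])]
    missing = set(samples["label"].unique()) - set(train["label"].unique())
    if missing:
        warnings.warn(
            f"classes absent from training split: {sorted(missing)}; "
            "models cannot predict them", stacklevel=2)
    return train, val


def _make_estimator(spec: BaseModelSpec) -> Pipeline:
    hp = spec.resolved()
    base = {
        "knn": KNeighborsClassifier,
        "rf": RandomForestClassifier,
        "svm": SVC,
        "gbdt": GradientBoostingClassifier,
    }[spec.model_id](**hp)
    steps = []
    if spec.model_id in _SCALED_MODELS:
        steps.append(("scale", StandardScaler()))
    steps.append(("model", base))
    return Pipeline(steps)


def _features(df: pd.DataFrame) -> np.ndarray:
    cols = [f"m{m:02d}" for m in range(1, 13)]
    return df[cols].to_numpy(dtype=float)


def train_model(spec: BaseModelSpec, train: pd.DataFrame) -> FittedModel:
    """Fit one base classifier on the training split."""
    if len(train) == 0:
        raise ValueError("empty training set")
    X, y = _features(train), train["label"].to_numpy()
    classes = tuple(sorted(set(y)))
    if len(classes) == 1:
        warnings.warn(
            f"single-class training set ({classes[0]!r}); model will predict "
            "only that class", stacklevel=2)
    est = _make_estimator(spec)
    est.fit(X, y)
    return FittedModel(spec.model_id, est, classes)


def validate_model(
    model: FittedModel,
    validation: pd.DataFrame,
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> FittedModel:
    """Score a fitted model on the validation split.

    Fills ``validation_confusion`` and ``validation_oa`` (percent) in place
    and returns the model.
    """
    pred = predict(model, _features(validation))
    cm = build_confusion(validation["label"].to_numpy(), pred, class_order)
    model.validation_confusion = cm
    model.validation_oa = overall_accuracy(cm)
    return model


def predict(model: FittedModel, features: np.ndarray) -> np.ndarray:
    """Predict class labels for an (n, 12) feature array."""
    X = np.asarray(features, dtype=float)
    if X.size == 0:
        return np.empty(0, dtype=object)
    if X.ndim != 2 or X.shape[1] != 12:
        raise ValueError("features must have shape (n, 12)")
    return model.estimator.predict(X)


def predict_raster(
    model: FittedModel, composite: np.ndarray, candidate: np.ndarray
) -> np.ndarray:
    """Classify the candidate pixels of a (12, H, W) composite.

    Returns an (H, W) uint8 raster with ``CLASS_CODES`` on candidate pixels
    and 0 elsewhere. Candidate pixels with any missing month are skipped
    (left 0) and counted.
    """
    comp = np.asarray(composite, dtype=float)
    cand = np.asarray(candidate, dtype=bool)
    feats = comp.reshape(12, -1).T
    sel = cand.ravel() & np.all(np.isfinite(feats), axis=1)
    n_skipped = int(np.count_nonzero(cand.ravel()) - np.count_nonzero(sel))
    if n_skipped:
        warnings.warn(f"{n_skipped} candidate pixels with missing months "
                      "skipped", stacklevel=2)
    out = np.zeros(feats.shape[0], dtype=np.uint8)
    if sel.any():
        labels = predict(model, feats[sel])
        out[sel] = [CLASS_CODES[str(l)] for l in labels]
    return out.reshape(cand.shape)
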