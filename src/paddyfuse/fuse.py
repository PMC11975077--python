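"""Accuracy-weighted scoring fusion of base-classifier votes.

Each base classifier votes one class per pixel. Its validation Overall
Accuracy serves as the weight of that vote. Per pixel, the weights of models
voting the same class are summed into the class's comprehensive score, and
the class with the highest score wins. With validation accuracies 85, 87, 89
and 90 and votes Type1/Type1/Type1/Type2, Type1 scores 85+87+89+0 = 261,
Type2 scores 90, and Type1 is the fused label.

Scores are invariant to a common rescaling of the weights (percent vs
fraction); with equal weights the rule reduces to plurality voting. Ties on
the comprehensive score go to the class voted by the single highest-weight
model among the tied classes, then to fixed model registration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FusionScoreboard:
    """Per-class comprehensive scores for one pixel."""

    scores: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.scores.values())


def fuse_pixel(
    votes: dict[str, str],
    weights: dict[str, float],
    classes: tuple[str, ...] | None = None,
    model_order: tuple[str, ...] | None = None,
) -> tuple[str, FusionScoreboard]:
    """Fuse one pixel's votes into a final label.

    Parameters
    ----------
    votes
        ``model_id -> predicted class``; at least one vote.
    weights
        ``model_id -> vote weight`` (validation Overall Accuracy); every
        voting model must have a weight.
    classes
        Class universe for the scoreboard; defaults to the voted classes.
        Classes receiving no vote score 0.
    model_order
        Registration order used as the final tie-break; defaults to the
        sorted model ids.

    Returns the fused class label and the full scoreboard.
    """
    if not votes:
        raise ValueError("at least one vote required")
    missing = [m for m in votes if m not in weights]
    if missing:
        raise ValueError(f"no weight for voting model(s): {missing}")
    if model_order is None:
        model_order = tuple(sorted(votes))
    if classes is None:
        classes = tuple(dict.fromkeys(votes[m] for m in votes))
    scores = {c: 0.0 for c in classes}
    for m, c in votes.items():
        if c not in scores:
            raise ValueError(f"vote {c!r} outside class set {classes}")
        scores[c] += float(weights[m])

    top = max(scores.values())
    tied = [c for c, s in scores.items() if s == top]
    if len(tied) == 1:
        return tied[0], FusionScoreboard(scores)
    # tie-break 1: class voted by the highest-weight model among tied classes;
    # tie-break 2: fixed model registration order
    ranked = sorted(
        (m for m in votes if votes[m] in tied),
        key=lambda m: (-float(weights[m]),
                       model_order.index(m) if m in model_order else len(model_order)),
    )
    return votes[ranked[0]], FusionScoreboard(scores)


def fuse_map(
    model_maps: dict[str, np.ndarray],
    weights: dict[str, float],
    legend: dict[str, int],
    mask_codes: np.ndarray | None = None,
    model_order: tuple[str, ...] | None = None,
    return_scores: bool = False,
):
    """Fuse co-registered classified rasters into one map.

    ``model_maps`` holds each model's (H, W) uint raster using ``legend``
    codes, with 0 for unclassified pixels. Pixels classified by no model stay
    0; where ``mask_codes`` is given, its non-candidate codes are carried
    through on those pixels. Optionally returns per-class score rasters.
    """
    if not model_maps:
        raise ValueError("at least one model map required")
    shapes = {m.shape for m in model_maps.values()}
    if len(shapes) != 1:
        raise ValueError(f"raster shape mismatch: {shapes}")
    missing = [m for m in model_maps if m not in weights]
    if missing:
        raise ValueError(f"no weight for model(s): {missing}")
    shape = shapes.pop()
    if model_order is None:
        model_order = tuple(sorted(model_maps))

    classes = list(legend)
    codes = np.array([legend[c] for c in classes])
    score = np.zeros((len(classes),) + shape)
    for m in model_order:
        amap = model_maps[m]
        for k, code in enumerate(codes):
            score[k][amap == code] += float(weights[m])

    voted = score.sum(axis=0) > 0
    best = np.argmax(score, axis=0)
    top = np.take_along_axis(score, best[None], axis=0)[0]
    n_tied = (score == top[None]).sum(axis=0)

    fused = np.zeros(shape, dtype=np.uint8)
    fused[voted] = codes[best[voted]]
    # resolve score ties pixel-wise with the fuse_pixel rule
    for i, j in zip(*np.nonzero(voted & (n_tied > 1))):
        votes = {
            m: classes[int(np.nonzero(codes == model_maps[m][i, j])[0][0])]
            for m in model_maps if model_maps[m][i, j] != 0
        }
        label, _ = fuse_pixel(votes, weights, classes=tuple(classes),
                              model_order=model_order)
        fused[i, j] = legend[label]
    if mask_codes is not None:
        keep = ~voted & (mask_codes != 0)
        fused[keep] = mask_codes[keep]
    if return_scores:
        return fused, {c: score[k] for k, c in enumerate(classes)}
    return fused
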