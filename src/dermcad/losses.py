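"""Losses and evaluation metrics for the two-stage pipeline.

This module provides the numpy reference forms used for evaluation and
testing; the training loops use the equivalent differentiable ops in
:mod:`dermcad.nn.engine`.

* :func:`softmax_map` — per-pixel softmax over class activations.
* :func:`weighted_cross_entropy` — boundary-weighted pixel-wise
  cross-entropy.  (The source formula is printed without a minus sign;
  the value returned here is negated so it is a loss to minimise.)
* :func:`bce_dice_loss` — the deep-supervision loss combining a binary
  cross-entropy dot product with a dice ratio over each flattened image.
  The printed form lacks the background term of standard BCE and halves
  the foreground term; it is implemented verbatim by default, with
  ``variant="standard"`` giving the conventional ``0.5*BCE - soft_dice``
  reading.
* :func:`dice_coefficient` — the overlap score
  ``100 * 2|P∩G| / (|P| + |G|)`` used to grade predicted masks.
* :func:`dice_distribution_report` — the per-dataset summary binning
  dice percentages into [90,100], [80,90), [70,80), [0,70).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "softmax_map",
    "weighted_cross_entropy",
    "bce_dice_loss",
    "dice_coefficient",
    "DiceReport",
    "dice_distribution_report",
]

LOG_EPS = 1e-12
DICE_EPS = 1e-6


def softmax_map(acts: np.ndarray) -> np.ndarray:
    """Per-pixel softmax of an H x W x K activation stack.

    Numerically stabilised by max subtraction, which does not change
    the value (the softmax is shift-invariant).
    """
    acts = np.asarray(acts, dtype=np.float64)
    if acts.ndim != 3 or acts.shape[2] < 2:
        raise ValueError(f"expected HxWxK activations with K >= 2, got {acts.shape}")
    z = acts - acts.max(axis=2, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=2, keepdims=True)


def weighted_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                           weights: np.ndarray) -> float:
    """Weighted pixel-wise cross-entropy: ``-sum_x w(x) log p_true(x)``.

    ``labels`` holds 0-based class indices; ``weights`` is the weight
    map.  Probabilities are clamped at 1e-12 before the log.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    weights = np.asarray(weights, dtype=np.float64)
    if probs.shape[:2] != labels.shape or labels.shape != weights.shape:
        raise ValueError("probs, labels and weights must agree spatially")
    pt = np.take_along_axis(probs, labels[..., None], axis=2)[..., 0]
    return float(-(weights * np.log(np.maximum(pt, LOG_EPS))).sum())


def _flatten_batch(y) -> list[np.ndarray]:
    if isinstance(y, np.ndarray) and y.ndim == 2:
        return [row for row in y]
    return [np.asarray(v).ravel() for v in y]


def bce_dice_loss(y_true, y_pred, variant: str = "printed",
                  eps: float = DICE_EPS) -> float:
    """Combined binary-cross-entropy + dice loss over a batch.

    ``y_true`` and ``y_pred`` are per-image flattened ground truths in
    {0,1} and predicted probabilities in [0,1] (lists of vectors or an
    (N, M) array).  With ``variant="printed"`` the per-image term is

        0.5 * Y·log(Ŷ)  +  2 * Y·Ŷ / (sum(Y) + sum(Ŷ) + eps)

    and the loss is the negated batch mean, so lower is better and a
    perfect all-foreground prediction attains -1 for the dice part.
    ``variant="standard"`` uses the conventional full BCE (mean over
    pixels, with background term) minus the soft dice ratio.
    """
    ys = _flatten_batch(y_true)
    ps = _flatten_batch(y_pred)
    if len(ys) != len(ps):
        raise ValueError("batch sizes differ")
    if not ys:
        raise ValueError("empty batch")
    total = 0.0
    for y, p in zip(ys, ps):
        if y.shape != p.shape:
            raise ValueError("flattened image sizes differ")
        y = y.astype(np.float64)
        p = np.asarray(p, dtype=np.float64)
        pc = np.clip(p, LOG_EPS, 1.0)
        dice = 2.0 * float(y @ p) / (float(y.sum() + p.sum()) + eps)
        if variant == "printed":
            total += 0.5 * float(y @ np.log(pc)) + dice
        elif variant == "standard":
            pc1 = np.clip(1.0 - p, LOG_EPS, 1.0)
            bce = float(-(y * np.log(pc) + (1 - y) * np.log(pc1)).mean())
            total += -(0.5 * bce - dice)
        else:
            raise ValueError(f"unknown variant {variant!r}")
    return -total / len(ys)


def dice_coefficient(P: np.ndarray, G: np.ndarray) -> float:
    """Dice similarity between two binary masks, as a percentage.

    ``100 * 2|P∩G| / (|P| + |G|)``; 100 means perfect agreement.  Two
    empty masks agree perfectly by convention (100).
    """
    P = np.asarray(P)
    G = np.asarray(G)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {G.shape}")
    for m, name in ((P, "P"), (G, "G")):
        if not np.all(np.isin(np.unique(m), (0, 1))):
            raise ValueError(f"{name} must be binary")
    inter = int(np.logical_and(P, G).sum())
    size = int(P.sum()) + int(G.sum())
    if size == 0:
        return 100.0
    return 100.0 * 2.0 * inter / size


@dataclass
class DiceReport:
    """Per-image dice percentages plus the four-bin distribution."""

    per_image: list[float]
    bins: tuple[float, float, float, float]  # [>=90, 80-90, 70-80, <70]
    mean: float = field(default=0.0)
    max: float = field(default=0.0)
    min: float = field(default=0.0)

    BIN_LABELS = (">=90", "80-90", "70-80", "<70")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "per_image": self.per_image,
            "bins": dict(zip(self.BIN_LABELS, self.bins)),
            "mean": self.mean, "max": self.max, "min": self.min,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"dice_percent": self.per_image}).to_csv(path, index_label="image")
        binpath = Path(path).with_name(Path(path).stem + "_bins.csv")
        pd.DataFrame({"bin": self.BIN_LABELS, "fraction": self.bins}).to_csv(
            binpath, index=False)


def dice_distribution_report(values) -> DiceReport:
    """Summarise a list of dice percentages.

    Bin fractions are over the disjoint ranges [90, 100], [80, 90),
    [70, 80) and [0, 70); they sum to 1.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("empty dice list")
    arr = np.asarray(vals)
    if arr.min() < 0 or arr.max() > 100:
        raise ValueError("dice values must lie in [0, 100]")
    n = len(vals)
    bins = (
        float((arr >= 90).sum()) / n,
        float(((arr >= 80) & (arr < 90)).sum()) / n,
        float(((arr >= 70) & (arr < 80)).sum()) / n,
        float((arr < 70).sum()) / n,
    )
    return DiceReport(per_image=vals, bins=bins, mean=float(arr.mean()),
                      max=float(arr.max()), min=float(arr.min()))
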