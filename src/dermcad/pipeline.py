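"""End-to-end training, inference and evaluation of the two-stage CAD.

Stage one segments the lesion: the RGB image is normalised, mirror-
padded to the network input size and passed through the segmentation
network; the two-class softmax output is thresholded into a binary
mask.  Stage two multiplies the mask into the RGB image (zeroing the
background) and classifies the extracted lesion as malignant or benign
with the CNN.

Training utilities accept lists of :class:`~dermcad.synthetic.Scene`
objects or plain ``(image, mask)`` / ``(image, label)`` pairs, so the
synthetic generator and a real-data manifest are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .config import ClassifierConfig, SegNetConfig, TrainConfig
from .losses import DICE_EPS, LOG_EPS, DiceReport, dice_coefficient, \
    dice_distribution_report
from .models import LesionClassifier, NestedUNet, SizeError, build_classifier, \
    build_unet, output_side
from .nn import engine
from .preprocess import binarize_mask, center_crop, normalize_image, pad_symmetric, \
    pad_zero
from .weightmap import weight_map

__all__ = [
    "TrainingHistory",
    "CadResult",
    "split_dataset",
    "fit_margin",
    "prepare_segmentation_data",
    "train_segmenter",
    "predict_mask",
    "extract_lesion",
    "train_classifier",
    "classify_lesion",
    "run_cad",
    "segmentation_report",
]


@dataclass
class TrainingHistory:
    """Per-epoch loss and accuracy for the train and validation streams."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self) + 1),
            "train_loss": self.train_loss, "train_acc": self.train_acc,
            "val_loss": self.val_loss, "val_acc": self.val_acc,
        })


@dataclass
class CadResult:
    """Structured output of the full two-stage pipeline for one image."""

    mask: np.ndarray
    lesion: np.ndarray
    label: str
    probability: float          # probability of the malignant class
    dice: float | None = None   # vs. ground truth, when supplied


# --------------------------------------------------------------------------
# dataset handling
# --------------------------------------------------------------------------

def split_dataset(manifest, n_train: int, seed: int):
    """Deterministic shuffled split into (train, validation).

    ``manifest`` may be a pandas DataFrame or any sequence; the split
    is disjoint with ``len(train) == n_train``."""
    n = len(manifest)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    order = np.random.default_rng(seed).permutation(n)
    tr_idx, va_idx = order[:n_train], order[n_train:]
    if isinstance(manifest, pd.DataFrame):
        return (manifest.iloc[tr_idx].reset_index(drop=True),
                manifest.iloc[va_idx].reset_index(drop=True))
    items = list(manifest)
    return [items[i] for i in tr_idx], [items[i] for i in va_idx]


def _unpack_seg(items):
    pairs = []
    for it in items:
        if hasattr(it, "image") and hasattr(it, "mask"):
            pairs.append((it.image, it.mask))
        else:
            pairs.append((it[0], it[1]))
    return pairs


def _unpack_clf(items):
    pairs = []
    for it in items:
        if hasattr(it, "image") and hasattr(it, "label"):
            pairs.append((it.image, it.label))
        else:
            pairs.append((it[0], it[1]))
    return pairs


def fit_margin(cfg: SegNetConfig, canvas_side: int) -> int:
    """Mirror-padding margin for which the network output matches the
    working resolution (21 for the default valid-mode architecture at
    canvas 128)."""
    if cfg.padding_mode == "same":
        return 0
    best = None
    for margin in range(0, canvas_side):
        try:
            if output_side(cfg, canvas_side + 2 * margin) == canvas_side:
                best = margin  # keep the largest margin: maximal mirror context
        except SizeError:
            continue
    if best is None:
        raise SizeError(f"no padding margin maps a {canvas_side} canvas onto itself")
    return best


def prepare_segmentation_data(items, net_cfg: SegNetConfig,
                              train_cfg: TrainConfig | None = None):
    """Assemble network-ready arrays from (image, mask) pairs.

    Images are normalised and mirror-padded to the network input side;
    mask targets are zero-padded and centre-aligned with the output
    grid; per-pixel weight maps are computed from the targets."""
    train_cfg = train_cfg or TrainConfig()
    pairs = _unpack_seg(items)
    canvas = pairs[0][0].shape[0]
    margin = fit_margin(net_cfg, canvas)
    in_side = canvas + 2 * margin
    out_side = output_side(net_cfg, in_side) if net_cfg.padding_mode == "valid" \
        else canvas
    X, Y, W = [], [], []
    for img, mask in pairs:
        xim = pad_symmetric(normalize_image(img), margin) if margin else \
            normalize_image(img)
        X.append(xim.transpose(2, 0, 1))
        target = center_crop(pad_zero(mask, margin), out_side) if margin else \
            center_crop(mask, out_side)
        Y.append(target)
        W.append(weight_map(target, train_cfg.omega0, train_cfg.sigma).weights)
    return (np.asarray(X, dtype=np.float32), np.asarray(Y, dtype=np.int64),
            np.asarray(W, dtype=np.float32))


# --------------------------------------------------------------------------
# graph-side deep-supervision loss
# --------------------------------------------------------------------------

def _bce_dice_graph(logits, targets: np.ndarray, variant: str = "printed"):
    """Differentiable BCE+dice loss on (N, 2, h, w) logits.

    Mirrors :func:`dermcad.losses.bce_dice_loss` inside the autodiff
    graph, taking the foreground softmax channel as the flattened
    predicted probability of each image."""
    n, _, h, w = logits.data.shape
    p = engine.softmax(logits, axis=1)
    pf = engine.reshape(engine.take_channel(p, 1), (n, h * w))
    y = targets.reshape(n, h * w).astype(np.float32)
    ysum = y.sum(axis=1)
    dot = engine.tsum(engine.mul(pf, y), axis=1)
    den = engine.add(engine.tsum(pf, axis=1), ysum + DICE_EPS)
    dice = engine.div(engine.mul(dot, 2.0), den)
    logp = engine.log(engine.clamp_min(pf, LOG_EPS))
    if variant == "printed":
        inner = engine.add(engine.mul(engine.tsum(engine.mul(logp, y), axis=1), 0.5),
                           dice)
        return engine.neg(engine.tmean(inner))
    # standard: 0.5 * full BCE (mean over pixels) - soft dice
    log1p = engine.log(engine.clamp_min(engine.sub(1.0, pf), LOG_EPS))
    bce = engine.neg(engine.tmean(
        engine.add(engine.mul(logp, y), engine.mul(log1p, 1.0 - y)), axis=1))
    per_image = engine.sub(engine.mul(bce, 0.5), dice)
    return engine.tmean(per_image)


# --------------------------------------------------------------------------
# training loops
# --------------------------------------------------------------------------

def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _seg_loss(model, X, Y, W, variant: str, training: bool):
    if isinstance(model, NestedUNet) and model.cfg.deep_supervision:
        heads = model.forward_heads(X, training=training)
        losses = [_bce_dice_graph(hd, Y, variant) for hd in heads]
        total = losses[0]
        for l in losses[1:]:
            total = engine.add(total, l)
        return engine.mul(total, 1.0 / len(losses)), heads[-1]
    logits = model.forward(X, training=training)
    return engine.weighted_softmax_cross_entropy(logits, Y, W), logits


def _seg_eval(model, X, Y, W, variant: str, batch_size: int):
    losses, correct, total = [], 0, 0
    with nn.no_grad():
        for start in range(0, len(X), batch_size):
            sl = slice(start, start + batch_size)
            loss, logits = _seg_loss(model, X[sl], Y[sl], W[sl], variant, False)
            losses.append(loss.item() * len(X[sl]))
            pred = logits.data.argmax(axis=1)
            correct += int((pred == Y[sl]).sum())
            total += Y[sl].size
    return float(np.sum(losses) / len(X)), correct / total


def train_segmenter(train, validation, net_cfg: SegNetConfig | None = None,
                    train_cfg: TrainConfig | None = None, seed: int = 0):
    """Train the segmentation network with Adam.

    Plain networks minimise the boundary-weighted cross-entropy; nested
    networks with deep supervision minimise the mean BCE+dice loss over
    their full-resolution heads.  Returns ``(model, history)``;
    deterministic given ``seed``.  Raises on non-finite loss."""
    net_cfg = net_cfg or SegNetConfig()
    train_cfg = train_cfg or TrainConfig()
    if not len(train) or not len(validation):
        raise ValueError("train and validation sets must be non-empty")
    Xtr, Ytr, Wtr = prepare_segmentation_data(train, net_cfg, train_cfg)
    Xva, Yva, Wva = prepare_segmentation_data(validation, net_cfg, train_cfg)
    model = build_unet(net_cfg, seed=seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.lr)
    rng = np.random.default_rng(seed + 1)
    history = TrainingHistory()
    for _ in range(train_cfg.epochs):
        for idx in _epoch_batches(len(Xtr), train_cfg.batch_size, rng):
            loss, _ = _seg_loss(model, Xtr[idx], Ytr[idx], Wtr[idx],
                                train_cfg.loss_variant, True)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"segmentation training diverged (loss={loss.item()})")
            opt.zero_grad()
            loss.backward()
            opt.step()
        tl, ta = _seg_eval(model, Xtr, Ytr, Wtr, train_cfg.loss_variant,
                           train_cfg.batch_size)
        vl, va = _seg_eval(model, Xva, Yva, Wva, train_cfg.loss_variant,
                           train_cfg.batch_size)
        history.train_loss.append(tl)
        history.train_acc.append(ta)
        history.val_loss.append(vl)
        history.val_acc.append(va)
    return model, history


def predict_mask(model, image: np.ndarray) -> np.ndarray:
    """Segment a preprocessed image into a binary lesion mask.

    ``image`` must already be normalised and padded to a valid network
    input side (for the default architecture: 170x170 for a 128x128
    working canvas); the output is the softmax foreground channel
    thresholded at 0.5 (ties to foreground)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 input, got {image.shape}")
    if image.shape[0] != image.shape[1]:
        raise SizeError("expected a square input image")
    model.output_side(image.shape[0])  # raises SizeError when incompatible
    with nn.no_grad():
        logits = model.forward(image[None].transpose(0, 3, 1, 2), training=False)
    z = logits.data[0] - logits.data[0].max(axis=0, keepdims=True)
    e = np.exp(z)
    p_fg = e[1] / e.sum(axis=0)
    return binarize_mask(p_fg, 0.5)


def extract_lesion(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero the background; lesion RGB values are preserved bit-exactly."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"size mismatch: image {image.shape[:2]} vs mask {mask.shape}")
    return image * mask[..., None].astype(image.dtype)


LABELS = ("benign", "malignant")


def _clf_arrays(items):
    pairs = _unpack_clf(items)
    X = np.asarray([normalize_image(img).transpose(2, 0, 1) for img, _ in pairs],
                   dtype=np.float32)
    y = np.asarray([LABELS.index(lbl) for _, lbl in pairs], dtype=np.int64)
    return X, y


def _clf_eval(model, X, y, batch_size):
    losses, correct = [], 0
    with nn.no_grad():
        for start in range(0, len(X), batch_size):
            sl = slice(start, start + batch_size)
            logits = model.forward(X[sl], training=False)
            loss = engine.softmax_cross_entropy(logits, y[sl])
            losses.append(loss.item() * len(X[sl]))
            correct += int((logits.data.argmax(axis=1) == y[sl]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train_classifier(train, validation, clf_cfg: ClassifierConfig | None = None,
                     train_cfg: TrainConfig | None = None, seed: int = 0):
    """Train the malignant/benign CNN on lesion images with Adam.

    Inputs are (image, label) pairs or Scene objects; a single-class
    training set raises.  Returns ``(model, history)``."""
    clf_cfg = clf_cfg or ClassifierConfig()
    train_cfg = train_cfg or TrainConfig()
    Xtr, ytr = _clf_arrays(train)
    Xva, yva = _clf_arrays(validation)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set contains a single class")
    model = build_classifier(clf_cfg, seed=seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.lr)
    rng = np.random.default_rng(seed + 1)
    history = TrainingHistory()
    for _ in range(train_cfg.epochs):
        for idx in _epoch_batches(len(Xtr), train_cfg.batch_size, rng):
            logits = model.forward(Xtr[idx], training=True)
            loss = engine.softmax_cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"classifier training diverged (loss={loss.item()})")
            opt.zero_grad()
            loss.backward()
            opt.step()
        tl, ta = _clf_eval(model, Xtr, ytr, train_cfg.batch_size)
        vl, va = _clf_eval(model, Xva, yva, train_cfg.batch_size)
        history.train_loss.append(tl)
        history.train_acc.append(ta)
        history.val_loss.append(vl)
        history.val_acc.append(va)
    return model, history


def classify_lesion(model: LesionClassifier, lesion: np.ndarray) -> tuple[str, float]:
    """Classify one lesion image; returns (label, P(malignant))."""
    lesion = np.asarray(lesion)
    if np.issubdtype(lesion.dtype, np.integer):
        lesion = normalize_image(lesion)
    proba = model.predict_proba(lesion[None].transpose(0, 3, 1, 2))[0]
    return LABELS[int(proba.argmax())], float(proba[1])


def run_cad(image: np.ndarray, seg_model, clf_model,
            ground_truth: np.ndarray | None = None) -> CadResult:
    """Run the full pipeline on one working-resolution RGB image.

    Equivalent to calling the stages in sequence: normalise and
    mirror-pad, segment, extract the lesion, classify.  If a ground
    truth mask is supplied, the dice score of the predicted mask
    against it is reported too."""
    image = np.asarray(image)
    canvas = image.shape[0]
    margin = fit_margin(seg_model.cfg, canvas)
    norm = normalize_image(image)
    padded = pad_symmetric(norm, margin) if margin else norm
    try:
        mask = predict_mask(seg_model, padded)
    except SizeError as err:
        raise SizeError(f"segmentation stage: {err}") from err
    lesion = extract_lesion(image, mask)
    try:
        label, prob = classify_lesion(clf_model, lesion)
    except SizeError as err:
        raise SizeError(f"classification stage: {err}") from err
    dice = None if ground_truth is None else dice_coefficient(mask, ground_truth)
    return CadResult(mask=mask, lesion=lesion, label=label, probability=prob,
                     dice=dice)


def segmentation_report(model, items) -> DiceReport:
    """Dice distribution of the model's predictions over (image, mask)
    pairs or Scenes."""
    pairs = _unpack_seg(items)
    margin = fit_margin(model.cfg, pairs[0][0].shape[0])
    values = []
    for img, mask in pairs:
        padded = pad_symmetric(normalize_image(img), margin) if margin else \
            normalize_image(img)
        pred = predict_mask(model, padded)
        values.append(dice_coefficient(pred, mask))
    return dice_distribution_report(values)
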