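"""Readers and writers for images, masks and dataset manifests.

A dataset manifest is a CSV with columns ``image_id, image_path,
mask_path, label`` (plus an optional ``excluded`` flag mirroring manual
curation); labels are binary, with seborrheic keratosis and moles both
mapping to "benign".
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocess import binarize_mask

__all__ = [
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "read_manifest",
    "load_record",
    "read_isic_layout",
]

_LABEL_MAP = {
    "malignant": "malignant",
    "melanoma": "malignant",
    "benign": "benign",
    "seborrheic_keratosis": "benign",
    "mole": "benign",
    "nevus": "benign",
}


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG dermoscopy image as uint8 HxWx3."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel PNG mask and binarize at threshold 128."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return binarize_mask(arr)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image).astype(np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask) * 255).astype(np.uint8))


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load a manifest CSV, normalising labels to malignant/benign."""
    df = pd.read_csv(path)
    required = {"image_id", "image_path", "mask_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df = df.copy()
    df["label"] = df["label"].str.lower().map(_LABEL_MAP)
    if df["label"].isna().any():
        bad = df.loc[df["label"].isna(), "image_id"].tolist()[:5]
        raise ValueError(f"unrecognised labels for images {bad}")
    if "excluded" not in df.columns:
        df["excluded"] = False
    if check_paths:
        for col in ("image_path", "mask_path"):
            for p in df[col]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file {p}")
    return df[~df["excluded"]].reset_index(drop=True)


def load_record(row) -> tuple[np.ndarray, np.ndarray, str]:
    """Load (image, mask, label) for one manifest row."""
    return read_image(row["image_path"]), read_mask(row["mask_path"]), row["label"]


def read_isic_layout(root: str | Path, labels_csv: str | Path | None = None
                     ) -> pd.DataFrame:
    """Build a manifest from an ISIC-2017-style directory layout.

    Expects images under ``root`` (jpg/png) and, for each image id, a
    mask named ``<id>_segmentation.png`` either next to the image or in
    a ``masks``/``GroundTruth`` sibling directory.  ``labels_csv`` maps
    ``image_id`` to a diagnosis column (``melanoma`` 0/1 or a ``label``
    string)."""
    root = Path(root)
    images = sorted(p for p in root.rglob("*") if p.suffix.lower() in
                    (".jpg", ".jpeg", ".png") and "_segmentation" not in p.stem
                    and "_mask" not in p.stem)
    labels = {}
    if labels_csv is not None:
        ldf = pd.read_csv(labels_csv)
        for _, r in ldf.iterrows():
            if "label" in ldf.columns:
                labels[str(r["image_id"])] = str(r["label"]).lower()
            else:
                labels[str(r["image_id"])] = (
                    "malignant" if float(r.get("melanoma", 0)) >= 0.5 else "benign")
    rows = []
    for img in images:
        stem = img.stem
        candidates = [img.with_name(f"{stem}_segmentation.png"),
                      img.with_name(f"{stem}_mask.png")]
        for sub in ("masks", "GroundTruth"):
            candidates.append(root / sub / f"{stem}_segmentation.png")
            candidates.append(root / sub / f"{stem}_mask.png")
        mask = next((c for c in candidates if c.exists()), None)
        if mask is None:
            continue
        rows.append({"image_id": stem, "image_path": str(img),
                     "mask_path": str(mask),
                     "label": labels.get(stem, "benign"), "excluded": False})
    if not rows:
        raise FileNotFoundError(f"no image/mask pairs found under {root}")
    df = pd.DataFrame(rows)
    df["label"] = df["label"].map(_LABEL_MAP).fillna("benign")
    return df
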