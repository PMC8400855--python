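"""Deterministic conditioning of dermoscopy images and lesion masks.

The segmentation network trains on unpadded (valid) convolutions, so its
output is smaller than its input.  The pipeline therefore resizes every
image to a common working resolution (128x128 by default), mirror-pads
the RGB image out to the network input size (170x170 for the default
architecture) and zero-pads the binary mask.  Mirror padding extends the
scene "as if reflected in a mirror", so the padded border never
introduces foreign structure; zero padding keeps the mask's foreground
mass unchanged.

Conventions (the source material leaves these open, so they are fixed
here once):

* mirror padding reflects *without* repeating the edge pixel
  (``[a, b, c]`` with margin 1 becomes ``[b, a, b, c, b]``);
* images are resized with bilinear interpolation, masks with
  nearest-neighbour so they stay binary;
* normalization divides 8-bit intensities by 255;
* 8-bit masks binarize at threshold 128, probability maps at 0.5, and
  ties go to foreground.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "resize_image",
    "resize_mask",
    "pad_symmetric",
    "pad_zero",
    "normalize_image",
    "binarize_mask",
    "center_crop",
]

#: margin that maps the 128 working resolution to the 170 network input
DEFAULT_MARGIN = 21


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    return image


def resize_image(image: np.ndarray, side: int, *, order: int = 1) -> np.ndarray:
    """Resize an RGB image to ``side`` x ``side`` (bilinear by default).

    Non-square inputs are resized anisotropically: every image is mapped
    to the same square working resolution regardless of aspect ratio.
    """
    image = _check_image(image)
    if side < 8:
        raise ValueError("side must be >= 8")
    if image.shape[:2] == (side, side) and order == 0:
        return image.copy()
    out = _sk_resize(image.astype(np.float64), (side, side), order=order,
                     mode="reflect", anti_aliasing=False, preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out.astype(image.dtype)


def resize_mask(mask: np.ndarray, side: int) -> np.ndarray:
    """Nearest-neighbour resize for binary masks (stays in {0, 1})."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected an HxW mask, got shape {mask.shape}")
    if mask.shape == (side, side):
        return mask.copy()
    out = _sk_resize(mask.astype(np.float64), (side, side), order=0,
                     mode="constant", anti_aliasing=False, preserve_range=True)
    return (out >= 0.5).astype(np.uint8)


def pad_symmetric(image: np.ndarray, margin: int) -> np.ndarray:
    """Mirror-pad an RGB image by ``margin`` pixels on every side.

    Uses reflection without edge repetition, so a 128x128 image with the
    default margin of 21 becomes the 170x170 network input.
    """
    image = _check_image(image)
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin >= min(image.shape[:2]):
        raise ValueError(
            f"margin {margin} must be smaller than the image sides {image.shape[:2]}"
        )
    if margin == 0:
        return image.copy()
    return np.pad(image, ((margin, margin), (margin, margin), (0, 0)), mode="reflect")


def pad_zero(mask: np.ndarray, margin: int) -> np.ndarray:
    """Zero-pad a binary mask; adds no foreground mass."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected an HxW mask, got shape {mask.shape}")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if margin == 0:
        return mask.copy()
    return np.pad(mask, margin, mode="constant", constant_values=0)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to [0, 1] by dividing by 255.

    Already-normalized input (floating point with max <= 1) is returned
    unchanged with a warning.
    """
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.floating) and (image.size == 0 or image.max() <= 1.0):
        warnings.warn("image appears to be normalized already; returning unchanged",
                      stacklevel=2)
        return image.astype(np.float32, copy=True)
    return (image.astype(np.float32) / 255.0)


def binarize_mask(grid: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Threshold a real grid into a {0, 1} mask; ties go to foreground.

    The default threshold is 128 for 8-bit grids and 0.5 for probability
    grids (inferred from the dtype).
    """
    grid = np.asarray(grid)
    if threshold is None:
        threshold = 128.0 if np.issubdtype(grid.dtype, np.integer) else 0.5
    return (grid >= threshold).astype(np.uint8)


def center_crop(array: np.ndarray, side: int) -> np.ndarray:
    """Center-crop the leading two axes of an array to ``side`` x ``side``."""
    H, W = array.shape[:2]
    if side > H or side > W:
        raise ValueError(f"cannot crop {H}x{W} to {side}x{side}")
    top, left = (H - side) // 2, (W - side) // 2
    return array[top : top + side, left : left + side, ...]
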