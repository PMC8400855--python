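"""Synthetic dermoscopy scenes with exact ground-truth masks.

Each scene is a skin-coloured canvas carrying a single pigmented lesion
whose boundary is a radial harmonic perturbation of an ellipse:

    r(theta) = r_ellipse(theta) * (1 + a1*cos(theta + phi1)
                                     + sum_k ak*cos(k*theta + phik))

The first harmonic encodes asymmetry (the clinical "A" rule), the
higher harmonics encode border irregularity ("B"), and colour
variegation patches inside the lesion encode "C".  Malignant scenes
draw from distributions with higher asymmetry, irregularity and
variegation and darker, more variable pigment than benign scenes, so
the malignant/benign task is learnable by design.  The mask is the
exact rasterised interior (the set of pixels whose signed boundary
field is <= 0), so segmentation ground truth carries no labelling
noise.

Dermoscopy nuisance structure is emulated by dark hair strokes
(quadratic Bezier curves) and a radial vignette.  The generator aims at
the statistical structure the method assumes, not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SceneParams",
    "sample_scene_params",
    "signed_boundary_field",
    "generate_scene",
    "add_hair_artifacts",
    "generate_scenes",
    "generate_dataset",
]

#: minimum separation between mean lesion and skin colour (8-bit units)
CONTRAST_MARGIN = 30.0


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters of one synthetic dermoscopy scene."""

    canvas_side: int = 128
    center: tuple[float, float] = (0.5, 0.5)        # fractions of the side
    radii: tuple[float, float] = (0.25, 0.2)        # ellipse semi-axes, fractions
    boundary_amplitude: float = 0.05
    boundary_harmonics: int = 3
    rotation: float = 0.0
    asymmetry: float = 0.0                          # first-harmonic amplitude
    skin_rgb: tuple[float, float, float] = (205.0, 170.0, 150.0)
    skin_sigma: float = 6.0
    lesion_rgb: tuple[float, float, float] = (140.0, 100.0, 85.0)
    lesion_sigma: float = 10.0
    variegation_patches: int = 1
    hair_count: int = 0
    hair_darkness: float = 0.6
    vignette: float = 0.15
    label: str = "benign"
    seed: int = 0

    def __post_init__(self):
        if max(self.radii) >= 0.5:
            raise ValueError("radii must be < canvas_side/2 (fraction < 0.5)")
        if self.skin_sigma < 0 or self.lesion_sigma < 0:
            raise ValueError("colour sigmas must be >= 0")
        if self.label not in ("benign", "malignant"):
            raise ValueError("label must be 'benign' or 'malignant'")


def sample_scene_params(label: str, seed: int, canvas_side: int = 128,
                        contrast: float = 1.0) -> SceneParams:
    """Draw scene parameters from the class-conditional distributions.

    ``contrast`` in (0, 1] shrinks the lesion/skin colour gap — the
    difficulty knob emulating low-contrast lesions."""
    rng = np.random.default_rng(seed)
    skin = np.array([205.0, 170.0, 150.0]) + rng.normal(0, 5, 3)
    if label == "malignant":
        asym = rng.uniform(0.20, 0.45)
        amp = rng.uniform(0.08, 0.18)
        harmonics = int(rng.integers(4, 8))
        patches = int(rng.integers(3, 8))
        lesion = np.array([105.0, 70.0, 60.0]) + rng.normal(0, 12, 3)
        lesion_sigma = rng.uniform(12.0, 20.0)
    elif label == "benign":
        asym = rng.uniform(0.0, 0.12)
        amp = rng.uniform(0.01, 0.06)
        harmonics = int(rng.integers(2, 5))
        patches = int(rng.integers(0, 2))
        lesion = np.array([150.0, 110.0, 90.0]) + rng.normal(0, 8, 3)
        lesion_sigma = rng.uniform(4.0, 8.0)
    else:
        raise ValueError("label must be 'benign' or 'malignant'")
    lesion = skin + (lesion - skin) * contrast
    return SceneParams(
        canvas_side=canvas_side,
        center=(0.5 + rng.uniform(-0.08, 0.08), 0.5 + rng.uniform(-0.08, 0.08)),
        radii=(rng.uniform(0.18, 0.32), rng.uniform(0.15, 0.28)),
        boundary_amplitude=amp,
        boundary_harmonics=harmonics,
        rotation=rng.uniform(0, np.pi),
        asymmetry=asym,
        skin_rgb=tuple(skin),
        lesion_rgb=tuple(np.clip(lesion, 0, 255)),
        lesion_sigma=lesion_sigma,
        variegation_patches=patches,
        hair_count=int(rng.integers(0, 4)),
        vignette=0.15,
        label=label,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _harmonic_phases(params: SceneParams) -> tuple[float, np.ndarray, np.ndarray]:
    """Deterministic per-scene phases/amplitudes of the boundary model."""
    rng = np.random.default_rng(params.seed)
    phi1 = rng.uniform(0, 2 * np.pi)
    ks = np.arange(2, 2 + params.boundary_harmonics)
    amps = params.boundary_amplitude * rng.uniform(0.3, 1.0, size=ks.size)
    phis = rng.uniform(0, 2 * np.pi, size=ks.size)
    return phi1, np.stack([ks, amps]), phis


def signed_boundary_field(params: SceneParams) -> np.ndarray:
    """Signed field F with F <= 0 exactly on the lesion interior.

    F(x) = rho(x) - r(theta(x)), in pixels, where rho/theta are polar
    coordinates about the lesion centre after undoing the rotation."""
    side = params.canvas_side
    cy, cx = params.center[0] * side, params.center[1] * side
    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(-params.rotation), np.sin(-params.rotation)
    rx = c * dx - s * dy
    ry = s * dx + c * dy
    rho = np.hypot(rx, ry)
    theta = np.arctan2(ry, rx)
    a = params.radii[0] * side
    b = params.radii[1] * side
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    phi1, karr, phis = _harmonic_phases(params)
    mod = 1.0 + params.asymmetry * np.cos(theta + phi1)
    for (k, amp), phi in zip(karr.T, phis):
        mod += amp * np.cos(k * theta + phi)
    mod = np.maximum(mod, 0.2)
    return rho - r_ell * mod


def generate_scene(params: SceneParams) -> tuple[np.ndarray, np.ndarray, str]:
    """Render one scene: (uint8 RGB image, {0,1} mask, label).

    Deterministic given ``params`` (including its seed)."""
    side = params.canvas_side
    rng = np.random.default_rng(params.seed + 1)
    field_vals = signed_boundary_field(params)
    mask = (field_vals <= 0).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("degenerate lesion: zero rasterised area")

    img = np.empty((side, side, 3), dtype=np.float64)
    for ch in range(3):
        img[..., ch] = params.skin_rgb[ch] + rng.normal(0, params.skin_sigma,
                                                        (side, side))
    lesion_tex = np.empty_like(img)
    for ch in range(3):
        lesion_tex[..., ch] = params.lesion_rgb[ch] + rng.normal(
            0, params.lesion_sigma, (side, side))
    img[mask == 1] = lesion_tex[mask == 1]

    # colour variegation: darker/shifted patches inside the lesion
    fg = np.argwhere(mask == 1)
    for _ in range(params.variegation_patches):
        cyx = fg[rng.integers(0, len(fg))]
        radius = rng.uniform(0.05, 0.15) * side
        shift = rng.uniform(-55, -15, 3) if params.label == "malignant" else \
            rng.uniform(-25, -5, 3)
        yy, xx = np.mgrid[0:side, 0:side]
        patch = (np.hypot(yy - cyx[0], xx - cyx[1]) <= radius) & (mask == 1)
        img[patch] += shift

    # radial vignette (dermoscope aperture)
    if params.vignette > 0:
        yy, xx = np.mgrid[0:side, 0:side]
        rho = np.hypot(yy - side / 2, xx - side / 2) / (side / np.sqrt(2))
        img *= (1.0 - params.vignette * rho[..., None] ** 2)

    img = np.clip(img, 0, 255).astype(np.uint8)
    if params.hair_count:
        img = add_hair_artifacts(img, params.hair_count, params.seed + 2,
                                 darkness=params.hair_darkness)
    return img, mask, params.label


def add_hair_artifacts(image: np.ndarray, count: int, seed: int,
                       darkness: float = 0.6) -> np.ndarray:
    """Overlay ``count`` dark hair-like strokes (quadratic Bezier curves).

    ``count=0`` returns the image unchanged; stroke pixels are darkened
    multiplicatively so they are never brighter than before."""
    if count < 0:
        raise ValueError("count must be >= 0")
    image = np.asarray(image)
    if count == 0:
        return image.copy()
    out = image.astype(np.float64).copy()
    H, W = image.shape[:2]
    rng = np.random.default_rng(seed)
    factor = 1.0 - np.clip(darkness, 0.0, 1.0)
    t = np.linspace(0, 1, 4 * max(H, W))[:, None]
    for _ in range(count):
        p0, p1, p2 = rng.uniform(0, [H, W], (3, 2))
        curve = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
        ys = np.clip(np.rint(curve[:, 0]).astype(int), 0, H - 1)
        xs = np.clip(np.rint(curve[:, 1]).astype(int), 0, W - 1)
        thick = int(rng.integers(1, 3))
        for dy in range(-thick + 1, thick):
            for dx in range(-thick + 1, thick):
                yy = np.clip(ys + dy, 0, H - 1)
                xx = np.clip(xs + dx, 0, W - 1)
                out[yy, xx] = np.minimum(out[yy, xx], image[yy, xx] * factor)
    return np.clip(np.rint(out), 0, 255).astype(image.dtype)


@dataclass
class Scene:
    image: np.ndarray
    mask: np.ndarray
    label: str
    params: SceneParams = field(repr=False, default=None)


def _scene_seed(master_seed: int, index: int) -> int:
    return int((master_seed * 100003 + 7919 * index + 1) % (2**31 - 1))


def generate_scenes(n: int, malignant_fraction: float = 0.5, seed: int = 0,
                    canvas_side: int = 128, contrast: float = 1.0) -> list[Scene]:
    """Generate ``n`` scenes in memory with the given class balance.

    Class counts follow rounding of ``n * malignant_fraction``;
    per-scene seeds are derived deterministically from ``seed``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < malignant_fraction < 1:
        raise ValueError("malignant_fraction must be in (0, 1)")
    n_mal = int(round(n * malignant_fraction))
    labels = ["malignant"] * n_mal + ["benign"] * (n - n_mal)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    scenes = []
    for i in range(n):
        label = labels[order[i]]
        params = sample_scene_params(label, _scene_seed(seed, i),
                                     canvas_side=canvas_side, contrast=contrast)
        img, mask, _ = generate_scene(params)
        scenes.append(Scene(image=img, mask=mask, label=label, params=params))
    return scenes


def generate_dataset(n: int, malignant_fraction: float, seed: int,
                     outdir: str | Path, canvas_side: int = 128,
                     contrast: float = 1.0) -> pd.DataFrame:
    """Write ``n`` scenes as PNG images/masks plus a manifest CSV.

    The manifest has the same contract as a real-data manifest
    (columns: image_id, image_path, mask_path, label, excluded), so
    synthetic and real datasets are interchangeable downstream."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    scenes = generate_scenes(n, malignant_fraction, seed, canvas_side, contrast)
    rows = []
    for i, sc in enumerate(scenes):
        image_id = f"syn_{i:05d}"
        ipath = outdir / "images" / f"{image_id}.png"
        mpath = outdir / "masks" / f"{image_id}_mask.png"
        iio.imwrite(ipath, sc.image)
        iio.imwrite(mpath, (sc.mask * 255).astype(np.uint8))
        rows.append({"image_id": image_id, "image_path": str(ipath),
                     "mask_path": str(mpath), "label": sc.label,
                     "excluded": False})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
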