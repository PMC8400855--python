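# Methods

## Overview

`dermcad` implements a two-stage computer-aided diagnosis of malignant
melanoma from dermoscopy images:

1. **Segmentation.** A U-shaped convolutional encoder/decoder labels
   every pixel lesion/background. Training is supervised by a
   boundary-weighted cross-entropy; inference thresholds the softmax
   foreground probability into a binary mask.
2. **Classification.** The predicted mask is multiplied into the RGB
   image (background zeroed) and a compact CNN classifies the extracted
   lesion as malignant or benign.

A synthetic dermoscopy scene generator provides image/mask/label
triplets with the statistical structure both stages rely on, so the
entire pipeline is exercisable and testable without any external
dataset.

## Segmentation model

The network uses unpadded ("valid") 3×3 convolutions, stride 1, 2×2 max
pooling, 64 base feature maps doubling per level, and Adam. Because
valid convolutions shrink the image, the pipeline mirror-pads the
working-resolution image (128×128) before the forward pass and the
network returns a map at exactly the working resolution.

**Depth reading.** The architecture table we follow lists "3 layers".
We read this as three *resolution levels*, i.e. two 2×2 pooling stages.
This is the only reading consistent with the published exact
input/output contract (170×170 in → 128×128 out) under valid
convolutions; with three pooling stages the deepest output reachable
from a 170 input is 76. The size trace of the default network is

    170 →(conv×2) 166 →(pool) 83 →(conv×2) 79 →(crop) 78 →(pool) 39
        →(conv×2) 35 →(up) 70 →(conv×2) 66 →(up) 132 →(conv×2) 128

Two mechanical consequences of valid mode are handled by centre crops:
odd sides are cropped to even before each pooling, and encoder skip
tensors are centre-cropped to the decoder stream's size before
concatenation. A 128-canvas therefore pairs with a mirror-pad margin of
21; when several margins reproduce the canvas (the interior even-crop
absorbs one pixel of parity), the largest is used, which maximises the
mirror context and matches the published 170 input.

**Mirror padding** reflects without repeating the edge pixel
(`[a,b,c]` → `[b,a,b,c,b]`): the padded border continues the scene as
in a mirror and introduces no foreign structure. Masks are zero-padded
instead so foreground mass is conserved; training targets are the
zero-padded masks centre-aligned with the output grid (with the default
geometry this is the identity).

**Weight map.** The training loss multiplies each pixel's negative
log-likelihood by

    w(x) = w_c(x) + w0 · exp(−(d1(x)+d2(x))² / (2σ²)),

with `w0 = 10` and `σ = 5` px (the convention of the original
biomedical U-Net this design follows). `d1`/`d2` are Euclidean
distances to the nearest and second-nearest connected foreground
*component* (8-connectivity, distances to component pixels, so `d1 = 0`
inside foreground). With fewer than two components `d2` is set to the
image diagonal, which drives the exponential term to numerical zero —
the single-lesion dermoscopy case degrades gracefully to pure class
balancing. The class-balance term is inverse-frequency,
`w_c(x) = N / (2·count(class of x))`, normalised so a 50/50 mask gets
weight 1 everywhere; the source material states only that the term
depends on class frequency, so this concrete form is a documented
convention of this package, not a quoted formula.

The loss is averaged (not summed) over pixels so its magnitude — and
hence the effective Adam step — is independent of image size.

**Nested variant.** A dense-skip redesign is also provided: node (i, j)
concatenates its j same-level predecessors with the 2×2
transposed-convolution up-sampling of node (i+1, j−1), so fan-in is 1
on the encoder backbone and j+1 elsewhere. With deep supervision every
full-resolution node (0, j), j ≥ 1 gets a 1×1 two-class head, and the
training loss is the mean over heads of a BCE+dice objective. That
objective is implemented exactly as printed in the source formula
(half the foreground log-likelihood dot product plus a dice ratio per
flattened image, negated batch mean); because the printed form lacks
the background BCE term, a `variant="standard"` switch provides the
conventional `0.5·BCE − soft-dice` reading. Neither reading is asserted
to be the original intent. The nested network uses same-padding
convolutions (input side divisible by 2^depth); the published 170→128
contract applies to the plain valid-mode network.

## Classifier

Four blocks of (3×3 same-padding conv with 64 kernels → batch norm →
ReLU → 2×2 max pool), then global average pooling and a dense two-way
softmax head. The source describes the body (four conv layers, 64
kernels, max pooling, batch normalisation, ReLU) but not the head;
global average pooling keeps the classifier input-size-agnostic and
nearly parameter-free. By default the classifier consumes
lesion-extracted images (background zeroed by the predicted mask); a
flagless alternative — classifying the raw image — is possible by
simply not extracting, and is useful for ablation.

## Numpy training backend

No autodiff framework is part of the dependency set; training runs on a
compact reverse-mode automatic-differentiation engine written for this
package (`dermcad.nn`). Convolution is im2col assembled from the k²
shifted channel-contiguous slices followed by a BLAS matmul; the 2×2
stride-2 transposed convolution, max-pooling, batch-norm, dense and
loss ops carry hand-derived gradients. Every gradient is verified
against central finite differences in the test suite. Parameters are
float32, He-normal initialised from an explicit seeded generator, so
two builds from the same configuration and seed are bitwise identical,
and whole training runs are bitwise reproducible on a fixed machine.

## Synthetic scenes

The lesion boundary is a radial harmonic perturbation of an ellipse:

    r(θ) = r_ellipse(θ) · (1 + a₁cos(θ+φ₁) + Σₖ aₖ cos(kθ+φₖ)),

where the first harmonic is clinical asymmetry (A), the higher
harmonics border irregularity (B), and colour variegation patches
inside the lesion implement the colour rule (C). The mask is the exact
set of pixels with signed boundary field ≤ 0 — ground truth carries no
labelling noise. Class-conditional parameter distributions were fixed
a priori from the A-B-C rules:

| parameter | benign | malignant |
|---|---|---|
| asymmetry a₁ | U(0, 0.12) | U(0.20, 0.45) |
| irregularity amplitude | U(0.01, 0.06) | U(0.08, 0.18) |
| harmonics | 2–4 | 4–7 |
| variegation patches | 0–1 | 3–7 |
| pigment RGB mean | ≈(150,110,90) | ≈(105,70,60), higher spread |

Nuisance structure: dark quadratic-Bézier hair strokes (multiplicative
darkening, so strokes never brighten), a radial vignette, and Gaussian
colour texture. A `contrast` knob in (0, 1] shrinks the lesion/skin
colour gap to emulate the hard low-contrast case.

What the generator does **not** emulate: dermoscopy optics, specular
reflection, gel bubbles, rulers/markers, pigment network texture, and
multi-lesion scenes. Passing learning tests on these scenes therefore
demonstrate that the pipeline's machinery (losses, gradients, data
flow, both stages) is correct and learnable, not that the trained
weights transfer to clinical images.

## Problem sizes and numerical choices

* Learning-property tests and examples run at a desk scale chosen once:
  200 scenes at 64×64 (160 train / 40 validation), segmentation with 8
  base features for 4 epochs (batch 8, Adam lr 1e-3), classification
  with 8 kernels per layer for 20 epochs (batch 16). The default model
  configuration keeps the published values (64 features; 50 epochs)
  and is what the CLI uses unless a config file overrides it.
* Log arguments are clamped at 1e-12; the soft-dice denominator carries
  ε = 1e-6; per-pixel softmax is stabilised by max subtraction.
* Mask binarisation: threshold 128 for 8-bit files, 0.5 for
  probabilities, ties to foreground. Hard dice of two empty masks is
  defined as 100.
* Images resize bilinearly (anisotropically — every input maps to the
  square working resolution), masks by nearest neighbour;
  normalisation divides by 255. The source states that resizing and
  normalisation happen but not how; these are this package's
  conventions.
* Non-square or too-small network inputs raise `SizeError` naming the
  minimal supported side.
* Class labels are 0 = benign, 1 = malignant throughout; reported
  probabilities are always P(malignant).

## Known limitations

* CPU-only numpy training: practical for the scaled-down study sizes,
  slow at the full published scale (2000 ISIC images, 50 epochs).
* The classifier trained on ground-truth-extracted lesions degrades on
  predicted-mask extractions (distribution shift); the pipeline example
  therefore trains it on predicted-mask extractions.
* The curation step that reduced the original dataset (hair, markers,
  noise exclusions) is represented only as a manifest `excluded`
  column, not an automatic detector.
* Only the dice overlap metric is implemented; no augmentation, no
  pretrained backbones, no hyper-parameter search.
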