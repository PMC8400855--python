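"""Segmentation and classification network architectures.

Three networks are provided, all built on :mod:`dermcad.nn`:

* :class:`UNet` — the classic encoder/decoder with skip connections.
  In ``valid`` padding mode every 3x3 convolution is unpadded, so the
  output is smaller than the input; centre crops are inserted before
  each pooling stage (to keep sides even) and at each skip connection.
  With the default two pooling stages a 170x170 input yields exactly a
  128x128 two-class output:
  170 -> 166 -> 83 -> 79 -> (crop) 78 -> 39 -> 35 -> 70 -> 66 -> 132 -> 128.
* :class:`NestedUNet` — the dense-skip redesign in which node (i, j)
  concatenates all j same-level predecessors with the up-sampled output
  of node (i+1, j-1); with deep supervision every full-resolution node
  (0, j), j >= 1 gets its own two-class head.
* :class:`LesionClassifier` — four blocks of (3x3 conv, batch norm,
  ReLU, 2x2 max pool) with 64 kernels each, global average pooling and
  a dense 2-class softmax head.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .config import ClassifierConfig, SegNetConfig
from .nn import engine

__all__ = [
    "SizeError",
    "node_input_count",
    "nested_node_graph",
    "unet_node_graph",
    "simulate_sizes",
    "min_input_side",
    "UNet",
    "NestedUNet",
    "LesionClassifier",
    "build_unet",
    "build_nested_unet",
    "build_classifier",
    "save_model",
    "load_model",
    "model_summary",
]


class SizeError(ValueError):
    """Raised when an input is spatially incompatible with a network."""


# --------------------------------------------------------------------------
# topology helpers
# --------------------------------------------------------------------------

def node_input_count(i: int, j: int) -> int:
    """Fan-in of nested node (i, j): 1 on the encoder backbone (j = 0),
    else j same-level predecessors plus one up-sampled input."""
    if i < 0 or j < 0:
        raise ValueError("node indices must be non-negative")
    return 1 if j == 0 else j + 1


def nested_node_graph(depth: int) -> dict[tuple[int, int], list]:
    """Abstract wiring of the nested network at a given pooling depth.

    Maps each node (i, j) — i the resolution level (0 = full
    resolution), j the skip-path index — to the list of its inputs
    ("input" for the image, otherwise node ids)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    graph: dict[tuple[int, int], list] = {}
    for i in range(depth + 1):
        graph[(i, 0)] = ["input"] if i == 0 else [(i - 1, 0)]
    for j in range(1, depth + 1):
        for i in range(depth + 1 - j):
            graph[(i, j)] = [(i, k) for k in range(j)] + [(i + 1, j - 1)]
    return graph


def unet_node_graph(depth: int) -> dict[tuple[int, int], list]:
    """Abstract wiring of the plain U-Net in the same node notation:
    encoder backbone (i, 0) plus one decoder node (i, 1) per level."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    graph: dict[tuple[int, int], list] = {}
    for i in range(depth + 1):
        graph[(i, 0)] = ["input"] if i == 0 else [(i - 1, 0)]
    for i in range(depth - 1, -1, -1):
        below = (depth, 0) if i == depth - 1 else (i + 1, 1)
        graph[(i, 1)] = [(i, 0), below]
    return graph


# --------------------------------------------------------------------------
# spatial size arithmetic
# --------------------------------------------------------------------------

def simulate_sizes(cfg: SegNetConfig, side: int) -> dict:
    """Trace the spatial side length through the network.

    Returns per-level encoder sizes (after the conv block, before the
    even-crop/pool), the bottleneck size, decoder sizes and the output
    side; raises :class:`SizeError` naming the minimal supported side
    if any stage collapses."""
    k = cfg.kernel
    shrink = 0 if cfg.padding_mode == "same" else 2 * (k - 1)
    s = side
    enc: list[int] = []
    try:
        for _ in range(cfg.depth):
            s -= shrink
            if s < k:
                raise _Collapse
            enc.append(s)
            if s % 2:
                s -= 1  # centre-crop to even before pooling
            s //= 2
            if s < 1:
                raise _Collapse
        s -= shrink  # bottleneck block
        if s < k:
            raise _Collapse
        bottleneck = s
        dec: list[int] = []
        for lvl in range(cfg.depth - 1, -1, -1):
            s *= 2
            if cfg.padding_mode == "valid" and s > enc[lvl]:
                raise _Collapse  # skip too small to crop down to the stream
            s -= shrink
            if s < 1:
                raise _Collapse
            dec.append(s)
    except _Collapse:
        raise SizeError(
            f"input side {side} is too small for this configuration; "
            f"the minimal supported side is {min_input_side(cfg)}"
        ) from None
    return {"encoder": enc, "bottleneck": bottleneck, "decoder": dec, "output": s}


def min_input_side(cfg: SegNetConfig, limit: int = 4096) -> int:
    """Smallest input side for which a forward pass succeeds."""
    for side in range(cfg.kernel, limit):
        try:
            _trace(cfg, side)
            return side
        except _Collapse:
            continue
    raise SizeError("no valid input side found below the search limit")


class _Collapse(Exception):
    pass


def _trace(cfg: SegNetConfig, side: int) -> int:
    """Raw size trace; raises :class:`_Collapse` on failure."""
    k = cfg.kernel
    shrink = 0 if cfg.padding_mode == "same" else 2 * (k - 1)
    s = side
    enc = []
    for _ in range(cfg.depth):
        s -= shrink
        if s < k:
            raise _Collapse
        enc.append(s)
        if s % 2:
            s -= 1
        s //= 2
        if s < 1:
            raise _Collapse
    s -= shrink
    if s < k:
        raise _Collapse
    for lvl in range(cfg.depth - 1, -1, -1):
        s *= 2
        if cfg.padding_mode == "valid":
            if s > enc[lvl]:
                raise _Collapse
        s -= shrink
        if s < 1:
            raise _Collapse
    return s


def output_side(cfg: SegNetConfig, side: int) -> int:
    """Output side for a given input side (raises SizeError if invalid)."""
    try:
        return _trace(cfg, side)
    except _Collapse:
        raise SizeError(
            f"input side {side} is too small for this configuration; "
            f"the minimal supported side is {min_input_side(cfg)}"
        ) from None


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

class _ConvBlock(nn.Layer):
    """Two convolutions, each followed by ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, padding: str):
        self.c1 = nn.Conv2d(in_ch, out_ch, kernel, rng, padding=padding)
        self.c2 = nn.Conv2d(out_ch, out_ch, kernel, rng, padding=padding)

    def __call__(self, x):
        return engine.relu(self.c2(engine.relu(self.c1(x))))

    def parameters(self):
        return self.c1.parameters() + self.c2.parameters()


def _crop_even(t):
    H, W = t.data.shape[-2:]
    oh, ow = H - (H % 2), W - (W % 2)
    if (oh, ow) == (H, W):
        return t
    return engine.center_crop(t, (oh, ow))


def _to_nchw(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.shape[-1] in (1, 3) and x.shape[1] not in (1, 3):
        x = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    return x


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

class UNet:
    """Plain encoder/decoder segmentation network."""

    def __init__(self, cfg: SegNetConfig | None = None, seed: int = 0):
        cfg = cfg or SegNetConfig()
        if cfg.nested:
            raise ValueError("use NestedUNet for nested=True configs")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f = cfg.base_features
        feats = [f * 2 ** i for i in range(cfg.depth + 1)]
        self.enc = []
        in_ch = cfg.in_channels
        for lvl in range(cfg.depth):
            self.enc.append(_ConvBlock(in_ch, feats[lvl], cfg.kernel, rng,
                                       cfg.padding_mode))
            in_ch = feats[lvl]
        self.bottleneck = _ConvBlock(in_ch, feats[cfg.depth], cfg.kernel, rng,
                                     cfg.padding_mode)
        self.ups = []
        self.dec = []
        for lvl in range(cfg.depth - 1, -1, -1):
            self.ups.append(nn.ConvTranspose2d(feats[lvl + 1], feats[lvl], rng))
            self.dec.append(_ConvBlock(2 * feats[lvl], feats[lvl], cfg.kernel, rng,
                                       cfg.padding_mode))
        self.head = nn.Conv2d(feats[0], cfg.n_classes, 1, rng, padding="valid")

    def parameters(self):
        ps = []
        for blk in self.enc + [self.bottleneck] + self.ups + self.dec + [self.head]:
            ps.extend(blk.parameters())
        return ps

    def zero_(self):
        for p in self.parameters():
            p.data[...] = 0

    def output_side(self, side: int) -> int:
        return output_side(self.cfg, side)

    def forward(self, x, training: bool = False):
        """Forward an NCHW (or HxWx3) array; returns class logits."""
        x = _to_nchw(x)
        side = x.shape[-1]
        self.output_side(side)  # raises SizeError early with a clear message
        h = engine.tensor(x)
        skips = []
        for blk in self.enc:
            h = blk(h)
            skips.append(h)
            h = engine.maxpool2x2(_crop_even(h))
        h = self.bottleneck(h)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up(h)
            hw = h.data.shape[-2:]
            sw = skip.data.shape[-2:]
            if self.cfg.padding_mode == "valid":
                skip_c = engine.center_crop(skip, hw)
            else:
                # same mode: the decoder stream may exceed the (even-cropped)
                # skip by at most one pixel per axis
                tgt = (min(hw[0], sw[0]), min(hw[1], sw[1]))
                skip_c = engine.center_crop(skip, tgt)
                h = engine.center_crop(h, tgt)
            h = blk(engine.concat([skip_c, h], axis=1))
        return self.head(h)

    __call__ = forward


class NestedUNet:
    """Dense-skip segmentation network with optional deep supervision.

    Node (i, j) receives its j same-level predecessors concatenated
    with the up-sampled output of node (i+1, j-1); uses same-padding
    convolutions (the input side must be divisible by 2**depth)."""

    def __init__(self, cfg: SegNetConfig | None = None, seed: int = 0):
        cfg = cfg or SegNetConfig(nested=True, padding_mode="same")
        if not cfg.nested:
            raise ValueError("NestedUNet requires nested=True")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d = cfg.depth
        feats = [cfg.base_features * 2 ** i for i in range(d + 1)]
        self.blocks: dict[tuple[int, int], _ConvBlock] = {}
        self.upsamplers: dict[tuple[int, int], nn.ConvTranspose2d] = {}
        for i in range(d + 1):
            in_ch = cfg.in_channels if i == 0 else feats[i - 1]
            self.blocks[(i, 0)] = _ConvBlock(in_ch, feats[i], cfg.kernel, rng, "same")
        for j in range(1, d + 1):
            for i in range(d + 1 - j):
                self.upsamplers[(i, j)] = nn.ConvTranspose2d(feats[i + 1], feats[i], rng)
                in_ch = j * feats[i] + feats[i]
                self.blocks[(i, j)] = _ConvBlock(in_ch, feats[i], cfg.kernel, rng, "same")
        head_js = range(1, d + 1) if cfg.deep_supervision else [d]
        self.heads = {j: nn.Conv2d(feats[0], cfg.n_classes, 1, rng, padding="valid")
                      for j in head_js}

    def parameters(self):
        ps = []
        for key in sorted(self.blocks):
            ps.extend(self.blocks[key].parameters())
        for key in sorted(self.upsamplers):
            ps.extend(self.upsamplers[key].parameters())
        for j in sorted(self.heads):
            ps.extend(self.heads[j].parameters())
        return ps

    def zero_(self):
        for p in self.parameters():
            p.data[...] = 0

    def node_graph(self) -> dict[tuple[int, int], list]:
        return nested_node_graph(self.cfg.depth)

    def output_side(self, side: int) -> int:
        if side % (2 ** self.cfg.depth):
            raise SizeError(
                f"nested network needs the side divisible by {2 ** self.cfg.depth}, "
                f"got {side}")
        return side

    def forward_heads(self, x, training: bool = False) -> list:
        x = _to_nchw(x)
        self.output_side(x.shape[-1])
        d = self.cfg.depth
        nodes: dict[tuple[int, int], engine.Tensor] = {}
        h = engine.tensor(x)
        for i in range(d + 1):
            h_in = h if i == 0 else engine.maxpool2x2(nodes[(i - 1, 0)])
            nodes[(i, 0)] = self.blocks[(i, 0)](h_in)
        for j in range(1, d + 1):
            for i in range(d + 1 - j):
                up = self.upsamplers[(i, j)](nodes[(i + 1, j - 1)])
                cat = engine.concat([nodes[(i, k)] for k in range(j)] + [up], axis=1)
                nodes[(i, j)] = self.blocks[(i, j)](cat)
        return [self.heads[j](nodes[(0, j)]) for j in sorted(self.heads)]

    def forward(self, x, training: bool = False):
        """Logits of the deepest full-resolution head."""
        return self.forward_heads(x, training)[-1]

    __call__ = forward


class LesionClassifier:
    """Malignant/benign CNN over (lesion-extracted) RGB images."""

    def __init__(self, cfg: ClassifierConfig | None = None, seed: int = 0):
        cfg = cfg or ClassifierConfig()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.convs = []
        self.bns = []
        in_ch = cfg.in_channels
        for _ in range(cfg.conv_layers):
            self.convs.append(nn.Conv2d(in_ch, cfg.kernels_per_layer, cfg.kernel, rng,
                                        padding="same"))
            if cfg.batch_norm:
                self.bns.append(nn.BatchNorm2d(cfg.kernels_per_layer))
            in_ch = cfg.kernels_per_layer
        self.fc = nn.Dense(cfg.kernels_per_layer, cfg.n_classes, rng)

    def parameters(self):
        ps = []
        for c in self.convs:
            ps.extend(c.parameters())
        for b in self.bns:
            ps.extend(b.parameters())
        ps.extend(self.fc.parameters())
        return ps

    def zero_(self):
        for p in self.parameters():
            p.data[...] = 0
        for b in self.bns:
            b.state["mean"][...] = 0
            b.state["var"][...] = 1

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, x, training: bool = False):
        """NCHW (or HWC) input -> (N, 2) class logits."""
        x = _to_nchw(x)
        if min(x.shape[-2:]) < 2 ** self.cfg.conv_layers:
            raise SizeError(
                f"input side must be >= {2 ** self.cfg.conv_layers} for "
                f"{self.cfg.conv_layers} pooling stages")
        h = engine.tensor(x)
        for idx, conv in enumerate(self.convs):
            h = conv(h)
            if self.bns:
                h = self.bns[idx](h, training=training)
            h = engine.relu(h)
            h = engine.maxpool2x2(_crop_even(h))
        return self.fc(engine.global_avg_pool(h))

    __call__ = forward

    def predict_proba(self, x) -> np.ndarray:
        with nn.no_grad():
            logits = self.forward(x, training=False)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# construction, persistence, summaries
# --------------------------------------------------------------------------

def build_unet(cfg: SegNetConfig | None = None, seed: int = 0):
    """Build the configured segmentation network (plain or nested)."""
    cfg = cfg or SegNetConfig()
    return NestedUNet(cfg, seed=seed) if cfg.nested else UNet(cfg, seed=seed)


def build_nested_unet(cfg: SegNetConfig | None = None, seed: int = 0) -> NestedUNet:
    cfg = cfg or SegNetConfig(nested=True, deep_supervision=True, padding_mode="same")
    return NestedUNet(cfg, seed=seed)


def build_classifier(cfg: ClassifierConfig | None = None, seed: int = 0) -> LesionClassifier:
    return LesionClassifier(cfg or ClassifierConfig(), seed=seed)


_KIND = {UNet: "unet", NestedUNet: "nested_unet", LesionClassifier: "classifier"}


def save_model(model, path: str | Path) -> None:
    """Checkpoint parameters (and batch-norm running stats) to .npz."""
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    if isinstance(model, LesionClassifier):
        for i, b in enumerate(model.bns):
            arrays[f"bn{i}_mean"] = b.state["mean"]
            arrays[f"bn{i}_var"] = b.state["var"]
    cfg = model.cfg.__dict__
    np.savez(path, __config__=json.dumps({"kind": _KIND[type(model)], "cfg": cfg}),
             **arrays)


def load_model(path: str | Path):
    data = np.load(Path(path), allow_pickle=False)
    meta = json.loads(str(data["__config__"]))
    kind, cfg = meta["kind"], meta["cfg"]
    if kind == "classifier":
        model = LesionClassifier(ClassifierConfig(**cfg))
    else:
        model = build_unet(SegNetConfig(**cfg))
    for i, p in enumerate(model.parameters()):
        p.data = data[f"p{i}"].copy()
    if kind == "classifier":
        for i, b in enumerate(model.bns):
            b.state["mean"] = data[f"bn{i}_mean"].copy()
            b.state["var"] = data[f"bn{i}_var"].copy()
    return model


def model_summary(model) -> str:
    """Plain-text architecture summary (layer, parameter count)."""
    lines = [f"{type(model).__name__}  (total params: "
             f"{sum(p.data.size for p in model.parameters()):,})"]
    if isinstance(model, UNet):
        groups = ([("enc", b) for b in model.enc] + [("bottleneck", model.bottleneck)]
                  + [("up", u) for u in model.ups] + [("dec", b) for b in model.dec]
                  + [("head", model.head)])
    elif isinstance(model, NestedUNet):
        groups = [(f"node{k}", v) for k, v in sorted(model.blocks.items())]
        groups += [(f"up{k}", v) for k, v in sorted(model.upsamplers.items())]
        groups += [(f"head{j}", h) for j, h in sorted(model.heads.items())]
    else:
        groups = [(f"conv{i}", c) for i, c in enumerate(model.convs)]
        groups += [(f"bn{i}", b) for i, b in enumerate(model.bns)]
        groups += [("dense", model.fc)]
    for name, layer in groups:
        n = sum(p.data.size for p in layer.parameters())
        lines.append(f"  {name:<14} params={n:,}")
    return "\n".join(lines)
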