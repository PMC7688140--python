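"""Catalog of the CNN architectures used in the histology-expression analysis.

Each architecture is represented declaratively: an ordered table of the
elementary layers of its feature-extraction part (:class:`LayerSpec`) plus a
closed-form table of its weight-bearing layers, from which the number of
visual features ``f_lz`` (one per layer/channel pair under the
architecture-family eligibility conventions) and the number of trainable
parameters are computed exactly, without materializing any weights.

The families follow the torchvision layer layouts: VGG nets are sequences of
3x3 conv / (batchnorm) / ReLU triples with five max-pools; AlexNet uses its
classic five-conv stem; ResNet34 is the 3-4-6-3 basic-block net; Inception v3
is the stem + Mixed 5b-7c tower with an auxiliary classifier branch.

Feature-eligibility conventions
-------------------------------
* AlexNet / VGG variants: every layer of the feature-extraction part is a
  feature layer (conv, batchnorm, ReLU and pooling layers all counted).
* VGG16_avg1FC: the VGG16 convolutional part plus the appended global
  average-pool layer's 512 channels.
* ResNet34: layers inside residual blocks are "skipped over" (their outputs
  are added to a skip connection and do not form complete representations);
  only the stem ReLU/max-pool, each block's post-addition ReLU and the global
  average pool are counted.
* Inception v3: only elementary layers with non-negative outputs (ReLU,
  max/avg-pooling, including branch pools and the final global average pool)
  that are not on the auxiliary branch; concatenated block outputs are
  redundant re-listings of their branches and are not counted.

Small sequential architectures ("tiny" and the VGG/AlexNet family) can also
be materialized as trainable NumPy models via :meth:`ArchitectureSpec.materialize`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

#: layer kinds with guaranteed non-negative outputs when fed non-negative input
_NONNEG_KINDS = {"relu", "maxpool", "avgpool"}

SUPPORTED = (
    "alexnet", "vgg11", "vgg13", "vgg16", "vgg19",
    "vgg11_bn", "vgg13_bn", "vgg16_bn", "vgg19_bn",
    "resnet34", "inception_v3", "vgg16_1fc", "vgg16_avg1fc", "tiny",
)


@dataclass(frozen=True)
class LayerSpec:
    """One elementary layer of the feature-extraction part."""

    index: int
    kind: str                  # conv | relu | maxpool | avgpool | batchnorm | ...
    channels: int
    nonneg_output: bool = False
    on_aux_branch: bool = False
    skipped: bool = False

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")


@dataclass(frozen=True)
class FeatureIndex:
    """A single visual feature: channel ``z`` of layer ``l``, written 'l_z'."""

    layer: int
    channel: int

    @property
    def id(self) -> str:
        return f"{self.layer}_{self.channel}"

    @classmethod
    def parse(cls, feature_id: str) -> "FeatureIndex":
        l, z = feature_id.split("_")
        return cls(int(l), int(z))


# closed-form parameter entries: (kind, *shape)
def _conv_params(in_ch, out_ch, kh, kw=None, bias=True):
    kw = kh if kw is None else kw
    return out_ch * in_ch * kh * kw + (out_ch if bias else 0)


def _bn_params(ch):
    return 2 * ch  # scale + shift


def _linear_params(in_dim, out_dim):
    return in_dim * out_dim + out_dim


@dataclass
class ArchitectureSpec:
    name: str
    layers: list[LayerSpec]
    head: str
    num_classes: int
    param_count: int
    # recipe to materialize a trainable model; None for branching topologies
    _factory: object | None = field(default=None, repr=False)

    def materialize(self, seed: int = 0) -> nn.Sequential:
        """Instantiate the trainable NumPy model (sequential topologies only)."""
        if self._factory is None:
            raise NotImplementedError(
                f"{self.name} has a branching topology; only its layer table "
                "and parameter count are modeled, not an executable network"
            )
        return self._factory(np.random.default_rng(seed))


class _Builder:
    """Accumulates feature-part layer specs and a running parameter count."""

    def __init__(self):
        self.layers: list[LayerSpec] = []
        self.params = 0
        self._i = 0

    def add(self, kind, channels, nonneg=None, aux=False, skipped=False, params=0):
        nonneg = kind in _NONNEG_KINDS if nonneg is None else nonneg
        self.layers.append(LayerSpec(self._i, kind, channels, nonneg, aux, skipped))
        self._i += 1
        self.params += params


# ---------------------------------------------------------------------------
# VGG family
# ---------------------------------------------------------------------------

_VGG_CFG = {
    "vgg11": [64, "M", 128, "M", 256, 256, "M", 512, 512, "M", 512, 512, "M"],
    "vgg13": [64, 64, "M", 128, 128, "M", 256, 256, "M", 512, 512, "M", 512, 512, "M"],
    "vgg16": [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M"],
    "vgg19": [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
              512, 512, 512, 512, "M", 512, 512, 512, 512, "M"],
}


def _vgg_feature_part(b: _Builder, cfg: list, batchnorm: bool) -> int:
    in_ch = 3
    last = in_ch
    for item in cfg:
        if item == "M":
            b.add("maxpool", last)
        else:
            b.add("conv", item, params=_conv_params(in_ch, item, 3))
            if batchnorm:
                b.add("batchnorm", item, params=_bn_params(item))
            b.add("relu", item)
            in_ch = last = item
    return last


def _vgg_head(b: _Builder, num_classes: int):
    b.params += (_linear_params(512 * 7 * 7, 4096) + _linear_params(4096, 4096)
                 + _linear_params(4096, num_classes))


def _vgg_factory(cfg, num_classes, head="full"):
    def make(rng):
        layers: list[nn.Layer] = []
        in_ch = 3
        for item in cfg:
            if item == "M":
                layers.append(nn.MaxPool2d(2))
            else:
                layers.append(nn.Conv2d(in_ch, item, 3, pad=1, rng=rng))
                layers.append(nn.ReLU())
                in_ch = item
        if head == "full":
            layers += [nn.Flatten(),
                       nn.Linear(25088, 4096, rng=rng), nn.ReLU(), nn.Dropout(0.5, rng=rng),
                       nn.Linear(4096, 4096, rng=rng), nn.ReLU(), nn.Dropout(0.5, rng=rng),
                       nn.Linear(4096, num_classes, rng=rng)]
        elif head == "1fc":
            layers += [nn.Flatten(), nn.Dropout(0.5, rng=rng),
                       nn.Linear(25088, num_classes, rng=rng)]
        elif head == "avg1fc":
            layers += [nn.AvgPool2d(7), nn.Flatten(), nn.Dropout(0.5, rng=rng),
                       nn.Linear(512, num_classes, rng=rng)]
        return nn.Sequential(layers)
    return make


# ---------------------------------------------------------------------------
# AlexNet
# ---------------------------------------------------------------------------

def _alexnet(b: _Builder, num_classes: int):
    convs = [(3, 64, 11), (64, 192, 5), (192, 384, 3), (384, 256, 3), (256, 256, 3)]
    pool_after = {0, 1, 4}
    for i, (ci, co, k) in enumerate(convs):
        b.add("conv", co, params=_conv_params(ci, co, k))
        b.add("relu", co)
        if i in pool_after:
            b.add("maxpool", co)
    b.params += (_linear_params(256 * 6 * 6, 4096) + _linear_params(4096, 4096)
                 + _linear_params(4096, num_classes))


# ---------------------------------------------------------------------------
# ResNet34
# ---------------------------------------------------------------------------

def _resnet34(b: _Builder, num_classes: int):
    b.add("conv", 64, skipped=True, params=_conv_params(3, 64, 7, bias=False))
    b.add("batchnorm", 64, skipped=True, params=_bn_params(64))
    b.add("relu", 64)           # stem relu: a complete representation
    b.add("maxpool", 64)
    stages = [(64, 64, 3), (64, 128, 4), (128, 256, 6), (256, 512, 3)]
    for s, (in_ch, out_ch, blocks) in enumerate(stages):
        for blk in range(blocks):
            ci = in_ch if blk == 0 else out_ch
            b.add("conv", out_ch, skipped=True, params=_conv_params(ci, out_ch, 3, bias=False))
            b.add("batchnorm", out_ch, skipped=True, params=_bn_params(out_ch))
            b.add("relu", out_ch, skipped=True)
            b.add("conv", out_ch, skipped=True, params=_conv_params(out_ch, out_ch, 3, bias=False))
            b.add("batchnorm", out_ch, skipped=True, params=_bn_params(out_ch))
            if blk == 0 and s > 0:  # 1x1 projection on the skip path
                b.add("conv", out_ch, skipped=True, params=_conv_params(ci, out_ch, 1, bias=False))
                b.add("batchnorm", out_ch, skipped=True, params=_bn_params(out_ch))
            b.add("residual-add", out_ch, skipped=True)
            b.add("relu", out_ch)  # post-addition relu: complete representation
    b.add("avgpool", 512)
    b.params += _linear_params(512, num_classes)


# ---------------------------------------------------------------------------
# Inception v3
# ---------------------------------------------------------------------------

def _inc_conv(b, in_ch, out_ch, kh, kw=None, aux=False):
    """BasicConv2d: bias-free conv + batchnorm + ReLU."""
    kw = kh if kw is None else kw
    b.add("conv", out_ch, aux=aux, params=_conv_params(in_ch, out_ch, kh, kw, bias=False))
    b.add("batchnorm", out_ch, aux=aux, params=_bn_params(out_ch))
    b.add("relu", out_ch, aux=aux)


def _inception_v3(b: _Builder, num_classes: int):
    _inc_conv(b, 3, 32, 3)
    _inc_conv(b, 32, 32, 3)
    _inc_conv(b, 32, 64, 3)
    b.add("maxpool", 64)
    _inc_conv(b, 64, 80, 1)
    _inc_conv(b, 80, 192, 3)
    b.add("maxpool", 192)

    def block_a(in_ch, pool_feat):
        _inc_conv(b, in_ch, 64, 1)
        _inc_conv(b, in_ch, 48, 1)
        _inc_conv(b, 48, 64, 5)
        _inc_conv(b, in_ch, 64, 1)
        _inc_conv(b, 64, 96, 3)
        _inc_conv(b, 96, 96, 3)
        b.add("avgpool", in_ch)
        _inc_conv(b, in_ch, pool_feat, 1)
        out = 64 + 64 + 96 + pool_feat
        b.add("concat", out, nonneg=True, skipped=True)  # redundant re-listing
        return out

    def block_b(in_ch):
        _inc_conv(b, in_ch, 384, 3)
        _inc_conv(b, in_ch, 64, 1)
        _inc_conv(b, 64, 96, 3)
        _inc_conv(b, 96, 96, 3)
        b.add("maxpool", in_ch)
        out = 384 + 96 + in_ch
        b.add("concat", out, nonneg=True, skipped=True)
        return out

    def block_c(in_ch, c7):
        _inc_conv(b, in_ch, 192, 1)
        _inc_conv(b, in_ch, c7, 1)
        _inc_conv(b, c7, c7, 1, 7)
        _inc_conv(b, c7, 192, 7, 1)
        _inc_conv(b, in_ch, c7, 1)
        _inc_conv(b, c7, c7, 7, 1)
        _inc_conv(b, c7, c7, 1, 7)
        _inc_conv(b, c7, c7, 7, 1)
        _inc_conv(b, c7, 192, 1, 7)
        b.add("avgpool", in_ch)
        _inc_conv(b, in_ch, 192, 1)
        b.add("concat", 768, nonneg=True, skipped=True)
        return 768

    def block_d(in_ch):
        _inc_conv(b, in_ch, 192, 1)
        _inc_conv(b, 192, 320, 3)
        _inc_conv(b, in_ch, 192, 1)
        _inc_conv(b, 192, 192, 1, 7)
        _inc_conv(b, 192, 192, 7, 1)
        _inc_conv(b, 192, 192, 3)
        b.add("maxpool", in_ch)
        out = 320 + 192 + in_ch
        b.add("concat", out, nonneg=True, skipped=True)
        return out

    def block_e(in_ch):
        _inc_conv(b, in_ch, 320, 1)
        _inc_conv(b, in_ch, 384, 1)
        _inc_conv(b, 384, 384, 1, 3)
        _inc_conv(b, 384, 384, 3, 1)
        _inc_conv(b, in_ch, 448, 1)
        _inc_conv(b, 448, 384, 3)
        _inc_conv(b, 384, 384, 1, 3)
        _inc_conv(b, 384, 384, 3, 1)
        b.add("avgpool", in_ch)
        _inc_conv(b, in_ch, 192, 1)
        b.add("concat", 2048, nonneg=True, skipped=True)
        return 2048

    ch = block_a(192, 32)     # Mixed 5b -> 256
    ch = block_a(ch, 64)      # Mixed 5c -> 288
    ch = block_a(ch, 64)      # Mixed 5d -> 288
    ch = block_b(ch)          # Mixed 6a -> 768
    ch = block_c(ch, 128)     # Mixed 6b
    ch = block_c(ch, 160)     # Mixed 6c
    ch = block_c(ch, 160)     # Mixed 6d
    ch = block_c(ch, 192)     # Mixed 6e
    # auxiliary classifier branch (trainable, excluded from features)
    b.add("avgpool", 768, aux=True)
    _inc_conv(b, 768, 128, 1, aux=True)
    _inc_conv(b, 128, 768, 5, aux=True)
    b.params += _linear_params(768, num_classes)
    ch = block_d(768)         # Mixed 7a -> 1280
    ch = block_e(ch)          # Mixed 7b -> 2048
    ch = block_e(ch)          # Mixed 7c -> 2048
    b.add("avgpool", 2048)    # global average pool
    b.params += _linear_params(2048, num_classes)


# ---------------------------------------------------------------------------
# tiny: a fixed 3-block net for desk-scale experiments
# ---------------------------------------------------------------------------

#: fixed 2x average-pool stem (raw-color features at 112^2), then three
#: conv/relu/maxpool blocks: 112 -> 56 -> 14 -> 7
TINY_BLOCKS = [(3, 8, 2), (8, 16, 4), (16, 32, 2)]  # (in_ch, out_ch, pool)
TINY_FLAT = 32 * 7 * 7


def _tiny(b: _Builder, num_classes: int):
    # the stem pool averages the signed normalized image, so its output is
    # not non-negative (unlike pools that follow ReLUs)
    b.add("avgpool", 3, nonneg=False)
    for in_ch, out_ch, _pool in TINY_BLOCKS:
        b.add("conv", out_ch, params=_conv_params(in_ch, out_ch, 3))
        b.add("relu", out_ch)
        b.add("maxpool", out_ch)
    b.params += _linear_params(TINY_FLAT, num_classes)


def _tiny_factory(num_classes):
    def make(rng):
        layers: list[nn.Layer] = [nn.AvgPool2d(2)]
        for in_ch, out_ch, pool in TINY_BLOCKS:
            layers.append(nn.Conv2d(in_ch, out_ch, 3, pad=1, rng=rng))
            layers.append(nn.ReLU())
            layers.append(nn.MaxPool2d(pool))
        layers += [nn.Flatten(), nn.Linear(TINY_FLAT, num_classes, rng=rng)]
        return nn.Sequential(layers)
    return make


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def build_architecture(name: str, num_classes: int) -> ArchitectureSpec:
    """Build the layer table (and, for sequential nets, a trainable model
    factory) for ``name`` adapted to ``num_classes`` output classes."""
    if name not in SUPPORTED:
        raise ValueError(f"unknown architecture {name!r}; supported: {', '.join(SUPPORTED)}")
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    b = _Builder()
    factory = None
    if name == "alexnet":
        _alexnet(b, num_classes)
        head = "Linear(9216,4096); ReLU; Dropout; Linear(4096,4096); ReLU; Linear(4096,C)"
    elif name in _VGG_CFG or name.removesuffix("_bn") in _VGG_CFG:
        base = name.removesuffix("_bn")
        batchnorm = name.endswith("_bn")
        _vgg_feature_part(b, _VGG_CFG[base], batchnorm)
        _vgg_head(b, num_classes)
        head = "Linear(25088,4096); ReLU; Dropout; Linear(4096,4096); ReLU; Dropout; Linear(4096,C)"
        if not batchnorm:
            factory = _vgg_factory(_VGG_CFG[base], num_classes)
    elif name == "vgg16_1fc":
        _vgg_feature_part(b, _VGG_CFG["vgg16"], batchnorm=False)
        b.params += _linear_params(25088, num_classes)
        head = "Dropout(0.5); Linear(25088,C)"
        factory = _vgg_factory(_VGG_CFG["vgg16"], num_classes, head="1fc")
    elif name == "vgg16_avg1fc":
        _vgg_feature_part(b, _VGG_CFG["vgg16"], batchnorm=False)
        b.add("avgpool", 512)   # global 7x7 average pool, a feature layer
        b.params += _linear_params(512, num_classes)
        head = "Dropout(0.5); Linear(512,C)"
        factory = _vgg_factory(_VGG_CFG["vgg16"], num_classes, head="avg1fc")
    elif name == "resnet34":
        _resnet34(b, num_classes)
        head = "Linear(512,C)"
    elif name == "inception_v3":
        _inception_v3(b, num_classes)
        head = "Linear(2048,C) + aux Linear(768,C)"
    elif name == "tiny":
        _tiny(b, num_classes)
        head = f"Flatten; Linear({TINY_FLAT},C)"
        factory = _tiny_factory(num_classes)
    return ArchitectureSpec(name, b.layers, head, num_classes, b.params, factory)


def enumerate_features(spec: ArchitectureSpec) -> list[FeatureIndex]:
    """All features f_lz of ``spec`` under its family's eligibility rules."""
    feats: list[FeatureIndex] = []
    for layer in spec.layers:
        if spec.name == "inception_v3":
            ok = (layer.kind in _NONNEG_KINDS and layer.nonneg_output
                  and not layer.on_aux_branch and not layer.skipped)
        elif spec.name == "resnet34":
            ok = not layer.skipped
        else:
            ok = layer.kind != "dropout"
        if ok:
            feats.extend(FeatureIndex(layer.index, z) for z in range(layer.channels))
    return feats


def count_parameters(model) -> int:
    """Trainable scalar count of an ArchitectureSpec or a materialized model."""
    if isinstance(model, ArchitectureSpec):
        return model.param_count
    return model.n_params


def describe(name: str, num_classes: int) -> dict:
    """JSON-ready catalog entry for one architecture."""
    spec = build_architecture(name, num_classes)
    return {
        "name": name,
        "num_classes": num_classes,
        "n_feature_layers": len(spec.layers),
        "n_features": len(enumerate_features(spec)),
        "n_parameters": spec.param_count,
        "head": spec.head,
        "layers": [
            {"index": l.index, "kind": l.kind, "channels": l.channels,
             "nonneg_output": l.nonneg_output, "aux": l.on_aux_branch,
             "skipped": l.skipped}
            for l in spec.layers
        ],
    }
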