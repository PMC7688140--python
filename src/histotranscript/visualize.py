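"""Feature visualization: guided backpropagation, activation maximization,
and representative-tile selection.

Guided backpropagation computes the gradient of a feature scalar with
respect to the input image while, at every ReLU, zeroing the propagated
gradient wherever the forward input was non-positive OR the incoming
gradient negative; on a ReLU-free network it equals the plain gradient.

Activation maximization synthesizes an input by gradient ascent on the
feature scalar from seeded random noise, with the usual regularizers (pixel
jitter, periodic Gaussian blur, an L2 penalty and clamping to the normalized
range of valid 8-bit inputs). The feature scalar in both cases is the same
aggregate f_lz (spatial sum, p = 1) that is correlated with gene expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import nn
from .tiler import IMAGENET_MEAN, IMAGENET_STD, denormalize
from .zoo import ArchitectureSpec, FeatureIndex


@dataclass
class GradientImage:
    """Signed per-pixel gradient of a feature w.r.t. the input (3 x H x W)."""

    values: np.ndarray
    feature: str


def _as_feature(feature) -> FeatureIndex:
    return FeatureIndex.parse(feature) if isinstance(feature, str) else feature


def _feature_value_and_seed(model: nn.Sequential, feat: FeatureIndex,
                            x: np.ndarray) -> tuple[float, np.ndarray]:
    if feat.layer >= len(model.layers):
        raise ValueError(f"layer {feat.layer} is beyond the model's {len(model.layers)} layers")
    # forward only up to the feature layer: deeper layers are irrelevant to
    # f_lz, and inputs of non-standard size need not fit the classifier head
    a = x
    for layer in model.layers[: feat.layer + 1]:
        a = layer.forward(a, train=False)
    if feat.channel >= a.shape[1]:
        raise ValueError(f"channel {feat.channel} out of range for layer {feat.layer}")
    grad = np.zeros_like(a)
    grad[:, feat.channel] = 1.0     # d(sum of channel map)/dY
    return float(a[:, feat.channel].sum()), grad


def guided_backprop(model: nn.Sequential, feature, x: np.ndarray) -> GradientImage:
    """Guided-backpropagation saliency of f_lz for a prepared input tile.

    ``x`` is (3, H, W) or (1, 3, H, W) as produced by the tiler.
    """
    feat = _as_feature(feature)
    xb = x[None] if x.ndim == 3 else x
    _, seed_grad = _feature_value_and_seed(model, feat, xb)
    g = model.backward(seed_grad, guided=True, from_layer=feat.layer)
    return GradientImage(g[0], feat.id)


def input_gradient(model: nn.Sequential, feature, x: np.ndarray) -> GradientImage:
    """Plain (unguided) gradient of f_lz w.r.t. the input."""
    feat = _as_feature(feature)
    xb = x[None] if x.ndim == 3 else x
    _, seed_grad = _feature_value_and_seed(model, feat, xb)
    g = model.backward(seed_grad, guided=False, from_layer=feat.layer)
    return GradientImage(g[0], feat.id)


def render_gradient(grad: GradientImage) -> np.ndarray:
    """Render a signed gradient as 8-bit RGB: affine rescale centered so that
    zero gradient maps to mid-gray. Deterministic; all-zero input gives a
    uniform mid-gray image."""
    v = np.asarray(grad.values if isinstance(grad, GradientImage) else grad,
                   dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("gradient contains non-finite values")
    m = np.abs(v).max()
    scaled = 0.5 if m == 0 else 0.5 + v / (2.0 * m)
    img = np.clip(np.round(np.asarray(scaled) * 255.0), 0, 255).astype(np.uint8)
    if img.ndim == 0:
        img = np.full_like(v, 128, dtype=np.uint8)
    return img.transpose(1, 2, 0)


@dataclass
class SynthImageConfig:
    steps: int = 256
    step_size: float = 0.05        # in normalized input units
    seed: int = 0
    jitter: int = 2                # +-pixels of random roll per step
    blur_every: int = 4            # Gaussian blur interval (steps)
    blur_sigma: float = 0.5
    l2_weight: float = 1e-4
    size: int = 224

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass
class SynthImageResult:
    x: np.ndarray                  # final normalized input, 3 x H x W
    trajectory: pd.DataFrame       # step, feature_value

    @property
    def image(self) -> np.ndarray:
        return denormalize(self.x)


def activation_maximization(model: nn.Sequential, feature,
                            config: SynthImageConfig = SynthImageConfig()
                            ) -> SynthImageResult:
    """Synthesize argmax_X f(X) by regularized gradient ascent.

    Starts from seeded Gaussian noise; each step jitters the image, ascends
    along the (plain) input gradient of the feature minus an L2 pull toward
    zero, un-jitters, periodically blurs, and clamps channels to the
    normalized range of valid 8-bit inputs. The feature-value trajectory is
    recorded; non-finite values abort with a diagnostic.
    """
    feat = _as_feature(feature)
    rng = np.random.default_rng(config.seed)
    lo = ((0.0 - IMAGENET_MEAN) / IMAGENET_STD).reshape(3, 1, 1)
    hi = ((1.0 - IMAGENET_MEAN) / IMAGENET_STD).reshape(3, 1, 1)
    x = rng.normal(0.0, 0.1, (1, 3, config.size, config.size)).astype(np.float32)
    x = np.clip(x, lo, hi)
    traj = []
    for step in range(config.steps + 1):
        # trajectory logs the feature on the un-jittered current image
        fval, _ = _feature_value_and_seed(model, feat, x)
        if not np.isfinite(fval):
            raise RuntimeError(f"activation maximization diverged at step {step}: "
                               f"feature value {fval}")
        traj.append({"step": step, "feature_value": fval})
        if step == config.steps:
            break
        shift = (rng.integers(-config.jitter, config.jitter + 1, 2)
                 if config.jitter else np.zeros(2, dtype=int))
        xs = np.roll(x, shift, axis=(2, 3))
        _, seed_grad = _feature_value_and_seed(model, feat, xs)
        g = model.backward(seed_grad, guided=False, from_layer=feat.layer)
        g = np.roll(g, -shift, axis=(2, 3))
        g -= 2.0 * config.l2_weight * x
        norm = np.sqrt(np.mean(g ** 2)) + 1e-8
        x = x + config.step_size * g / norm
        if config.blur_every and (step + 1) % config.blur_every == 0:
            x = gaussian_filter(x, sigma=(0, 0, config.blur_sigma, config.blur_sigma))
        x = np.clip(x, lo, hi).astype(np.float32)
    return SynthImageResult(x[0], pd.DataFrame(traj))


def select_representative_tiles(tile_features: pd.DataFrame, feature: str,
                                k: int, per_slide_cap: int | None = None,
                                slide_of=None) -> list[str]:
    """Top-k tiles by feature value, at most ``per_slide_cap`` per slide.

    ``tile_features`` is the tile-level feature matrix (rows = tile ids of
    the form ``{slide}_{gx}_{gy}``); ties are broken by tile id, so the
    selection is deterministic. This greedy rule stands in for a
    representative-tile selection step whose published description is not
    available.
    """
    vals = tile_features[feature]
    if slide_of is None:
        slide_of = {t: str(t).rsplit("_", 2)[0] for t in vals.index}
    order = sorted(vals.index, key=lambda t: (-vals[t], str(t)))
    chosen: list[str] = []
    per_slide: dict[str, int] = {}
    for t in order:
        if len(chosen) == k:
            break
        s = slide_of[t]
        if per_slide_cap is not None and per_slide.get(s, 0) >= per_slide_cap:
            continue
        chosen.append(t)
        per_slide[s] = per_slide.get(s, 0) + 1
    return chosen
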