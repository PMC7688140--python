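"""Location-invariant feature quantification: f_lz = sum over space of Y_lz^p.

A feature is one (layer, channel) pair of the network's feature-extraction
part. For an input tile X, the feature value is the spatial sum of that
channel's activation map raised to the exponent p (p = 1 by default, which is
the spatial average up to the constant map area); for a whole slide W the
tile values are summed over W's tiles, making the quantity additive over any
partition of the slide.

Materialized models built by the zoo share layer numbering with their
ArchitectureSpec, so activations are captured at the spec's layer indices
(each layer's output, post-nonlinearity).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import nn
from .zoo import ArchitectureSpec, FeatureIndex, enumerate_features


def _feature_layers(spec: ArchitectureSpec, layers="all") -> dict[int, list[int]]:
    """Map eligible layer index -> channel list, optionally restricted."""
    feats = enumerate_features(spec)
    if layers != "all":
        wanted = set(layers)
        feats = [f for f in feats if f.layer in wanted]
    by_layer: dict[int, list[int]] = {}
    for f in feats:
        by_layer.setdefault(f.layer, []).append(f.channel)
    return by_layer


def feature_ids(spec: ArchitectureSpec, layers="all") -> list[str]:
    return [FeatureIndex(l, z).id
            for l, chans in _feature_layers(spec, layers).items() for z in chans]


def tile_features(model: nn.Sequential, spec: ArchitectureSpec,
                  x: np.ndarray, p: int = 1, layers="all") -> np.ndarray:
    """Feature vectors for a batch of prepared inputs.

    ``x`` is (N, 3, H, W); returns (N, n_features) in :func:`feature_ids`
    order. Non-integer p is undefined on layers that can go negative and
    raises there; integer p is allowed everywhere.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    by_layer = _feature_layers(spec, layers)
    if p != int(p):
        spec_layers = {l.index: l for l in spec.layers}
        bad = [l for l in by_layer if not spec_layers[l].nonneg_output]
        if bad:
            raise ValueError(
                f"non-integer p={p} is undefined on layers with negative "
                f"activations: {bad}")
    _, acts = model.forward(x, train=False, capture=set(by_layer))
    cols = []
    for l, chans in by_layer.items():
        a = acts[l][:, chans]
        if a.ndim == 2:          # post-flatten layer: already one value/channel
            a = a[..., None]
        a = a.astype(np.float64)
        vals = (a if p == 1 else a ** p).reshape(a.shape[0], len(chans), -1).sum(axis=2)
        cols.append(vals)
    return np.concatenate(cols, axis=1)


def slide_features(tile_feature_vectors: np.ndarray) -> np.ndarray:
    """Aggregate tile-level vectors of one slide: the per-feature sum."""
    tile_feature_vectors = np.asarray(tile_feature_vectors)
    if tile_feature_vectors.ndim != 2 or len(tile_feature_vectors) == 0:
        raise ValueError("expected a non-empty (n_tiles, n_features) array")
    return tile_feature_vectors.sum(axis=0)


def tile_feature_matrix(model: nn.Sequential, spec: ArchitectureSpec,
                        x: np.ndarray, tile_ids: list[str], p: int = 1,
                        layers="all", batch: int = 16) -> pd.DataFrame:
    """Tile-level feature matrix (rows = tiles, columns = 'l_z' ids)."""
    out = [tile_features(model, spec, x[i:i + batch], p, layers)
           for i in range(0, len(x), batch)]
    return pd.DataFrame(np.concatenate(out, axis=0), index=tile_ids,
                        columns=feature_ids(spec, layers), dtype=float)


def build_feature_matrix(model: nn.Sequential, spec: ArchitectureSpec,
                         x: np.ndarray, slide_ids: list[str], p: int = 1,
                         layers="all", batch: int = 16) -> pd.DataFrame:
    """Slide-level feature matrix: tile features summed per slide.

    ``x`` holds prepared tiles, ``slide_ids`` the owning slide of each tile.
    Rows are keyed by slide_id (first-appearance order); slides contributing
    zero tiles are simply absent (callers warn when they drop slides
    upstream). Deterministic given the model weights.
    """
    tiles = tile_feature_matrix(model, spec, x,
                                tile_ids=list(range(len(x))), p=p,
                                layers=layers, batch=batch)
    groups = pd.Index(slide_ids)
    mat = tiles.groupby(groups.take(tiles.index), sort=False).sum()
    missing = [s for s in dict.fromkeys(slide_ids) if s not in mat.index]
    if missing:
        warnings.warn(f"slides with no tiles dropped from feature matrix: {missing}")
    mat.index.name = "slide_id"
    return mat
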