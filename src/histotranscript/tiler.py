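"""Whole-slide image tiling, tissue filtering and model-input preparation.

A slide raster (assumed already at the target magnification, ~1 micron per
pixel) is cut into a non-overlapping grid of square tiles; partial edge tiles
are dropped. Tiles dominated by background (near-white pixels) are removed,
and surviving tiles are resized to the 224x224 network input and normalized
with the conventional ImageNet channel statistics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

#: a pixel whose darkest channel is at least this bright is called background
BACKGROUND_BRIGHTNESS = 220


@dataclass
class SlideRecord:
    slide_id: str
    tissue: str
    image: np.ndarray | None = None      # HxWx3 uint8
    path: str | None = None
    mpp: float = 0.9884
    split: str = "unassigned"

    def load(self) -> np.ndarray:
        if self.image is None:
            self.image = np.asarray(Image.open(self.path).convert("RGB"))
        return self.image


@dataclass
class Tile:
    slide_id: str
    grid_x: int
    grid_y: int
    pixels: np.ndarray                    # TxTx3 uint8
    label: str
    tissue_fraction: float = field(default=np.nan)

    @property
    def tile_id(self) -> str:
        return f"{self.slide_id}_{self.grid_x}_{self.grid_y}"


def extract_tiles(slide: SlideRecord, tile_size: int = 512) -> list[Tile]:
    """Cut the slide into the full grid of square ``tile_size`` tiles.

    Grid coordinates are 0-based with pixel origin at the top-left; tile
    (gx, gy) covers the half-open window [gx*T, (gx+1)*T) x [gy*T, (gy+1)*T)
    in (column, row) pixel coordinates. Non-square remainders at the right
    and bottom edges are discarded, so an image smaller than one tile yields
    an empty list.
    """
    img = slide.load()
    h, w = img.shape[:2]
    t = tile_size
    tiles = []
    for gy in range(h // t):
        for gx in range(w // t):
            px = img[gy * t:(gy + 1) * t, gx * t:(gx + 1) * t]
            tiles.append(Tile(slide.slide_id, gx, gy, px, slide.tissue))
    return tiles


def tissue_fraction(tile: Tile | np.ndarray,
                    background_brightness: int = BACKGROUND_BRIGHTNESS) -> float:
    """Fraction of pixels classified as tissue (i.e. not near-white).

    Background is defined as min(R, G, B) >= ``background_brightness``; any
    stained pixel darkens at least one channel and is counted as tissue.
    """
    px = tile.pixels if isinstance(tile, Tile) else tile
    bg = px.min(axis=-1) >= background_brightness
    return float(1.0 - bg.mean())


def filter_tiles(tiles: list[Tile], min_fraction: float = 0.5,
                 background_brightness: int = BACKGROUND_BRIGHTNESS) -> list[Tile]:
    """Keep tiles with at least ``min_fraction`` tissue (strictly-less removed)."""
    kept = []
    for tile in tiles:
        if np.isnan(tile.tissue_fraction):
            tile.tissue_fraction = tissue_fraction(tile, background_brightness)
        if tile.tissue_fraction >= min_fraction:
            kept.append(tile)
    return kept


def prepare_input(tile: Tile | np.ndarray, out_size: int = 224) -> np.ndarray:
    """Resize a square tile to the network input and normalize it.

    Bilinear (antialiased) resize to ``out_size``, then per-channel
    (value/255 - mean)/std with the ImageNet constants. Returns a CHW
    float32 array.
    """
    px = tile.pixels if isinstance(tile, Tile) else tile
    if px.shape[0] != px.shape[1]:
        raise ValueError(f"tile must be square, got {px.shape[:2]}")
    x = px.astype(np.float32) / 255.0
    if px.shape[0] != out_size:
        x = resize(x, (out_size, out_size), order=1, anti_aliasing=True,
                   preserve_range=True).astype(np.float32)
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def denormalize(x: np.ndarray) -> np.ndarray:
    """Invert :func:`prepare_input` normalization back to uint8 HWC."""
    img = x.transpose(1, 2, 0) * IMAGENET_STD + IMAGENET_MEAN
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def read_slide_manifest(path: str) -> list[SlideRecord]:
    """Slide manifest TSV with columns slide_id, path, tissue[, split]."""
    df = pd.read_csv(path, sep="\t")
    root = os.path.dirname(os.path.abspath(path))
    slides = []
    for row in df.itertuples():
        p = row.path if os.path.isabs(row.path) else os.path.join(root, row.path)
        slides.append(SlideRecord(str(row.slide_id), str(row.tissue), path=p,
                                  split=getattr(row, "split", "unassigned")))
    return slides


def tile_slides(slides: list[SlideRecord], tile_size: int = 512,
                min_fraction: float = 0.5, out_dir: str | None = None) -> tuple[list[Tile], pd.DataFrame]:
    """Tile and filter every slide; optionally write tile PNGs named
    ``{slide_id}_{gx}_{gy}.png`` plus a tile manifest."""
    all_tiles: list[Tile] = []
    rows = []
    for slide in slides:
        tiles = filter_tiles(extract_tiles(slide, tile_size), min_fraction)
        for tile in tiles:
            rows.append({"tile_id": tile.tile_id, "slide_id": slide.slide_id,
                         "grid_x": tile.grid_x, "grid_y": tile.grid_y,
                         "tissue": slide.tissue, "split": slide.split,
                         "tissue_fraction": tile.tissue_fraction})
            if out_dir is not None:
                Image.fromarray(tile.pixels).save(
                    os.path.join(out_dir, tile.tile_id + ".png"))
        all_tiles.extend(tiles)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "tiles.tsv"), sep="\t", index=False)
    return all_tiles, manifest
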