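"""Tile a synthetic slide, apply the 50% tissue filter, and prepare inputs.

Slides are cut into a non-overlapping 512x512 grid (partial edge tiles
dropped); a tile is kept when at least half its pixels are tissue (darker
than the near-white background threshold). Kept tiles are resized to
224x224 and normalized with the ImageNet channel statistics.
"""

import numpy as np

from histotranscript import synthetic, tiler

latents = synthetic.sample_latents(0, np.random.default_rng(0))
img = synthetic.make_tissue_image(0, latents, size=1030, seed=0)
slide = tiler.SlideRecord("demo", "glandular", image=img)

tiles = tiler.extract_tiles(slide, tile_size=512)
print(f"slide {img.shape[1]}x{img.shape[0]} -> {len(tiles)} full tiles "
      "(edge remainders dropped)")

kept = tiler.filter_tiles(tiles, min_fraction=0.5)
for t in tiles:
    print(f"  tile ({t.grid_x},{t.grid_y}): tissue fraction {t.tissue_fraction:.3f}")
print(f"{len(kept)} tiles pass the 50% tissue filter")

x = tiler.prepare_input(kept[0])
print(f"prepared input: shape {x.shape}, per-channel means "
      f"{np.round(x.mean(axis=(1, 2)), 3)} (normalized units)")
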