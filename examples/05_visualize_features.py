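"""Explain a visual feature: guided backpropagation and a synthetic
maximizing image.

Guided backpropagation highlights the input pixels driving a feature
(zeroing, at every ReLU, gradients where the forward input was non-positive
or the incoming gradient negative). Activation maximization synthesizes,
from seeded noise, an image that maximizes the feature by regularized
gradient ascent.
"""

import numpy as np

from histotranscript import synthetic, tiler, visualize, zoo
from histotranscript.visualize import SynthImageConfig

spec = zoo.build_architecture("tiny", 4)
model = spec.materialize(seed=0)

latents = synthetic.sample_latents(0, np.random.default_rng(3))
img = synthetic.make_tissue_image(0, latents, size=512, seed=3)
x = tiler.prepare_input(img)

feature = "4_3"   # channel 3 of the second conv layer
gbp = visualize.guided_backprop(model, feature, x)
render = visualize.render_gradient(gbp)
print(f"guided backprop of {feature}: gradient {gbp.values.shape}, "
      f"rendered {render.shape} uint8 (zero gradient -> mid-gray 128)")
print(f"  nonzero-gradient pixels: {(np.abs(gbp.values) > 0).mean():.1%}")

res = visualize.activation_maximization(
    model, feature, SynthImageConfig(steps=64, seed=5))
t = res.trajectory["feature_value"]
print(f"activation maximization: feature value {t.iloc[0]:.1f} -> {t.iloc[-1]:.1f} "
      f"over {len(t) - 1} steps; image {res.image.shape} uint8")

tf_demo = visualize.select_representative_tiles
print("representative tiles are picked with", tf_demo.__name__,
      "(top-k by feature value with a per-slide cap)")
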