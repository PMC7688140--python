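"""Enumerate visual features f_lz and count trainable parameters for the
CNN tissue-classifier architectures.

A feature is one (layer, channel) pair of the feature-extraction part,
written "layer_channel" (e.g. 29_499 = channel 499 of VGG16's layer 29).
Feature eligibility follows each family's convention: every feature-part
layer for AlexNet/VGG, non-skipped layers for ResNet34, and elementary
non-negative layers off the auxiliary branch for Inception v3.
"""

from histotranscript import zoo

print(f"{'network':14s} {'features f_lz':>14s} {'parameters':>14s}")
for name in zoo.SUPPORTED:
    spec = zoo.build_architecture(name, num_classes=39)
    n_feat = len(zoo.enumerate_features(spec))
    print(f"{name:14s} {n_feat:>14,d} {spec.param_count:>14,d}")

print("\nEach row is computed from the declared layer table: the feature "
      "count is the sum of eligible layer channel counts, and the parameter "
      "count the exact sum of weight and bias scalars at 39 output classes.")
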