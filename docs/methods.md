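# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Pipeline

A run executes five stages on paired (slide image, expression) data:

1. **Tile.** Each slide raster (assumed already at the target magnification,
   ≈1 µm/px) is cut into a non-overlapping grid of 512×512 tiles with
   0-based, half-open pixel windows in row-major order; partial edge tiles
   are discarded. A tile is kept when at least `min_tissue = 0.5` of its
   pixels are tissue. Because no operational definition of "tissue pixel"
   accompanies the 50% rule in the source data, we use a brightness rule:
   background = `min(R,G,B) ≥ 220` (near-white); any stained pixel darkens
   at least one channel. The threshold is exposed in the API. Kept tiles are
   resized to 224×224 (bilinear with antialiasing — the resize filter is
   otherwise unspecified, so one is fixed for reproducibility) and
   normalized per channel with the conventional ImageNet statistics,
   means (0.485, 0.456, 0.406) and SDs (0.229, 0.224, 0.225).
2. **Split and train.** Splits are 60/20/20 (train/validation/test) at the
   *slide* level, stratified per tissue with largest-remainder rounding, so
   no tile of a held-out slide can reach a training batch. Training uses
   momentum SGD (momentum 0.9, weight decay 1e-4 — the optimizer beyond the
   learning-rate schedule is a package choice, logged in the config) with
   initial learning rate 0.01 divided by 10 every 30 epochs, 90 epochs at
   full scale. The checkpoint with the best validation tile accuracy is
   kept (ties → earliest epoch); the test split is never consulted. Whole
   slides are classified by majority vote over tile predictions; vote ties
   are broken by summed softmax scores, then lowest class index.
3. **Quantify.** Features `f_lz` are spatial sums of layer activations
   captured at each enumerated layer's output (post-nonlinearity), with
   global exponent `p = 1`; slide values are sums over the slide's tiles
   (exactly additive over tile partitions). Feature sums accumulate in
   float64 so they match an exact summation oracle to 1e-6 relative even on
   112² maps. Inference is deterministic and batch-composition invariant.
4. **Correlate.** Expression is transformed to `log2(1+E)`; duplicate
   samples per slide are averaged on that log scale (deterministic and
   variance-reducing; the resolution rule is a package choice). Genes pass
   when their maximum per-tissue median reaches `E_T` — the boundary is
   inclusive, and a gene just below (e.g. a median of 6.84 against a
   threshold of 7) is excluded. Pearson correlations are computed on the
   test split only; pairs with `|r| ≥ R_T` are selected (absolute value by
   default; a signed mode exists because the sign convention is a genuinely
   open choice). Permutation p-values use the +1 correction; supplementary
   Benjamini–Hochberg q-values are reported as a labeled extension, not
   used for selection.
5. **Conditional independence.** `g ⊥ f | t` uses the partial correlation
   after least-squares residualization on tissue indicators (algebraically
   identical to within-group centering; the identity is tested to 1e-10)
   with a t-test on `n − 2 − k` degrees of freedom, `k = #tissues − 1`.
   For `f ⊥ t | g` and `g ⊥ t | f`, tissue is categorical, so the indicator
   block is tested jointly with an F-statistic after removing the scalar
   covariate. A pair is flagged indirect when the corresponding test fails
   to reject at level α (default 0.01); α = 0 is treated as the degenerate
   level at which nothing is flagged. Pairs with constant inputs are
   excluded from all counts.

## Architecture catalog

Feature and parameter counts for the thirteen published 39-class
architectures are computed in closed form from declarative layer tables;
the counts for every AlexNet/VGG variant and both reduced-head VGG16
variants, and the trainable-parameter counts of all thirteen, reproduce the
published table exactly. Eligibility conventions: AlexNet/VGG count every
feature-part layer (conv, batchnorm, ReLU, pooling); VGG16_avg1FC adds the
global average pool's 512 channels; Inception v3 counts only elementary
non-negative layers (ReLU and pools, including branch pools and the final
global average pool) off the auxiliary branch, which reproduces its
published feature count of 27,712; ResNet34 counts the stem ReLU/max-pool,
post-addition ReLUs and the global average pool (4,416 features). The
ResNet34 eligible-layer list is not published; our reading does not
reproduce its printed feature count, and that count is deliberately not a
verified quantity here.

The network engine is a self-contained NumPy implementation (im2col
convolution in channels-last layout, reshape-based pooling, momentum SGD,
reverse-mode gradients with a guided ReLU mode). Sequential topologies
(AlexNet, the VGG family, tiny) are materializable and trainable; the
branching ResNet34/Inception v3 exist as layer tables for counting only.
The `tiny` architecture — a fixed 2× average-pool stem (so convolutions run
at 112² and below on one CPU) followed by three conv/ReLU/max-pool blocks
(8, 16, 32 channels) and one linear head; 171 features, 67,223 parameters
at 4 classes — is the versioned desk-scale model.

## Synthetic data generator

The generator emulates the *statistical* structure the analysis assumes,
not histological realism. Each tissue class has a distinct cell palette and
packing regime; per-slide continuous latents (cell radius in px, cell
density per 10⁴ px², hue shift in 8-bit units) vary within class with SDs
(1.5, 7, 10). Slides are rendered as overlapping disk "cells" with ±20%
per-cell radius jitter and mild per-cell staining variation on a white
background, plus Gaussian pixel noise (SD 3). Class densities
(55, 60, 38, 60 for the default four classes) are sized so that slide
coverage stays above the 50% tissue filter even for unlucky latent draws.

Gene expression on the log2 scale: direct genes are linear in the
standardized realized target latent with amplitude 1.5 and noise SD 0.7265,
giving a planted gene–latent correlation of 0.9 (ρ = a·sd/√(a²·var + σ²));
direct genes target cell density and cell radius, whose visual footprint
(coverage) is first order — hue is kept as a nuisance latent because at
realistic amplitudes it is second-order relative to coverage variation and
interferes with class palettes. Tissue markers get per-class means with a
3-log2 spread (random class order per gene, within-class SD 0.7); null
genes are `6 + N(0,1)`. Values are clamped at 0 and inverted to raw scale
as `E = 2ˣ − 1`, making the pipeline's `log2(1+E)` an exact round trip.
10% of slides carry a duplicate (re-noised) expression sample.

What passing tests on this generator do **not** show: robustness to stain
variation, scanner artifacts, nuclear morphology, spatial autocorrelation
of expression, or compositional (cell-type-mixture) effects — none of which
are simulated.

## Problem sizes

Desk-scale runs use the default recipe: 4 classes × 30 slides of 1024×1024
px (4 tiles each, 480 tiles), 60 genes (20 direct / 20 marker / 20 null),
the tiny model trained 20 epochs with batch 32, screening at `R_T = 0.6`,
`E_T = 0`, 1000 permutations, α = 0.01 — chosen as the smallest
configuration at which every planted-signal property is measurable with
margin. Full-scale defaults (90 epochs, `R_T = 0.8`, `E_T = 10`, batch 40)
remain the config defaults.

## Statistical power and the indirect-dependency flags

With 24 test slides and 4 tissues, the partial-correlation test has 19
residual degrees of freedom, so rejection at α = 0.01 needs a partial
correlation of about 0.55. Direct genes therefore escape the `g–t–f` flag
reliably only through their best-evidence pairs; they also legitimately
carry many tissue-mediated "piggyback" pairs (features of other classes'
textures) that are *correctly* flagged indirect. Pipeline-level tests
compare marker pair flag rates against direct genes' best-evidence
(minimum CI p) pairs; the clean planted-pair discrimination (≥90% of
indirect pairs flagged, ≤10% of direct pairs) is verified in a numeric
simulation at n = 300 over 100 seeds, where pair identity is unambiguous.

## Visualization choices

Both visualizations use the same scalar that is correlated with genes: the
spatially aggregated `f_lz`. Activation-maximization defaults: 256 steps,
step size 0.05 in normalized units along the RMS-normalized gradient,
jitter ±2 px per step, Gaussian blur σ = 0.5 every 4 steps, L2 weight 1e-4,
channels clamped to the normalized range of valid 8-bit inputs, outputs
de-normalized with the ImageNet constants. The trajectory is logged on the
un-jittered image each step. Periodic blur necessarily costs feature value,
so the trajectory is monotone only outside blur steps (≈99% of non-blur
steps ascend); the ascent contract is final > initial. Gradient images are
rendered by an affine rescale centered so zero gradient maps to mid-gray.
Representative tiles are the top-k by feature value with a per-slide cap
and deterministic ties by tile id — a documented stand-in for an
unpublished selection procedure, not a reproduction of it.

## Known limitations

- The tissue/background rule is a reproducible stand-in; it will not
  reproduce tile counts obtained with any other (unpublished) rule.
- ResNet34/Inception v3 are not executable networks here; analyses
  involving trained models use the sequential architectures.
- The brightness-based generator draws from a Boolean disk model; feature
  saturation at high coverage compresses latent–feature relationships.
- Permutation and partial-correlation inference assume exchangeable samples
  (one expression value per slide after duplicate resolution) and linear
  tissue effects.
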