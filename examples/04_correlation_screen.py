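"""Screen gene expression against visual features and probe tissue mediation.

Feature values f_lz(W) (spatial sums of layer activations, summed over a
slide's tiles) are correlated with log2(1+E) gene expression over the
held-out test slides. Pairs passing the correlation threshold get a
permutation p-value, and a partial correlation given tissue identity asks
whether the association is tissue-mediated (indirect g-t-f).
"""

import numpy as np

from histotranscript import (features, pipeline, synthetic, tiler, trainer,
                             zoo)
from histotranscript.correlation import Thresholds
from histotranscript.trainer import TrainConfig

ds = synthetic.generate_dataset(n_classes=3, slides_per_class=24,
                                image_size=512, seed=11)
split = trainer.split_slides(ds.slides, seed=11)
tiles, _ = tiler.tile_slides(ds.slides)
classes = sorted({s.tissue for s in ds.slides})
sets = {n: trainer.TileSet.from_tiles([t for t in tiles if split[t.slide_id] == n],
                                      classes)
        for n in ("train", "validation", "test")}
spec = zoo.build_architecture("tiny", len(classes))
model = spec.materialize(seed=12)
trainer.train_classifier(model, sets["train"], sets["validation"],
                         TrainConfig(epochs=8, batch_size=8, seed=13))

fmat = features.build_feature_matrix(model, spec, sets["test"].x,
                                     sets["test"].slide_ids)
print(f"feature matrix: {fmat.shape[0]} test slides x {fmat.shape[1]} features")

thresholds = Thresholds(r_t=0.6, e_t=0.0, alpha_ci=0.01, n_perm=1000)
_, _, r, pairs, counts, patterns = pipeline.correlate_stage(
    fmat, ds.expression, ds.metadata, split, thresholds, seed=14)
print(f"significant pairs at |r| >= {thresholds.r_t}: {counts}")
print(f"indirect-dependency counts at alpha = {thresholds.alpha_ci}: {patterns}")

truth = ds.ground_truth.set_index("gene")
annotated = pairs.assign(gene_type=truth.loc[pairs["gene"], "gene_type"].to_numpy())
print("\nstrongest pair per planted gene type:")
for gtype in ("direct", "tissue_marker", "null"):
    sub = annotated[annotated.gene_type == gtype]
    if sub.empty:
        print(f"  {gtype}: no pair passed the threshold (expected for null)")
        continue
    row = sub.loc[sub["r"].abs().idxmax()]
    print(f"  {row.gene} ({gtype}) ~ {row.feature}: r={row.r:.3f} "
          f"perm_p={row.perm_p:.4f} r|tissue={row.partial_r_given_tissue:.3f} "
          f"tissue-mediated={bool(row.gtf_indirect)}")
print("\nMarker genes lose most of their correlation once tissue identity "
      "is conditioned out; direct genes retain a within-tissue component. "
      "At this reduced scale the conditional-independence test has little "
      "power, so many direct pairs are still flagged; the full recipe "
      "(examples/06_full_pipeline.py) uses 24 test slides.")
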