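"""Train the small tissue classifier on a reduced synthetic dataset.

Slides are split 60/20/20 at the slide level (stratified by tissue), the
classifier is trained with momentum SGD under the step learning-rate
schedule, the best validation epoch is kept, and whole slides are
classified by majority vote over their tiles.
"""

from histotranscript import synthetic, tiler, trainer, zoo
from histotranscript.trainer import TrainConfig

ds = synthetic.generate_dataset(n_classes=3, slides_per_class=10,
                                image_size=512, seed=11)
split = trainer.split_slides(ds.slides, seed=11)
tiles, _ = tiler.tile_slides(ds.slides)
classes = sorted({s.tissue for s in ds.slides})
sets = {name: trainer.TileSet.from_tiles(
            [t for t in tiles if split[t.slide_id] == name], classes)
        for name in ("train", "validation", "test")}

spec = zoo.build_architecture("tiny", num_classes=len(classes))
model = spec.materialize(seed=12)
result = trainer.train_classifier(model, sets["train"], sets["validation"],
                                  TrainConfig(epochs=5, batch_size=8, seed=13))
print(result.log.to_string(index=False))
print(f"selected epoch {result.best_epoch} "
      f"(best validation tile accuracy {result.best_val_accuracy:.3f})")

tile_acc, confusion = trainer.evaluate_tiles(model, sets["test"])
slide_acc, _ = trainer.evaluate_slides(model, sets["test"])
print(f"test tile accuracy {tile_acc:.3f}, majority-vote slide accuracy {slide_acc:.3f}")
print("confusion matrix (rows = truth):")
print(confusion)
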