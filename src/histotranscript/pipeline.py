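"""End-to-end orchestration: tile -> train -> quantify -> correlate -> visualize.

A run is driven by one :class:`RunConfig` whose master seed determines every
source of randomness (split, weight init, batch shuffling, permutations,
synthetic data). Feature quantification and correlation read ONLY the test
split — the correlate stage refuses any feature row belonging to a training
or validation slide — so model selection can never leak into the screen.

Full-scale defaults (90 epochs, R_T = 0.8, E_T = 10, N = 1000 permutations,
alpha = 0.01) are the config defaults; :func:`desk_recipe` returns the
desk-scale configuration used for the synthetic study (tiny model, 20
epochs, R_T = 0.6, E_T = 0).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import correlation, features, nn, synthetic, tiler, trainer, visualize, zoo
from .correlation import Thresholds
from .trainer import TrainConfig


@dataclass
class RunConfig:
    arch: str = "vgg16"
    tile_size: int = 512
    min_tissue: float = 0.5
    p: int = 1
    train: TrainConfig = field(default_factory=TrainConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    visualize_top: int = 1        # pairs to visualize (0 disables the stage)
    synth_steps: int = 64

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def desk_recipe(seed: int = 0) -> RunConfig:
    """The desk-scale synthetic study configuration (one CPU, minutes)."""
    return RunConfig(
        arch="tiny",
        train=TrainConfig(epochs=20, batch_size=32, seed=seed + 2),
        thresholds=Thresholds(r_t=0.6, e_t=0.0, alpha_ci=0.01, n_perm=1000),
        seed=seed,
    )


@dataclass
class RunResult:
    config: RunConfig
    split: dict[str, str]
    tile_manifest: pd.DataFrame
    train_log: pd.DataFrame
    best_epoch: int
    tile_accuracy: float
    slide_accuracy: float
    confusion: pd.DataFrame
    feature_matrix: pd.DataFrame          # test slides x features
    r_matrix: pd.DataFrame
    pairs: pd.DataFrame
    counts: dict
    pattern_counts: dict
    model: nn.Sequential = field(repr=False, default=None)
    spec: zoo.ArchitectureSpec = field(repr=False, default=None)
    visualizations: dict = field(default_factory=dict, repr=False)


def assert_test_only(feature_matrix: pd.DataFrame, split: dict[str, str]) -> None:
    """Leakage guard: the screen must only ever see test-split slides."""
    bad = [s for s in feature_matrix.index if split.get(s) != "test"]
    if bad:
        raise ValueError(
            f"correlate stage received non-test slides {bad[:5]}...; "
            "gene-feature correlations are computed on the test split only")


def correlate_stage(feature_matrix: pd.DataFrame, expression: pd.DataFrame,
                    metadata: pd.DataFrame, split: dict[str, str],
                    thresholds: Thresholds, seed: int,
                    alpha: float | None = None):
    """Duplicate resolution, screening, permutation p and CI patterns on the
    test split. ``expression`` is raw genes x samples."""
    assert_test_only(feature_matrix, split)
    sample_to_slide = metadata.set_index("sample")["slide_id"]
    slide_tissue = metadata.drop_duplicates("slide_id").set_index("slide_id")["tissue"]
    expr_log = correlation.resolve_duplicates(expression, sample_to_slide)
    expr_log = expr_log[[c for c in expr_log.columns if c in feature_matrix.index]]
    meta = correlation.gene_meta(expr_log, slide_tissue)
    r = correlation.correlate(expr_log, feature_matrix)
    pairs, counts = correlation.select_significant(r, thresholds, meta)
    pairs = correlation.add_permutation_p(pairs, expr_log, feature_matrix,
                                          thresholds.n_perm, seed)
    pairs, pattern_counts = correlation.dependency_patterns(
        pairs, expr_log, feature_matrix, slide_tissue,
        alpha if alpha is not None else thresholds.alpha_ci)
    return expr_log, meta, r, pairs, counts, pattern_counts


def run_all(config: RunConfig, dataset: synthetic.SyntheticDataset | None = None,
            out_dir: str | None = None) -> RunResult:
    """Execute the full pipeline on a paired image/expression dataset.

    With no dataset given, the default synthetic recipe is generated from the
    config seed. Stages run in order tile -> train -> quantify(test) ->
    correlate(test) -> visualize; every output is deterministic for a given
    config.
    """
    if dataset is None:
        dataset = synthetic.generate_dataset(seed=config.seed)

    # --- split (slide level, stratified) ---
    split = trainer.split_slides(dataset.slides, config.split_fractions,
                                 seed=config.seed)
    for s in dataset.slides:
        s.split = split[s.slide_id]

    # --- tile ---
    tiles, manifest = tiler.tile_slides(dataset.slides, config.tile_size,
                                        config.min_tissue)
    classes = sorted({s.tissue for s in dataset.slides})
    sets = {}
    for name in ("train", "validation", "test"):
        subset = [t for t in tiles if split[t.slide_id] == name]
        sets[name] = trainer.TileSet.from_tiles(subset, classes)

    # --- train ---
    spec = zoo.build_architecture(config.arch, num_classes=len(classes))
    model = spec.materialize(seed=config.seed + 1)
    result = trainer.train_classifier(model, sets["train"], sets["validation"],
                                      config.train)
    tile_acc, confusion = trainer.evaluate_tiles(model, sets["test"])
    slide_acc, _ = trainer.evaluate_slides(model, sets["test"])

    # --- quantify (test split only) ---
    test = sets["test"]
    fmat = features.build_feature_matrix(model, spec, test.x, test.slide_ids,
                                         p=config.p)

    # --- correlate (test split only) ---
    _, _, r, pairs, counts, pattern_counts = correlate_stage(
        fmat, dataset.expression, dataset.metadata, split,
        config.thresholds, seed=config.seed + 3)

    # --- visualize the top pairs ---
    vis = {}
    if config.visualize_top and len(pairs):
        top = pairs.reindex(pairs["r"].abs().sort_values(ascending=False).index)
        for row in top.head(config.visualize_top).itertuples():
            tf = features.tile_feature_matrix(
                model, spec, test.x, [tiles[i].tile_id for i in range(len(tiles))
                                      if split[tiles[i].slide_id] == "test"],
                p=config.p)
            pick = visualize.select_representative_tiles(tf, row.feature, k=1)
            idx = list(tf.index).index(pick[0])
            gbp = visualize.guided_backprop(model, row.feature, test.x[idx])
            synth = visualize.activation_maximization(
                model, row.feature,
                visualize.SynthImageConfig(steps=config.synth_steps,
                                           seed=config.seed + 4))
            vis[row.feature] = {"gene": row.gene, "tile": pick[0],
                                "gbp": visualize.render_gradient(gbp),
                                "synthetic": synth.image,
                                "trajectory": synth.trajectory}
            break

    run = RunResult(config, split, manifest, result.log, result.best_epoch,
                    tile_acc, slide_acc, confusion, fmat, r, pairs, counts,
                    pattern_counts, model=model, spec=spec, visualizations=vis)
    if out_dir is not None:
        write_run(run, out_dir)
    return run


def write_run(run: RunResult, out_dir: str) -> None:
    """Persist a run directory: config + hash, logs, matrices, pair table."""
    os.makedirs(out_dir, exist_ok=True)
    stamp = {"config": asdict(run.config), "config_hash": run.config.config_hash(),
             "tile_accuracy": run.tile_accuracy, "slide_accuracy": run.slide_accuracy,
             "best_epoch": run.best_epoch, "counts": run.counts,
             "pattern_counts": run.pattern_counts}
    with open(os.path.join(out_dir, "run.json"), "w") as fh:
        json.dump(stamp, fh, indent=2, default=str)
    run.tile_manifest.to_csv(os.path.join(out_dir, "tiles.tsv"), sep="\t", index=False)
    run.train_log.to_csv(os.path.join(out_dir, "train_log.tsv"), sep="\t", index=False)
    run.confusion.to_csv(os.path.join(out_dir, "confusion.tsv"), sep="\t")
    run.feature_matrix.to_csv(os.path.join(out_dir, "features.tsv"), sep="\t")
    run.pairs.to_csv(os.path.join(out_dir, "pairs.tsv"), sep="\t", index=False)
    save_model(run.model, run.spec, os.path.join(out_dir, "best.npz"))


def save_model(model: nn.Sequential, spec: zoo.ArchitectureSpec, path: str) -> None:
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    np.savez(path, _name=spec.name, _num_classes=spec.num_classes, **arrays)


def load_model(path: str) -> tuple[nn.Sequential, zoo.ArchitectureSpec]:
    data = np.load(path)
    spec = zoo.build_architecture(str(data["_name"]), int(data["_num_classes"]))
    model = spec.materialize()
    for i, p in enumerate(model.params()):
        p[...] = data[f"p{i}"]
    return model, spec
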