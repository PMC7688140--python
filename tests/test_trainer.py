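"""Splitting, the training schedule, evaluation, majority vote and merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from histotranscript import nn, trainer
from histotranscript.trainer import TrainConfig

# the five published groups of histologically similar tissues
MERGE_GROUPS = [
    ("Artery - Aorta", "Artery - Coronary", "Artery - Tibial"),
    ("Colon - Sigmoid", "Colon - Transverse"),
    ("Esophagus - Gastroesophageal Junction", "Esophagus - Muscularis"),
    ("Heart - Atrial Appendage", "Heart - Left Ventricle"),
    ("Skin - Not Sun Exposed", "Skin - Sun Exposed"),
]


def _slides(counts: dict[str, int]):
    return [(f"{t}-{i}", t) for t, n in counts.items() for i in range(n)]


def test_split_sizes_single_class():
    split = trainer.split_slides(_slides({"liver": 10}), seed=0)
    sizes = pd.Series(split).value_counts()
    assert sizes["train"] == 6 and sizes["validation"] == 2 and sizes["test"] == 2


def test_split_deterministic_and_seed_sensitive():
    slides = _slides({"liver": 20, "lung": 20})
    a = trainer.split_slides(slides, seed=5)
    b = trainer.split_slides(slides, seed=5)
    c = trainer.split_slides(slides, seed=6)
    assert a == b
    assert a != c


def test_split_stratified_within_one_slide():
    slides = _slides({c: 25 for c in "abcd"})
    split = trainer.split_slides(slides, seed=3)
    df = pd.DataFrame([{"tissue": t, "split": split[s]} for s, t in slides])
    for _, grp in df.groupby("tissue"):
        counts = grp["split"].value_counts()
        assert abs(counts.get("train", 0) - 15) <= 1
        assert abs(counts.get("validation", 0) - 5) <= 1
        assert abs(counts.get("test", 0) - 5) <= 1


def test_split_small_class_goes_to_train():
    with pytest.warns(UserWarning, match="assigning all to train"):
        split = trainer.split_slides(_slides({"rare": 2, "liver": 10}), seed=0)
    assert all(split[s] == "train" for s, t in _slides({"rare": 2}) if "rare" in s)


def test_lr_schedule_steps():
    cfg = TrainConfig()
    assert cfg.learning_rate(0) == 0.01
    assert cfg.learning_rate(29) == 0.01
    assert cfg.learning_rate(30) == pytest.approx(0.001)
    assert cfg.learning_rate(60) == pytest.approx(0.0001)
    assert cfg.learning_rate(89) == pytest.approx(0.0001)


def test_accuracy_counting_with_planted_errors(rng):
    truth = rng.integers(0, 4, 100)
    pred = truth.copy()
    wrong = rng.choice(100, size=17, replace=False)
    pred[wrong] = (truth[wrong] + 1) % 4
    acc, cm = trainer.accuracy_and_confusion(truth, pred, list("abcd"))
    assert acc == pytest.approx(0.83)
    assert cm.to_numpy().sum() == 100
    assert np.trace(cm.to_numpy()) == 83
    assert (cm.sum(axis=1).to_numpy() == np.bincount(truth, minlength=4)).all()


def test_perfect_and_constant_predictors():
    truth = np.repeat(np.arange(4), 5)
    acc, cm = trainer.accuracy_and_confusion(truth, truth, list("abcd"))
    assert acc == 1.0 and np.all(cm.to_numpy() == np.diag([5] * 4))
    acc, _ = trainer.accuracy_and_confusion(truth, np.zeros_like(truth), list("abcd"))
    assert acc == 0.25


class _FixedLogits(nn.Layer):
    def __init__(self, table):
        self.table = table
        self.i = 0

    def forward(self, x, train=False):
        out = self.table[self.i:self.i + len(x)]
        self.i += len(x)
        return out


def _vote(table):
    model = nn.Sequential([_FixedLogits(np.asarray(table, dtype=np.float32))])
    return trainer.predict_slide(model, np.zeros((len(table), 1, 2, 2), np.float32))


def test_majority_vote():
    assert _vote([[5, 0], [5, 0], [0, 5]]) == 0          # (A, A, B) -> A
    assert _vote([[0, 5], [0, 5], [0, 5]]) == 1          # unanimous B
    # tie (A, A, B, B): summed softmax favors B
    assert _vote([[1.0, 0.0], [1.0, 0.0], [0.0, 4.0], [0.0, 4.0]]) == 1
    # exact tie in scores too: lowest class index wins
    assert _vote([[2.0, 0.0], [0.0, 2.0]]) == 0


def test_predict_slide_requires_tiles(tiny_model):
    with pytest.raises(ValueError):
        trainer.predict_slide(tiny_model, np.zeros((0, 3, 224, 224), np.float32))


def test_merging_published_groups_gives_33_classes():
    other = [f"Tissue-{i}" for i in range(28)]
    labels = other + [t for g in MERGE_GROUPS for t in g]
    assert len(set(labels)) == 39
    merged = trainer.merge_classes(labels, MERGE_GROUPS)
    assert len(set(merged)) == 33


def test_merge_empty_groups_is_identity():
    labels = ["a", "b", "c"]
    assert trainer.merge_classes(labels, []) == labels


def test_merge_overlapping_groups_rejected():
    with pytest.raises(ValueError):
        trainer.merge_map(["a", "b", "c"], [("a", "b"), ("b", "c")])


@given(st.integers(0, 10 ** 6))
def test_collapsing_confusion_never_decreases_accuracy(seed):
    rng = np.random.default_rng(seed)
    cm = pd.DataFrame(rng.integers(0, 20, (4, 4)), index=list("abcd"),
                      columns=list("abcd"))
    if cm.to_numpy().sum() == 0:
        return
    merged = trainer.collapse_confusion(cm, [("a", "b")])
    assert merged.shape == (3, 3)
    assert trainer.confusion_accuracy(merged) >= trainer.confusion_accuracy(cm)
    assert merged.to_numpy().sum() == cm.to_numpy().sum()


def test_training_separates_linearly_separable_classes(rng):
    """A small net on color-separable synthetic tiles reaches validation
    accuracy 1.0, selection picks the argmax epoch, and no test tile is seen."""
    def make(n, label):
        base = 0.8 if label else -0.8
        x = (base + 0.05 * rng.standard_normal((n, 3, 16, 16))).astype(np.float32)
        return x, np.full(n, label, dtype=np.int64)

    x0, y0 = make(20, 0)
    x1, y1 = make(20, 1)
    x = np.concatenate([x0, x1])
    y = np.concatenate([y0, y1])
    train = trainer.TileSet(x, y, [f"s{i}" for i in range(40)], ["neg", "pos"])
    xv, yv = make(10, 0)[0], np.zeros(10, np.int64)
    xv2, yv2 = make(10, 1)
    val = trainer.TileSet(np.concatenate([xv, xv2]), np.concatenate([yv, yv2]),
                          [f"v{i}" for i in range(20)], ["neg", "pos"])
    net = nn.Sequential([nn.Conv2d(3, 4, 3, pad=1, rng=rng), nn.ReLU(),
                         nn.MaxPool2d(16), nn.Flatten(), nn.Linear(4, 2, rng=rng)])
    cfg = TrainConfig(epochs=8, lr0=0.05, batch_size=8, seed=0)
    res = trainer.train_classifier(net, train, val, cfg)
    assert res.best_val_accuracy == 1.0
    log = res.log
    assert res.best_epoch == int(log["val_accuracy"].idxmax())
    acc, _ = trainer.evaluate_tiles(net, val)
    assert acc == 1.0


def test_training_rejects_empty_split(tiny_model):
    empty = trainer.TileSet(np.zeros((0, 3, 224, 224), np.float32),
                            np.zeros(0, np.int64), [], ["a"])
    with pytest.raises(ValueError):
        trainer.train_classifier(tiny_model, empty, empty, TrainConfig(epochs=1))


def test_no_slide_crosses_splits(mini_dataset):
    """Leakage check: every slide is in exactly one split, so no tile of a
    validation/test slide can enter a training batch."""
    split = trainer.split_slides(mini_dataset.slides, seed=0)
    assert set(split) == {s.slide_id for s in mini_dataset.slides}
    from histotranscript import tiler
    tiles, _ = tiler.tile_slides(mini_dataset.slides[:6])
    by_split = {}
    for t in tiles:
        by_split.setdefault(split[t.slide_id], set()).add(t.slide_id)
    groups = list(by_split.values())
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            assert not (groups[i] & groups[j])
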