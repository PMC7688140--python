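"""Slide-level splitting, tile-classifier training, and evaluation.

Training follows the step schedule used for the tissue classifiers: SGD with
an initial learning rate of 0.01 divided by 10 every 30 epochs, 90 epochs by
default (desk-scale runs use far fewer), and model selection at the epoch
with the best validation *tile* accuracy. Splits are always made at the slide
level so no tile of a validation/test slide can leak into training. Whole
slides are classified by majority vote over their tiles' predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .tiler import Tile, prepare_input


@dataclass
class TrainConfig:
    epochs: int = 90
    lr0: float = 0.01
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 30
    batch_size: int = 40
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0

    def learning_rate(self, epoch: int) -> float:
        """Step schedule; epochs are 0-based."""
        return self.lr0 / self.lr_decay_factor ** (epoch // self.lr_decay_every)


def split_slides(slides, fractions=(0.6, 0.2, 0.2), seed: int = 0) -> dict[str, str]:
    """Per-tissue stratified random split at the slide level.

    ``slides`` is a list of SlideRecord (or (slide_id, tissue) pairs). Counts
    per tissue follow the largest-remainder rule so each class lands within
    one slide of the requested fractions. A tissue with fewer than 3 slides
    is assigned entirely to training, with a warning. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    by_tissue: dict[str, list[str]] = {}
    for s in slides:
        sid, tissue = (s.slide_id, s.tissue) if hasattr(s, "slide_id") else s
        by_tissue.setdefault(tissue, []).append(sid)
    names = ("train", "validation", "test")
    assignment: dict[str, str] = {}
    for tissue in sorted(by_tissue):
        ids = sorted(by_tissue[tissue])
        rng.shuffle(ids)
        n = len(ids)
        if n < 3:
            warnings.warn(f"tissue {tissue!r} has {n} slide(s); assigning all to train")
            assignment.update({sid: "train" for sid in ids})
            continue
        exact = np.array(fractions, dtype=float) * n
        counts = np.floor(exact).astype(int)
        for i in np.argsort(-(exact - counts)):
            if counts.sum() == n:
                break
            counts[i] += 1
        pos = 0
        for name, c in zip(names, counts):
            for sid in ids[pos:pos + c]:
                assignment[sid] = name
            pos += c
    return assignment


@dataclass
class TileSet:
    """Prepared tiles ready for the network: inputs, labels, bookkeeping."""

    x: np.ndarray                      # N x 3 x 224 x 224 float32
    y: np.ndarray                      # N int labels
    slide_ids: list[str]
    classes: list[str]                 # index -> tissue name

    @classmethod
    def from_tiles(cls, tiles: list[Tile], classes: list[str] | None = None) -> "TileSet":
        classes = classes or sorted({t.label for t in tiles})
        idx = {c: i for i, c in enumerate(classes)}
        x = np.stack([prepare_input(t) for t in tiles])
        y = np.array([idx[t.label] for t in tiles], dtype=np.int64)
        return cls(x, y, [t.slide_id for t in tiles], classes)

    def subset(self, keep: np.ndarray) -> "TileSet":
        return TileSet(self.x[keep], self.y[keep],
                       [s for s, k in zip(self.slide_ids, keep) if k], self.classes)


@dataclass
class TrainResult:
    log: pd.DataFrame                  # epoch, lr, train_loss, val_accuracy
    best_epoch: int
    best_val_accuracy: float
    best_params: list = field(repr=False, default_factory=list)


def predict_logits(model: nn.Sequential, x: np.ndarray, batch: int = 64) -> np.ndarray:
    out = [model.forward(x[i:i + batch], train=False) for i in range(0, len(x), batch)]
    return np.concatenate(out, axis=0)


def train_classifier(model: nn.Sequential, train_set: TileSet, val_set: TileSet,
                     config: TrainConfig) -> TrainResult:
    """Minimize cross-entropy with momentum SGD under the step lr schedule;
    return the per-epoch log and restore the best-validation-epoch weights.

    Model selection never consults any test split; validation-accuracy ties
    go to the earliest epoch.
    """
    if len(train_set.x) == 0:
        raise ValueError("empty training split")
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model, lr=config.lr0, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    rows = []
    best = (-1.0, -1, None)  # (val_acc, epoch, params)
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate(epoch)
        order = rng.permutation(len(train_set.x))
        losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            logits = model.forward(train_set.x[sel], train=True)
            loss, grad = nn.cross_entropy(logits, train_set.y[sel])
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_acc, _ = evaluate_tiles(model, val_set)
        rows.append({"epoch": epoch, "lr": opt.lr,
                     "train_loss": float(np.mean(losses)), "val_accuracy": val_acc})
        if val_acc > best[0]:
            best = (val_acc, epoch, [p.copy() for p in model.params()])
    for p, bp in zip(model.params(), best[2]):
        p[...] = bp
    return TrainResult(pd.DataFrame(rows), best[1], best[0], best[2])


def evaluate_tiles(model: nn.Sequential, tiles: TileSet) -> tuple[float, pd.DataFrame]:
    """Tile accuracy and a rows=truth / cols=prediction confusion matrix."""
    pred = predict_logits(model, tiles.x).argmax(axis=1)
    return accuracy_and_confusion(tiles.y, pred, tiles.classes)


def accuracy_and_confusion(truth: np.ndarray, pred: np.ndarray,
                           classes: list[str]) -> tuple[float, pd.DataFrame]:
    k = len(classes)
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (truth, pred), 1)
    acc = float(np.trace(cm)) / max(1, len(truth))
    return acc, pd.DataFrame(cm, index=classes, columns=classes)


def predict_slide(model: nn.Sequential, slide_tiles: np.ndarray) -> int:
    """Majority vote over tile predictions; ties broken by the summed softmax
    scores across tiles, then by the lowest class index."""
    if len(slide_tiles) == 0:
        raise ValueError("slide has no tiles")
    logits = predict_logits(model, slide_tiles)
    votes = np.bincount(logits.argmax(axis=1), minlength=logits.shape[1])
    top = np.flatnonzero(votes == votes.max())
    if len(top) == 1:
        return int(top[0])
    scores = nn.softmax(logits).sum(axis=0)
    return int(top[np.argmax(scores[top])])


def evaluate_slides(model: nn.Sequential, tiles: TileSet) -> tuple[float, pd.DataFrame]:
    """Slide-level accuracy under majority vote."""
    order: dict[str, list[int]] = {}
    for i, sid in enumerate(tiles.slide_ids):
        order.setdefault(sid, []).append(i)
    truths, preds = [], []
    for sid, idxs in order.items():
        truths.append(tiles.y[idxs[0]])
        preds.append(predict_slide(model, tiles.x[idxs]))
    return accuracy_and_confusion(np.array(truths), np.array(preds), tiles.classes)


# ---------------------------------------------------------------------------
# class merging
# ---------------------------------------------------------------------------

def merge_map(classes: list[str], groups: list[tuple[str, ...]]) -> dict[str, str]:
    """Map each label to its merged-class name (groups must be disjoint)."""
    seen: set[str] = set()
    for g in groups:
        if seen & set(g):
            raise ValueError("merge groups must be disjoint")
        seen |= set(g)
    mapping = {c: c for c in classes}
    for g in groups:
        merged = "|".join(g)
        for c in g:
            mapping[c] = merged
    return mapping


def merge_classes(labels, groups: list[tuple[str, ...]]):
    """Relabel ``labels`` (sequence or Series) under the merged class set."""
    classes = sorted(set(labels))
    mapping = merge_map(classes, groups)
    if isinstance(labels, pd.Series):
        return labels.map(mapping)
    return [mapping[v] for v in labels]


def collapse_confusion(cm: pd.DataFrame, groups: list[tuple[str, ...]]) -> pd.DataFrame:
    """Re-evaluate a confusion matrix after merging classes (sums rows/cols)."""
    mapping = merge_map(list(cm.index), groups)
    merged = cm.copy()
    merged.index = [mapping[c] for c in cm.index]
    merged.columns = [mapping[c] for c in cm.columns]
    merged = merged.groupby(level=0).sum().T.groupby(level=0).sum().T
    return merged


def confusion_accuracy(cm: pd.DataFrame) -> float:
    return float(np.trace(cm.to_numpy())) / max(1, int(cm.to_numpy().sum()))
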