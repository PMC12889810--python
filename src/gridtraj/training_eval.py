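"""Training and evaluation: Adam/cross-entropy training loop and the
imbalance-aware F1 metrics.

The training protocol — Adam, learning rate 0.001, softmax
cross-entropy, 50 epochs — is applied uniformly to all three
architectures so their comparison isolates the representation and the
model, not the optimization recipe.  Evaluation reports per-class
precision/recall/F1 plus two aggregates: the **macro F1** (unweighted
mean over classes, sensitive to the minority class) and the **weighted
F1** (support-weighted mean).  The positive class for confusion counts
is *abnormal* unless stated otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .dataset_builder import GridDataset

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "Metrics",
    "train",
    "predict",
    "predict_proba",
    "confusion_counts",
    "compute_metrics",
    "evaluate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")


def train(
    model: nn.Module, train_set: GridDataset, config: TrainConfig = TrainConfig()
) -> tuple[nn.Module, list[float]]:
    """Train ``model`` in place; returns it with the per-epoch mean loss.

    Shuffling is seeded; with a fixed seed, model init and data order,
    the run is bit-reproducible.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    if len(set(train_set.labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    X = train_set.grids.astype(nn.DTYPE)
    y = train_set.labels
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    model.train()
    history: list[float] = []
    n = len(X)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(X[idx])
            loss, dlogits = nn.cross_entropy(logits, y[idx])
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
        logger.debug(
            "epoch %d/%d mean_loss=%.6f", len(history), config.epochs, history[-1]
        )
    return model, history


def predict_proba(
    model: nn.Module, dataset: GridDataset, batch_size: int = 64
) -> np.ndarray:
    """Class probabilities (softmax of logits), shape (N, 2)."""
    model.eval()
    X = dataset.grids.astype(nn.DTYPE)
    chunks = [
        nn.softmax(model.forward(X[i : i + batch_size]))
        for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(chunks) if chunks else np.zeros((0, 2))


def predict(model: nn.Module, dataset: GridDataset, batch_size: int = 64) -> np.ndarray:
    """Argmax labels; ties break toward class index 0 (normal)."""
    probs = predict_proba(model, dataset, batch_size)
    return probs.argmax(axis=1)  # argmax returns the first maximum: tie -> 0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    support: dict[int, int]
    macro_f1: float
    weighted_f1: float

    def as_dict(self) -> dict:
        return {
            "per_class": {
                str(c): {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                    "support": self.support[c],
                }
                for c in sorted(self.support)
            },
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
        }


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int], positive_class: int = 1
) -> ConfusionCounts:
    """Exact TP/FP/FN/TN with respect to ``positive_class``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    t = y_true == positive_class
    p = y_pred == positive_class
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
        tn=int((~t & ~p).sum()),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (0/0); returning 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], classes: Sequence[int] = (0, 1)
) -> Metrics:
    """Per-class precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R); macro F1 = unweighted class mean; weighted F1 =
    support-weighted class mean.  0/0 cases are defined as 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    precision, recall, f1, support = {}, {}, {}, {}
    for c in classes:
        cc = confusion_counts(y_true, y_pred, positive_class=c)
        prec = _safe_div(cc.tp, cc.tp + cc.fp, f"precision of class {c}")
        rec = _safe_div(cc.tp, cc.tp + cc.fn, f"recall of class {c}")
        precision[c] = prec
        recall[c] = rec
        f1[c] = _safe_div(2.0 * prec * rec, prec + rec, f"F1 of class {c}")
        support[c] = int((y_true == c).sum())
    macro = float(np.mean([f1[c] for c in classes]))
    total = sum(support.values())
    weighted = (
        float(sum(support[c] * f1[c] for c in classes) / total) if total else 0.0
    )
    return Metrics(precision, recall, f1, support, macro, weighted)


def evaluate(model: nn.Module, dataset: GridDataset, batch_size: int = 64) -> Metrics:
    """Predict on ``dataset`` and compute the full metric set."""
    return compute_metrics(dataset.labels, predict(model, dataset, batch_size))
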