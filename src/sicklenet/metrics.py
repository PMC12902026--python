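"""Evaluation metrics and the backbone x loss experiment grid.

The positive class is sickle (label 1).  Accuracy, precision, recall and F1
are computed from confusion counts; F1 is the harmonic mean of precision and
recall, defined as 0 when precision + recall = 0.  Reported tables round to
3 decimal places.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GRID_COLUMNS = [
    "network", "loss", "epoch", "batch_size", "learn_rate",
    "val_accuracy", "test_accuracy", "precision", "recall", "f1",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionCounts:
    y = np.asarray(true_labels)
    yp = np.asarray(predicted_labels)
    if y.shape != yp.shape:
        raise ValueError("label sequences must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be binary (0 = normal, 1 = sickle)")
    return ConfusionCounts(
        tp=int(((y == 1) & (yp == 1)).sum()),
        fp=int(((y == 0) & (yp == 1)).sum()),
        tn=int(((y == 0) & (yp == 0)).sum()),
        fn=int(((y == 1) & (yp == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> MetricSet:
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero samples")
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        logger.warning("no positive predictions; precision defined as 0")
        precision = 0.0
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        logger.warning("no positive samples; recall defined as 0")
        recall = 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MetricSet(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def evaluate(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> MetricSet:
    return metrics(confusion(true_labels, predicted_labels))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def experiment_grid(backbones: Sequence[str], losses: Sequence[str],
                    train_dataset, test_dataset, epochs: int = 10,
                    seed: int = 0, knn_k: int = 5) -> pd.DataFrame:
    """Train every (backbone, loss) combination and tabulate test metrics.

    One row per combination, in the result tables' column order.  A failing
    combination is recorded in an ``error`` column and the grid continues.
    """
    from .pipeline import run_experiment  # late import: avoids a cycle

    rows = []
    for backbone in backbones:
        for loss in losses:
            row = {"network": backbone, "loss": loss}
            try:
                result = run_experiment(
                    backbone=backbone, loss=loss, train_dataset=train_dataset,
                    test_dataset=test_dataset, epochs=epochs, seed=seed, knn_k=knn_k,
                )
                row.update(result)
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 — grid must continue
                logger.warning("grid cell (%s, %s) failed: %s", backbone, loss, exc)
                row["error"] = str(exc)
            rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = [c for c in GRID_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    return frame[ordered + extra]
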