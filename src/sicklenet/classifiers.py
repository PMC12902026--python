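"""Back-end classifiers operating in the learned embedding space.

Two predictors are provided: nearest class-centroid assignment (the natural
readout for a metric-learned space) and k-nearest-neighbour majority vote
(default k = 5) over stored training embeddings.  Both use Euclidean
distance; the squared form is compared internally since argmin is unchanged
under the monotone square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .embedding_net import EmbeddingBatch


@dataclass
class ClassCentroids:
    centroids: Dict[int, np.ndarray]
    counts: Dict[int, int]

    @property
    def dim(self) -> int:
        return len(next(iter(self.centroids.values())))


def fit_centroids(batch: EmbeddingBatch) -> ClassCentroids:
    """Per-class arithmetic mean embeddings; requires both classes present."""
    labels = np.asarray(batch.labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("both classes must be present to fit centroids")
    centroids = {int(c): batch.vectors[labels == c].mean(axis=0) for c in classes}
    counts = {int(c): int((labels == c).sum()) for c in classes}
    return ClassCentroids(centroids=centroids, counts=counts)


def centroid_predict(centroids: ClassCentroids, z: np.ndarray) -> int:
    """Label of the nearest centroid by L2 distance; exact ties -> class 0."""
    z = np.asarray(z, dtype=float)
    if z.shape != (centroids.dim,):
        raise ValueError(
            f"embedding dimension {z.shape} does not match centroids ({centroids.dim},)"
        )
    classes = sorted(centroids.centroids)
    dists = [float(((z - centroids.centroids[c]) ** 2).sum()) for c in classes]
    return classes[int(np.argmin(dists))]  # argmin takes the first (lowest class) on ties


def centroid_predict_batch(centroids: ClassCentroids, vectors: np.ndarray) -> np.ndarray:
    return np.array([centroid_predict(centroids, z) for z in np.atleast_2d(vectors)])


@dataclass
class KnnModel:
    vectors: np.ndarray
    labels: np.ndarray
    k: int = 5

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.k < 1 or self.k > len(self.vectors):
            raise ValueError("k must satisfy 1 <= k <= number of stored vectors")


def fit_knn(batch: EmbeddingBatch, k: int = 5) -> KnnModel:
    return KnnModel(vectors=batch.vectors, labels=batch.labels, k=k)


def knn_predict(model: KnnModel, z: np.ndarray) -> int:
    """Majority vote among the k nearest stored embeddings.

    Distance ties are broken by stored index ascending (stable sort); a vote
    tie (only possible for even k) falls back to the nearest neighbour's
    label.
    """
    z = np.asarray(z, dtype=float)
    if z.shape != model.vectors.shape[1:]:
        raise ValueError("query dimension does not match stored embeddings")
    d = ((model.vectors - z) ** 2).sum(axis=1)
    order = np.argsort(d, kind="stable")[: model.k]
    votes = model.labels[order]
    counts = {c: int((votes == c).sum()) for c in set(votes.tolist())}
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    if len(winners) == 1:
        return int(winners[0])
    return int(model.labels[order[0]])


def knn_predict_batch(model: KnnModel, vectors: np.ndarray) -> np.ndarray:
    return np.array([knn_predict(model, z) for z in np.atleast_2d(vectors)])


def predictions_to_frame(source_ids: Sequence[str], true_labels: Sequence[int],
                         predicted: Sequence[int],
                         scores: Sequence[float] | None = None) -> pd.DataFrame:
    scores = scores if scores is not None else [np.nan] * len(source_ids)
    return pd.DataFrame(
        {
            "image_id": list(source_ids),
            "true_label": np.asarray(true_labels, dtype=int),
            "predicted_label": np.asarray(predicted, dtype=int),
            "decision_score": np.asarray(scores, dtype=float),
        }
    )
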