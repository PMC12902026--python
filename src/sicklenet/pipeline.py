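"""End-to-end experiment helpers shared by the grid, the facade and the CLI."""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from . import classifiers, metrics
from .embedding_net import (
    BackboneSpec,
    EmbeddingBatch,
    EmbeddingModel,
    HeadSpec,
    build_model,
    embed,
)
from .synthetic import LabeledDataset
from .trainer import TrainConfig, train


def extract_features(model: EmbeddingModel, images: Sequence,
                     labels=None, source_ids=None) -> EmbeddingBatch:
    """Feature vectors for the back-end classifier.

    Embedding-head models yield their 128-d embeddings; probability-head
    models yield the penultimate (post-batch-norm) representation, the last
    layer before the classification head.
    """
    if model.mode == "embedding":
        return embed(model, images, labels=labels, source_ids=source_ids)
    x = model.preprocess(images)
    model.forward(x, train=False)
    vecs = model.net.outputs["bn"]
    n = len(images)
    labels = np.asarray(labels if labels is not None else np.full(n, -1))
    ids = list(source_ids) if source_ids is not None else [f"img_{i:05d}" for i in range(n)]
    return EmbeddingBatch(vectors=vecs.copy(), labels=labels, source_ids=ids)


def run_experiment(backbone: str, loss: str, train_dataset: LabeledDataset,
                   test_dataset: LabeledDataset, epochs: int = 10, seed: int = 0,
                   knn_k: int = 5, input_size: int = 64) -> Dict[str, float]:
    """Train one (backbone, loss) cell and evaluate with the KNN back-end."""
    head = "embedding" if loss == "triplet" else "probability"
    model = build_model(
        BackboneSpec(name=backbone, input_size=input_size), HeadSpec(mode=head),
        seed=seed,
    )
    config = TrainConfig(loss=loss, epochs=epochs, seed=seed)
    model, history = train(model, train_dataset, config)

    train_batch = extract_features(model, list(train_dataset), train_dataset.labels())
    test_batch = extract_features(model, list(test_dataset), test_dataset.labels())
    knn = classifiers.fit_knn(train_batch, k=knn_k)
    pred = classifiers.knn_predict_batch(knn, test_batch.vectors)
    mset = metrics.evaluate(test_batch.labels, pred)
    return {
        "epoch": epochs,
        "batch_size": config.batch_size,
        "learn_rate": config.lr0,
        "val_accuracy": round(history.val_accuracy[-1], 3) if len(history) else float("nan"),
        "test_accuracy": round(mset.accuracy, 3),
        "precision": round(mset.precision, 3),
        "recall": round(mset.recall, 3),
        "f1": round(mset.f1, 3),
    }
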