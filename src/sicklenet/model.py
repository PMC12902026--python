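"""High-level Model / Results interface.

``SmearClassificationModel`` bundles a labelled smear dataset with a
backbone and training objective; ``fit()`` fine-tunes the network and
returns a ``SmearClassificationResults`` holding the trained weights,
training history, fitted back-end classifiers and (when test data was
supplied) evaluation metrics, with a ``summary()`` table.

    >>> from sicklenet.model import SmearClassificationModel
    >>> m = SmearClassificationModel.from_synthetic(
    ...     n_train_per_class=60, n_test_per_class=30, seed=0)
    >>> res = m.fit(epochs=10)
    >>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import classifiers, metrics
from .embedding_net import BackboneSpec, HeadSpec, build_model
from .gradcam import Heatmap, gradcam, localization_fraction
from .pipeline import extract_features
from .synthetic import JitterParams, LabeledDataset, generate_dataset
from .trainer import TrainConfig, TrainHistory, train


class SmearClassificationModel:
    """Sickle-vs-normal smear classifier definition, pre-fit."""

    def __init__(self, train_data: LabeledDataset,
                 test_data: Optional[LabeledDataset] = None,
                 backbone: str = "tinycnn", loss: str = "triplet",
                 knn_k: int = 5, input_size: int = 64):
        self.train_data = train_data
        self.test_data = test_data
        self.backbone = backbone
        self.loss = loss
        self.knn_k = knn_k
        self.input_size = input_size

    @classmethod
    def from_synthetic(cls, n_train_per_class: int = 60, n_test_per_class: int = 30,
                       seed: int = 0, jitter: JitterParams | None = None,
                       **kwargs) -> "SmearClassificationModel":
        """Build from freshly generated synthetic smears (separable preset)."""
        jitter = jitter or JitterParams.separable()
        train_ds = generate_dataset(
            {"normal": n_train_per_class, "sickle": n_train_per_class},
            jitter=jitter, seed=seed)
        test_ds = generate_dataset(
            {"normal": n_test_per_class, "sickle": n_test_per_class},
            jitter=jitter, seed=seed + 10_000)
        return cls(train_ds, test_ds, **kwargs)

    def fit(self, epochs: int = 10, seed: int = 0,
            config: TrainConfig | None = None) -> "SmearClassificationResults":
        head = "embedding" if self.loss == "triplet" else "probability"
        net = build_model(
            BackboneSpec(name=self.backbone, input_size=self.input_size),
            HeadSpec(mode=head), seed=seed)
        config = config or TrainConfig(loss=self.loss, epochs=epochs, seed=seed)
        net, history = train(net, self.train_data, config)
        return SmearClassificationResults(self, net, history, config)


class SmearClassificationResults:
    """Fitted estimates: trained network, back-end classifiers, metrics."""

    def __init__(self, spec: SmearClassificationModel, network, history: TrainHistory,
                 config: TrainConfig):
        self.model = spec
        self.network = network
        self.history = history
        self.config = config

        self.train_features_ = extract_features(
            network, list(spec.train_data), spec.train_data.labels())
        self.centroids_ = classifiers.fit_centroids(self.train_features_)
        self.knn_ = classifiers.fit_knn(self.train_features_, k=spec.knn_k)

        self.test_metrics_ = {}
        if spec.test_data is not None:
            for name in ("centroid", "knn"):
                pred = self.predict(list(spec.test_data), classifier=name)
                self.test_metrics_[name] = metrics.evaluate(
                    spec.test_data.labels(), pred)

    def predict(self, images: Sequence, classifier: str = "knn") -> np.ndarray:
        feats = extract_features(self.network, images)
        if classifier == "knn":
            return classifiers.knn_predict_batch(self.knn_, feats.vectors)
        if classifier == "centroid":
            return classifiers.centroid_predict_batch(self.centroids_, feats.vectors)
        raise ValueError(f"unknown classifier {classifier!r}")

    def evaluate(self, dataset: LabeledDataset, classifier: str = "knn") -> metrics.MetricSet:
        pred = self.predict(list(dataset), classifier=classifier)
        return metrics.evaluate(dataset.labels(), pred)

    def gradcam(self, image, class_index: int = 1) -> Heatmap:
        cents = self.centroids_ if self.network.mode == "embedding" else None
        return gradcam(self.network, image, class_index=class_index, centroids=cents)

    def gradcam_localization(self, images=None, class_index: int = 1) -> float:
        images = images if images is not None else list(self.model.test_data)
        cents = self.centroids_ if self.network.mode == "embedding" else None
        return localization_fraction(self.network, images, centroids=cents,
                                     class_index=class_index)

    def summary(self) -> str:
        spec = self.model
        lines = [
            "Smear classification results",
            "=" * 46,
            f"{'backbone':<22}{spec.backbone:>24}",
            f"{'loss':<22}{spec.loss:>24}",
            f"{'epochs':<22}{self.config.epochs:>24}",
            f"{'batch size':<22}{self.config.batch_size:>24}",
            f"{'learning rate':<22}{self.config.lr0:>24.6g}",
            f"{'train images':<22}{len(spec.train_data):>24}",
        ]
        if len(self.history):
            lines += [
                f"{'final train loss':<22}{self.history.train_loss[-1]:>24.4f}",
                f"{'final val accuracy':<22}{self.history.val_accuracy[-1]:>24.4f}",
            ]
        if self.test_metrics_:
            lines.append("-" * 46)
            lines.append(f"{'classifier':<12}{'acc':>8}{'prec':>8}{'rec':>9}{'f1':>9}")
            for name, m in self.test_metrics_.items():
                lines.append(
                    f"{name:<12}{m.accuracy:>8.3f}{m.precision:>8.3f}"
                    f"{m.recall:>9.3f}{m.f1:>9.3f}"
                )
        lines.append("=" * 46)
        return "\n".join(lines)
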