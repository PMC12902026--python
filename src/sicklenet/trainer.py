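"""Model fine-tuning under the three objectives.

Optimization protocol: Adam, initial learning rate 1e-4, batch size 16 for
triplet training (drawn class-balanced so triplets can always be mined) and
32 for BCE / focal, stratified 80/20 train/validation split.  Focal-loss
runs decay the learning rate by a factor of 0.2 after 3 consecutive epochs
without validation-loss improvement (plateau rule), with a 1e-7 floor;
triplet and BCE runs keep the rate static.

Validation accuracy during triplet training is computed with a class-
centroid classifier fitted on the training-fold embeddings of the current
weights — a metric-learning model has no probability output of its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import nn, objectives
from .classifiers import centroid_predict_batch, fit_centroids
from .embedding_net import EmbeddingBatch, EmbeddingModel
from .synthetic import LabeledDataset

logger = logging.getLogger(__name__)

LOSSES = ("triplet", "bce", "focal")
DEFAULT_BATCH = {"triplet": 16, "bce": 32, "focal": 32}


@dataclass
class TrainConfig:
    loss: str = "triplet"
    epochs: int = 30
    batch_size: Optional[int] = None  # default 16 (triplet) / 32 (bce, focal)
    lr0: float = 1e-4
    plateau: Optional[bool] = None  # default: enabled only for focal
    plateau_factor: float = 0.2
    plateau_patience: int = 3
    min_lr: float = 1e-7
    seed: int = 0
    split_fraction: float = 0.8
    margin: float = 0.2
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.batch_size is None:
            self.batch_size = DEFAULT_BATCH[self.loss]
        if self.loss == "triplet" and self.batch_size < 2:
            raise ValueError("triplet training needs batch_size >= 2")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.plateau is None:
            self.plateau = self.loss == "focal"


@dataclass
class TrainHistory:
    epochs: List[int] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)
    lr: List[float] = field(default_factory=list)

    def append(self, epoch, train_loss, val_loss, val_acc, lr):
        self.epochs.append(epoch)
        self.train_loss.append(train_loss)
        self.val_loss.append(val_loss)
        self.val_accuracy.append(val_acc)
        self.lr.append(lr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_acc": self.val_accuracy,
                "lr": self.lr,
            }
        )

    def __len__(self) -> int:
        return len(self.epochs)


def split_dataset(dataset: LabeledDataset, fraction: float = 0.8,
                  seed: int = 0) -> Tuple[LabeledDataset, LabeledDataset]:
    """Stratified split; validation gets floor((1-fraction)*n) per class.

    Deterministic given the seed; the two parts are disjoint and their union
    is the input.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    labels = np.array([im.label for im in dataset])
    rng = np.random.default_rng(seed)
    val_idx: List[int] = []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 members to split")
        rng.shuffle(idx)
        n_val = int(np.floor((1 - fraction) * len(idx) + 1e-9))
        val_idx.extend(idx[:n_val].tolist())
    val_set = set(val_idx)
    train = LabeledDataset([dataset[i] for i in range(len(dataset)) if i not in val_set])
    val = LabeledDataset([dataset[i] for i in sorted(val_set)])
    return train, val


def plateau_step(val_losses: List[float], current_lr: float,
                 factor: float = 0.2, patience: int = 3) -> float:
    """Decay lr by ``factor`` after ``patience`` epochs without improvement.

    An epoch "improves" when its validation loss is strictly below the best
    seen before it; the counter is the number of epochs since the last
    improvement.
    """
    if not val_losses:
        raise ValueError("history must be non-empty")
    last_improving = 0
    best = val_losses[0]
    for i, v in enumerate(val_losses[1:], start=1):
        if v < best:
            best = v
            last_improving = i
    stalled = len(val_losses) - 1 - last_improving
    if stalled >= patience:
        return current_lr * factor
    return current_lr


def _triplet_batches(labels: np.ndarray, batch_size: int,
                     rng: np.random.Generator) -> List[np.ndarray]:
    """Class-balanced batch index draws (both classes in every batch)."""
    half = batch_size // 2
    c0 = np.flatnonzero(labels == 0)
    c1 = np.flatnonzero(labels == 1)
    rng.shuffle(c0)
    rng.shuffle(c1)
    n_batches = min(len(c0), len(c1)) // half
    batches = []
    for b in range(n_batches):
        idx = np.concatenate([c0[b * half : (b + 1) * half], c1[b * half : (b + 1) * half]])
        rng.shuffle(idx)
        batches.append(idx)
    return batches


def _check_compat(model: EmbeddingModel, loss: str) -> None:
    need = "embedding" if loss == "triplet" else "probability"
    if model.mode != need:
        raise ValueError(
            f"loss {loss!r} requires a {need}-head model, got {model.mode!r}"
        )


def train(model: EmbeddingModel, dataset, config: TrainConfig | None = None
          ) -> Tuple[EmbeddingModel, TrainHistory]:
    """Fine-tune ``model`` under ``config.loss``; returns (model, history).

    ``dataset`` is either a LabeledDataset (split 80/20 internally) or an
    explicit ``(train, validation)`` pair.  Fully deterministic given
    ``config.seed`` (pure NumPy arithmetic).
    """
    config = config or TrainConfig()
    _check_compat(model, config.loss)
    history = TrainHistory()
    if config.epochs == 0:
        return model, history

    if isinstance(dataset, tuple):
        train_ds, val_ds = dataset
    else:
        train_ds, val_ds = split_dataset(dataset, config.split_fraction, config.seed)

    x_train = model.preprocess(list(train_ds))
    y_train = train_ds.labels()
    x_val = model.preprocess(list(val_ds))
    y_val = val_ds.labels()

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.net.params(), lr=config.lr0)
    tparams = objectives.TripletParams(margin=config.margin)
    fparams = objectives.FocalParams(alpha=config.focal_alpha, gamma=config.focal_gamma)
    lr = config.lr0
    stall = 0
    best_val = np.inf

    for epoch in range(config.epochs):
        optimizer.lr = lr
        epoch_losses = []
        if config.loss == "triplet":
            batches = _triplet_batches(y_train, config.batch_size, rng)
        else:
            order = rng.permutation(len(y_train))
            batches = [order[s : s + config.batch_size]
                       for s in range(0, len(order), config.batch_size)]
        for idx in batches:
            model.net.zero_grad()
            if config.loss == "triplet":
                emb = model.forward(x_train[idx], train=True)
                loss, demb, n_mined = objectives.batch_triplet_grad(
                    emb, y_train[idx], tparams
                )
                if n_mined == 0:
                    logger.debug("epoch %d: no semi-hard triplets in batch", epoch)
                    epoch_losses.append(0.0)
                    continue
                model.net.backward(demb)
            else:
                logit = model.logits(x_train[idx], train=True)
                y = y_train[idx].astype(float)
                if config.loss == "bce":
                    loss = float(np.mean(objectives.bce_loss(y, objectives.sigmoid(logit))))
                    dlogit = objectives.bce_grad_logit(y, logit) / len(idx)
                else:
                    loss = float(np.mean(objectives.focal_loss(
                        y, objectives.sigmoid(logit), fparams)))
                    dlogit = objectives.focal_grad_logit(y, logit, fparams) / len(idx)
                model.net.backward(dlogit[:, None], from_layer="head")
            optimizer.step()
            epoch_losses.append(loss)

        val_loss, val_acc = _validate(model, x_train, y_train, x_val, y_val, config,
                                      tparams, fparams)
        history.append(epoch, float(np.mean(epoch_losses)) if epoch_losses else 0.0,
                       val_loss, val_acc, lr)

        if config.plateau:
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                stall = 0
            else:
                stall += 1
            if stall >= config.plateau_patience:
                lr = max(lr * config.plateau_factor, config.min_lr)
                stall = 0
                logger.info("epoch %d: plateau decay, lr -> %.2e", epoch, lr)
    return model, history


def _validate(model, x_train, y_train, x_val, y_val, config, tparams, fparams):
    if config.loss == "triplet":
        val_emb = model.forward(x_val, train=False)
        val_loss = objectives.batch_triplet_objective(val_emb, y_val, tparams)
        train_emb = model.forward(x_train, train=False)
        try:
            cents = fit_centroids(EmbeddingBatch(
                vectors=train_emb, labels=y_train,
                source_ids=[str(i) for i in range(len(y_train))]))
            pred = centroid_predict_batch(cents, val_emb)
            val_acc = float((pred == y_val).mean())
        except ValueError:
            val_acc = float("nan")
        return float(val_loss), val_acc
    logit = model.logits(x_val, train=False)
    prob = objectives.sigmoid(logit)
    if config.loss == "bce":
        val_loss = float(np.mean(objectives.bce_loss(y_val.astype(float), prob)))
    else:
        val_loss = float(np.mean(objectives.focal_loss(y_val.astype(float), prob, fparams)))
    val_acc = float(((prob >= 0.5).astype(int) == y_val).mean())
    return val_loss, val_acc
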