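"""Embedding networks: backbone + GAP/Dropout/BatchNorm head.

The model maps an RGB image to either a 128-dimensional ReLU embedding
(metric-learning mode, used with triplet loss) or a single sigmoid
probability (used with BCE / focal loss).  Classification then happens in
the embedding space (centroid or KNN) or directly from the probability.

The only runnable backbone in this package is ``tinycnn`` — three small
convolution blocks (< 50k parameters) suited to CPU-scale experiments.
ImageNet backbone names (resnet50, densenet121, efficientnetb0, mobilenetv2)
are recognised but require a pretrained-model backend, which this package
does not bundle; requesting one raises a clear error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn
from .synthetic import SmearImage

KNOWN_BACKBONES = ("resnet50", "densenet121", "efficientnetb0", "mobilenetv2", "tinycnn")
EMBEDDING_DIM = 128


@dataclass
class BackboneSpec:
    name: str = "tinycnn"
    pretrained: bool = False
    input_size: int = 64

    def __post_init__(self) -> None:
        if self.name not in KNOWN_BACKBONES:
            raise ValueError(
                f"unknown backbone {self.name!r}; known: {KNOWN_BACKBONES}"
            )


@dataclass
class HeadSpec:
    mode: str = "embedding"  # "embedding" | "probability"
    embedding_dim: int = EMBEDDING_DIM
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("embedding", "probability"):
            raise ValueError(f"unknown head mode {self.mode!r}")


@dataclass
class EmbeddingBatch:
    vectors: np.ndarray  # N x 128
    labels: np.ndarray  # N, ints (0 normal / 1 sickle)
    source_ids: List[str]

    def __post_init__(self) -> None:
        if len(self.vectors) != len(self.labels) or len(self.vectors) != len(self.source_ids):
            raise ValueError("vectors, labels and source_ids must align")


class EmbeddingModel:
    """A built network plus its preprocessing and head contract."""

    def __init__(self, net: nn.Sequential, backbone: BackboneSpec, head: HeadSpec,
                 last_conv: str):
        self.net = net
        self.backbone = backbone
        self.head = head
        self.last_conv = last_conv

    @property
    def mode(self) -> str:
        return self.head.mode

    def preprocess(self, images: Sequence) -> np.ndarray:
        """uint8 HWC images -> float NCHW in [0, 1], resized to input_size."""
        s = self.backbone.input_size
        out = np.empty((len(images), 3, s, s))
        for i, im in enumerate(images):
            px = im.pixels if isinstance(im, SmearImage) else np.asarray(im)
            arr = px.astype(float) / 255.0
            if arr.shape[:2] != (s, s):
                arr = resize(arr, (s, s), order=1, preserve_range=True,
                             anti_aliasing=True)
            out[i] = arr.transpose(2, 0, 1)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-sigmoid scores (probability mode only)."""
        if self.mode != "probability":
            raise ValueError("logits are only defined for probability-head models")
        self.net.forward(x, train=train)
        return self.net.outputs["head"][:, 0]

    def save(self, path: str) -> None:
        state = self.net.state_dict()
        meta = dict(
            backbone=self.backbone.name, input_size=self.backbone.input_size,
            mode=self.head.mode, dropout=self.head.dropout,
        )
        np.savez(path, __meta__=np.array([json.dumps(meta)]), **state)

    @classmethod
    def load(cls, path: str) -> "EmbeddingModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"][0]))
        model = build_model(
            BackboneSpec(name=meta["backbone"], input_size=int(meta["input_size"])),
            HeadSpec(mode=meta["mode"], dropout=float(meta["dropout"])),
        )
        model.net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model


def build_model(backbone: BackboneSpec | str = "tinycnn",
                head: HeadSpec | str = "embedding",
                seed: int = 0) -> EmbeddingModel:
    """Assemble backbone + GAP + Dropout + BatchNorm + output head.

    The embedding head ends in ReLU (all components non-negative); the
    probability head ends in a sigmoid.  All layers are trainable — nothing
    is frozen.
    """
    if isinstance(backbone, str):
        backbone = BackboneSpec(name=backbone)
    if isinstance(head, str):
        head = HeadSpec(mode=head)
    if backbone.name != "tinycnn":
        raise NotImplementedError(
            f"backbone {backbone.name!r} needs a pretrained-model backend, "
            "which this package does not bundle; use 'tinycnn'"
        )
    if backbone.input_size % 8 != 0:
        raise ValueError("tinycnn input_size must be a multiple of 8")

    rng = np.random.default_rng(seed)
    widths = (16, 32, 64)
    layers: List[tuple] = []
    in_ch = 3
    for i, w in enumerate(widths, start=1):
        layers.append((f"conv{i}", nn.Conv2d(in_ch, w, k=3, stride=1, pad=1, rng=rng)))
        layers.append((f"relu{i}", nn.ReLU()))
        layers.append((f"pool{i}", nn.MaxPool2x2()))
        in_ch = w
    last_conv = f"conv{len(widths)}"
    layers.append(("gap", nn.GlobalAvgPool()))
    # BatchNorm ahead of Dropout so its running statistics are estimated on
    # noise-free activations.
    layers.append(("bn", nn.BatchNorm1d(in_ch)))
    layers.append(("dropout", nn.Dropout(rate=head.dropout, rng=np.random.default_rng(seed + 1))))
    if head.mode == "embedding":
        layers.append(("head", nn.Dense(in_ch, head.embedding_dim, rng=rng)))
        layers.append(("head_relu", nn.ReLU()))
    else:
        layers.append(("head", nn.Dense(in_ch, 1, rng=rng)))
        layers.append(("sigmoid", nn.Sigmoid()))
    return EmbeddingModel(nn.Sequential(layers), backbone, head, last_conv)


def embed(model: EmbeddingModel, images: Sequence,
          labels: Sequence[int] | None = None,
          source_ids: Sequence[str] | None = None,
          batch_size: int = 64) -> EmbeddingBatch:
    """Map images to 128-d embeddings (inference mode, order-preserving)."""
    if model.mode != "embedding":
        raise ValueError("embed() requires an embedding-head model")
    n = len(images)
    vecs = np.empty((n, model.head.embedding_dim))
    for start in range(0, n, batch_size):
        chunk = images[start : start + batch_size]
        x = model.preprocess(chunk)
        vecs[start : start + len(chunk)] = model.forward(x, train=False)
    labels = np.asarray(labels if labels is not None else np.full(n, -1))
    ids = list(source_ids) if source_ids is not None else [f"img_{i:05d}" for i in range(n)]
    return EmbeddingBatch(vectors=vecs, labels=labels, source_ids=ids)


def embeddings_to_frame(batch: EmbeddingBatch) -> pd.DataFrame:
    cols = {f"e{i:03d}": batch.vectors[:, i] for i in range(batch.vectors.shape[1])}
    return pd.DataFrame({"id": batch.source_ids, "label": batch.labels, **cols})


def embeddings_from_frame(frame: pd.DataFrame) -> EmbeddingBatch:
    ecols = [c for c in frame.columns if c.startswith("e")]
    return EmbeddingBatch(
        vectors=frame[ecols].to_numpy(float),
        labels=frame["label"].to_numpy(int),
        source_ids=list(frame["id"].astype(str)),
    )
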