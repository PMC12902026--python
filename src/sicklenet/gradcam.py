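"""Grad-CAM saliency maps for trained models.

For a target class score y^c and the activations A^k of the final
convolutional layer, the channel weights are the spatial means of the
gradients, alpha_k = mean_ij d y^c / d A^k_ij, and the map is

    ReLU( sum_k alpha_k A^k ),

bilinearly upsampled to the input resolution.  For probability-head models
the pre-sigmoid score (the logit) is differentiated, following the usual
"pre-softmax score" convention.  Metric-learning models have no logit; the
differentiable class score used instead is the negative squared distance to
the class centroid, -||z - mu_c||^2, whose argmax over classes coincides
with the centroid classifier's prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .classifiers import ClassCentroids
from .embedding_net import EmbeddingModel
from .synthetic import SmearImage


@dataclass
class Heatmap:
    values: np.ndarray  # H x W, >= 0
    source_layer: str
    class_index: int


def channel_weights(gradients: np.ndarray) -> np.ndarray:
    """Spatial mean per feature map: (K, H', W') -> (K,)."""
    g = np.asarray(gradients, dtype=float)
    if g.ndim != 3 or g.shape[1] == 0 or g.shape[2] == 0:
        raise ValueError("expected a non-empty K x H' x W' gradient stack")
    return g.mean(axis=(1, 2))


def embedding_class_score(z: np.ndarray, centroids: ClassCentroids, c: int
                          ) -> Tuple[float, np.ndarray]:
    """Score -||z - mu_c||^2 and its gradient -2 (z - mu_c) w.r.t. z."""
    if c not in centroids.centroids:
        raise ValueError(f"no centroid fitted for class {c}")
    z = np.asarray(z, dtype=float)
    mu = centroids.centroids[c]
    if z.shape != mu.shape:
        raise ValueError("embedding dimension does not match centroids")
    diff = z - mu
    return float(-(diff**2).sum()), -2.0 * diff


def gradcam(model: EmbeddingModel, image, class_index: int = 1,
            centroids: ClassCentroids | None = None,
            layer: str | None = None, score: str = "contrastive") -> Heatmap:
    """Grad-CAM heatmap at input resolution for one image.

    ``centroids`` is required for embedding-head models (defines the class
    score); probability-head models differentiate the logit (negated for
    class 0).

    For embedding models two scoring rules are available.  ``"centroid"``
    differentiates -||z - mu_c||^2 directly; its gradient vanishes as z
    approaches the centroid, so confidently classified images yield near-
    empty, noise-dominated maps.  The default ``"contrastive"`` score
    ||z - mu_other||^2 - ||z - mu_c||^2 (gradient 2 (mu_c - mu_other),
    never vanishing, same argmax) highlights what pushes the embedding
    toward class c rather than the alternative.
    """
    layer = layer or model.last_conv
    conv_layers = {name for name, l in model.net.layers if hasattr(l, "w") and
                   getattr(l, "k", None) is not None}
    if layer not in conv_layers:
        raise ValueError(f"{layer!r} is not a convolutional layer of this model")

    px = image.pixels if isinstance(image, SmearImage) else np.asarray(image)
    x = model.preprocess([px])
    out = model.forward(x, train=False)
    activations = model.net.outputs[layer][0]  # K x H' x W'

    if model.mode == "embedding":
        if centroids is None:
            raise ValueError("embedding-head Grad-CAM needs fitted class centroids")
        if score == "contrastive":
            others = [c for c in centroids.centroids if c != class_index]
            if not others:
                raise ValueError("contrastive score needs a second centroid")
            _, dz_c = embedding_class_score(out[0], centroids, class_index)
            _, dz_o = embedding_class_score(out[0], centroids, others[0])
            dz = dz_c - dz_o  # = 2 (mu_c - mu_other)
        elif score == "centroid":
            _, dz = embedding_class_score(out[0], centroids, class_index)
        else:
            raise ValueError(f"unknown scoring rule {score!r}")
        model.net.backward(dz[None, :])
    else:
        sign = 1.0 if class_index == 1 else -1.0
        model.net.backward(np.array([[sign]]), from_layer="head")

    grads = model.net.grads_at[layer][0]  # K x H' x W'
    alpha = channel_weights(grads)
    cam = np.maximum((alpha[:, None, None] * activations).sum(axis=0), 0.0)
    h, w = px.shape[:2]
    cam_up = resize(cam, (h, w), order=1, preserve_range=True, anti_aliasing=False)
    cam_up = np.maximum(cam_up, 0.0)
    return Heatmap(values=cam_up, source_layer=layer, class_index=class_index)


def overlay(image, heatmap: Heatmap, opacity: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend a colormapped, min-max-scaled heatmap onto the image."""
    px = image.pixels if isinstance(image, SmearImage) else np.asarray(image)
    if px.shape[:2] != heatmap.values.shape:
        raise ValueError("image and heatmap spatial dimensions differ")
    if not 0 <= opacity <= 1:
        raise ValueError("opacity must lie in [0, 1]")
    if opacity == 0:
        return px.copy()
    v = heatmap.values
    rng_ = v.max() - v.min()
    scaled = (v - v.min()) / rng_ if rng_ > 0 else np.zeros_like(v)
    colored = colormaps[cmap](scaled)[..., :3] * 255.0
    blended = (1 - opacity) * px.astype(float) + opacity * colored
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def localization_fraction(model: EmbeddingModel, images, centroids=None,
                          class_index: int = 1) -> float:
    """Share of images whose mean heatmap value inside the sickle mask
    exceeds the mean outside (the saliency sits on the sickle cells)."""
    hits = 0
    used = 0
    for im in images:
        if not isinstance(im, SmearImage) or not im.sickle_mask.any():
            continue
        if im.sickle_mask.all():
            continue
        hm = gradcam(model, im, class_index=class_index, centroids=centroids)
        inside = hm.values[im.sickle_mask].mean()
        outside = hm.values[~im.sickle_mask].mean()
        used += 1
        if inside > outside:
            hits += 1
    if used == 0:
        raise ValueError("no usable sickle-class images with masks")
    return hits / used
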