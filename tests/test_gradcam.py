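"""Grad-CAM: channel weights, closed-form toy model, overlays."""

import numpy as np
import pytest

from sicklenet import nn
from sicklenet.classifiers import centroid_predict, fit_centroids
from sicklenet.embedding_net import BackboneSpec, EmbeddingBatch, EmbeddingModel, HeadSpec
from sicklenet.gradcam import (
    Heatmap,
    channel_weights,
    embedding_class_score,
    gradcam,
    overlay,
)


class TestChannelWeights:
    def test_constant_map_gives_its_value(self):
        g = np.full((1, 4, 4), 2.5)
        assert channel_weights(g)[0] == pytest.approx(2.5)

    def test_balanced_signs_cancel(self):
        g = np.ones((1, 2, 4))
        g[0, 1] = -1
        assert channel_weights(g)[0] == pytest.approx(0.0)

    def test_matches_double_loop_mean(self, rng):
        g = rng.normal(size=(4, 3, 3))
        w = channel_weights(g)
        for k in range(4):
            total = 0.0
            for i in range(3):
                for j in range(3):
                    total += g[k, i, j]
            assert w[k] == pytest.approx(total / 9, abs=1e-12)


def toy_model(c: float, size: int = 16, n_maps: int = 3) -> EmbeddingModel:
    """Model whose class score is c * sum_{i,j,k} A^k_{i,j}.

    conv1 produces nonnegative activations (absolute-valued fixed weights on
    a nonnegative input); GAP then a dense layer with every weight c*H*W
    turns the pooled means back into c times the total activation sum.
    """
    rng = np.random.default_rng(0)
    conv = nn.Conv2d(3, n_maps, 3, 1, 1, rng=rng)
    conv.w.value = np.abs(conv.w.value)
    head = nn.Dense(n_maps, 1, rng=rng)
    head.w.value[...] = c * size * size
    head.b.value[...] = 0.0
    net = nn.Sequential([("conv1", conv), ("gap", nn.GlobalAvgPool()), ("head", head)])
    return EmbeddingModel(
        net, BackboneSpec("tinycnn", input_size=size), HeadSpec(mode="probability"),
        last_conv="conv1",
    )


class TestClosedForm:
    def test_heatmap_equals_analytic_expression(self, rng):
        c = 0.7
        model = toy_model(c)
        image = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        hm = gradcam(model, image, class_index=1)
        x = model.preprocess([image])
        acts = dict(model.net.layers)["conv1"].forward(x)[0]
        expected = np.maximum(c * acts.sum(axis=0), 0.0)
        np.testing.assert_allclose(hm.values, expected, atol=1e-5)

    def test_negative_weight_annihilated_by_relu(self, rng):
        model = toy_model(-0.5)
        image = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        hm = gradcam(model, image, class_index=1)
        assert np.allclose(hm.values, 0.0)

    def test_heatmap_nonnegative_everywhere(self, rng):
        model = toy_model(0.3)
        for _ in range(3):
            image = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
            assert gradcam(model, image, class_index=1).values.min() >= 0

    def test_non_conv_layer_rejected(self, rng):
        model = toy_model(1.0)
        image = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        with pytest.raises(ValueError):
            gradcam(model, image, layer="gap")


class TestEmbeddingScore:
    def _centroids(self, rng):
        v = rng.normal(size=(20, 8))
        y = np.array([0, 1] * 10)
        return fit_centroids(
            EmbeddingBatch(vectors=v, labels=y, source_ids=[str(i) for i in range(20)])
        )

    def test_score_maximized_at_centroid(self, rng):
        cents = self._centroids(rng)
        s, _ = embedding_class_score(cents.centroids[1], cents, 1)
        assert s == pytest.approx(0.0)
        s_off, _ = embedding_class_score(cents.centroids[1] + 0.5, cents, 1)
        assert s_off < 0

    def test_monotone_in_distance(self, rng):
        cents = self._centroids(rng)
        direction = rng.normal(size=8)
        direction /= np.linalg.norm(direction)
        scores = [
            embedding_class_score(cents.centroids[0] + t * direction, cents, 0)[0]
            for t in (0.1, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_argmax_matches_centroid_classifier(self, rng):
        cents = self._centroids(rng)
        for z in rng.normal(size=(50, 8)):
            s0, _ = embedding_class_score(z, cents, 0)
            s1, _ = embedding_class_score(z, cents, 1)
            best = 0 if s0 >= s1 else 1
            assert best == centroid_predict(cents, z)


class TestOverlay:
    def _image(self, rng):
        return rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)

    def test_zero_heatmap_uniform_blend(self, rng):
        img = self._image(rng)
        hm = Heatmap(values=np.zeros((32, 32)), source_layer="conv1", class_index=1)
        out = overlay(img, hm, opacity=0.5)
        residual = out.astype(float) - 0.5 * img.astype(float)
        # remaining component is the constant colormap floor: spatially flat
        assert np.ptp(residual.reshape(-1, 3), axis=0).max() <= 1.0

    def test_zero_opacity_returns_original(self, rng):
        img = self._image(rng)
        hm = Heatmap(values=rng.random((32, 32)), source_layer="conv1", class_index=1)
        np.testing.assert_array_equal(overlay(img, hm, opacity=0.0), img)

    def test_output_stays_in_byte_range(self, rng):
        img = self._image(rng)
        hm = Heatmap(values=rng.random((32, 32)) * 100, source_layer="conv1", class_index=1)
        out = overlay(img, hm, opacity=0.8)
        assert out.dtype == np.uint8 and out.min() >= 0 and out.max() <= 255

    def test_dims_mismatch_rejected(self, rng):
        img = self._image(rng)
        hm = Heatmap(values=np.zeros((16, 16)), source_layer="conv1", class_index=1)
        with pytest.raises(ValueError):
            overlay(img, hm)
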