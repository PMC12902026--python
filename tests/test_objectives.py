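"""Losses and mining: hand-checked values, oracles, gradients, invariances."""

import numpy as np
import pytest

from sicklenet.objectives import (
    FocalParams,
    TripletParams,
    batch_triplet_grad,
    batch_triplet_objective,
    bce_grad_logit,
    bce_loss,
    focal_grad_logit,
    focal_loss,
    pairwise_sq_distances,
    semi_hard_triplets,
    sigmoid,
    triplet_loss,
)


def oracle_semi_hard(vectors, labels, margin):
    """Independent exhaustive three-loop enumeration."""
    v = np.asarray(vectors, float)
    out = []
    for a in range(len(labels)):
        for p in range(len(labels)):
            if p == a or labels[p] != labels[a]:
                continue
            d_ap = ((v[a] - v[p]) ** 2).sum()
            for n in range(len(labels)):
                if labels[n] == labels[a]:
                    continue
                d_an = ((v[a] - v[n]) ** 2).sum()
                if d_ap < d_an < d_ap + margin:
                    out.append((a, p, n))
    return out


class TestPairwise:
    def test_three_four_five(self):
        d = pairwise_sq_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(25.0)
        assert d[1, 0] == pytest.approx(25.0)

    def test_single_vector(self):
        d = pairwise_sq_distances(np.array([[1.0, 2.0, 3.0]]))
        assert d.shape == (1, 1) and d[0, 0] == pytest.approx(0.0)

    def test_matches_double_loop(self, rng):
        v = rng.normal(size=(5, 8))
        d = pairwise_sq_distances(v)
        for i in range(5):
            for j in range(5):
                assert d[i, j] == pytest.approx(((v[i] - v[j]) ** 2).sum(), abs=1e-10)


class TestTripletLoss:
    def test_identical_triple_returns_margin(self):
        z = np.zeros(4)
        assert triplet_loss(z, z, z, TripletParams(0.5)) == pytest.approx(0.5)

    def test_easy_triplet_hinged_to_zero(self):
        assert triplet_loss([0, 0], [0, 0], [1, 0], TripletParams(0.5)) == 0.0

    def test_hand_evaluated_value(self):
        # d_ap = 0.09, d_an = 0.16 -> max(0, 0.09 - 0.16 + 0.2) = 0.13
        assert triplet_loss([0.0], [0.3], [0.4], TripletParams(0.2)) == pytest.approx(0.13)

    def test_upper_bound(self, rng):
        for _ in range(20):
            a, p, n = rng.normal(size=(3, 6))
            m = 0.3
            val = triplet_loss(a, p, n, TripletParams(m))
            assert 0 <= val <= ((a - p) ** 2).sum() + m + 1e-12


class TestSemiHardMining:
    def test_included_when_within_margin(self):
        v = np.array([[0.0], [0.1], [0.5]])
        y = np.array([0, 0, 1])
        trips = semi_hard_triplets(v, y, TripletParams(0.3))
        assert (0, 1, 2) in {(t.a, t.p, t.n) for t in trips}

    def test_excluded_when_negative_too_easy(self):
        v = np.array([[0.0], [0.1], [0.5]])
        y = np.array([0, 0, 1])
        trips = semi_hard_triplets(v, y, TripletParams(0.2))
        assert (0, 1, 2) not in {(t.a, t.p, t.n) for t in trips}

    def test_identical_embeddings_mine_nothing(self):
        v = np.zeros((6, 3))
        y = np.array([0, 0, 0, 1, 1, 1])
        assert semi_hard_triplets(v, y, TripletParams(0.5)) == []

    def test_single_class_is_empty_signal(self):
        v = np.random.default_rng(0).normal(size=(5, 2))
        assert semi_hard_triplets(v, np.zeros(5, int), TripletParams(0.5)) == []

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 17))
            v = rng.normal(size=(n, 4))
            y = rng.integers(0, 2, size=n)
            m = float(rng.uniform(0.05, 2.0))
            got = [(t.a, t.p, t.n) for t in semi_hard_triplets(v, y, TripletParams(m))]
            assert got == oracle_semi_hard(v, y, m)


class TestBatchObjective:
    def test_no_triplets_gives_zero(self):
        v = np.zeros((4, 2))
        y = np.array([0, 0, 1, 1])
        assert batch_triplet_objective(v, y, TripletParams(0.1)) == 0.0

    def test_equals_oracle_mean(self, rng):
        for _ in range(10):
            v = rng.normal(size=(8, 3))
            y = rng.integers(0, 2, size=8)
            m = 0.8
            trips = oracle_semi_hard(v, y, m)
            expected = (
                np.mean([
                    max(0.0, ((v[a] - v[p]) ** 2).sum() - ((v[a] - v[n]) ** 2).sum() + m)
                    for a, p, n in trips
                ])
                if trips
                else 0.0
            )
            assert batch_triplet_objective(v, y, TripletParams(m)) == pytest.approx(expected)

    def test_rotation_invariance(self, rng):
        v = rng.normal(size=(10, 6))
        y = rng.integers(0, 2, size=10)
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        params = TripletParams(0.5)
        assert batch_triplet_objective(v @ q, y, params) == pytest.approx(
            batch_triplet_objective(v, y, params), abs=1e-9
        )

    def test_gradient_matches_finite_differences(self, rng):
        # compact cloud + wide margin guarantees a non-empty semi-hard set
        v = 0.4 * rng.normal(size=(8, 5))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        params = TripletParams(1.0)
        loss, grad, n_mined = batch_triplet_grad(v, y, params)
        assert n_mined > 0
        eps = 1e-6
        for idx in [(0, 0), (3, 2), (7, 4)]:
            v[idx] += eps
            lp = batch_triplet_objective(v, y, params)
            v[idx] -= 2 * eps
            lm = batch_triplet_objective(v, y, params)
            v[idx] += eps
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == pytest.approx(0.5)

    def test_symmetry_identity(self):
        assert sigmoid(3.7) + sigmoid(-3.7) == pytest.approx(1.0)

    def test_value_at_ten(self):
        assert sigmoid(10.0) == pytest.approx(0.9999546, abs=1e-7)


class TestBce:
    def test_half_probability_is_ln2(self):
        assert bce_loss(1, 0.5) == pytest.approx(np.log(2), abs=1e-6)

    def test_confident_correct_near_zero(self):
        assert bce_loss(0, 1e-6) < 1e-4

    def test_hand_value(self):
        assert bce_loss(1, 0.9) == pytest.approx(0.10536, abs=1e-4)

    def test_extreme_probabilities_finite(self):
        assert np.isfinite(bce_loss(1, 0.0))
        assert np.isfinite(bce_loss(0, 1.0))

    def test_strictly_decreasing_in_yp_for_positive(self):
        grid = np.linspace(0.01, 0.99, 50)
        vals = bce_loss(np.ones_like(grid), grid)
        assert (np.diff(vals) < 0).all()

    def test_gradient_matches_finite_differences(self):
        for y in (0.0, 1.0):
            for x in (-2.0, 0.3, 4.0):
                eps = 1e-6
                num = (bce_loss(y, sigmoid(x + eps)) - bce_loss(y, sigmoid(x - eps))) / (2 * eps)
                assert bce_grad_logit(y, x) == pytest.approx(num, abs=1e-6)


class TestFocal:
    def test_reduces_to_bce(self):
        grid = np.linspace(0.001, 0.999, 500)
        params = FocalParams(alpha=1.0, gamma=0.0)
        for y in (0.0, 1.0):
            np.testing.assert_allclose(
                focal_loss(np.full_like(grid, y), grid, params),
                bce_loss(np.full_like(grid, y), grid),
                atol=1e-12,
            )

    def test_hand_value(self):
        val = focal_loss(1, 0.9, FocalParams(alpha=0.25, gamma=2.0))
        assert val == pytest.approx(0.25 * 0.01 * 0.10536, rel=1e-3)

    def test_easy_examples_downweighted_more_than_bce(self):
        params = FocalParams(alpha=0.25, gamma=2.0)
        focal_ratio = focal_loss(1, 0.99, params) / focal_loss(1, 0.6, params)
        bce_ratio = bce_loss(1, 0.99) / bce_loss(1, 0.6)
        assert focal_ratio < bce_ratio / 10

    def test_monotone_decreasing_in_pt(self):
        grid = np.linspace(0.01, 0.99, 99)
        vals = focal_loss(np.ones_like(grid), grid, FocalParams(0.5, 2.0))
        assert (np.diff(vals) < 0).all()

    def test_gradient_matches_finite_differences(self):
        params = FocalParams(alpha=0.25, gamma=2.0)
        for y in (0.0, 1.0):
            for x in (-1.5, 0.2, 2.5):
                eps = 1e-6
                num = (
                    focal_loss(y, sigmoid(x + eps), params)
                    - focal_loss(y, sigmoid(x - eps), params)
                ) / (2 * eps)
                assert focal_grad_logit(y, x, params) == pytest.approx(num, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FocalParams(alpha=0.0)
        with pytest.raises(ValueError):
            FocalParams(gamma=-1.0)
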