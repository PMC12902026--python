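"""Training protocol: stratified split, plateau rule, learning dynamics."""

import numpy as np
import pytest

from sicklenet.embedding_net import build_model
from sicklenet.synthetic import LabeledDataset, SmearImage, generate_dataset, JitterParams
from sicklenet.trainer import TrainConfig, plateau_step, split_dataset, train


def _stub_image(label, seed=0):
    pixels = np.full((64, 64, 3), 200, dtype=np.uint8)
    mask = np.zeros((64, 64), dtype=bool)
    if label == "sickle":
        mask[0, 0] = True
    return SmearImage(pixels=pixels, label=label, cells=[], sickle_mask=mask, seed=seed)


def _stub_dataset(n_normal, n_sickle):
    return LabeledDataset(
        [_stub_image("normal", i) for i in range(n_normal)]
        + [_stub_image("sickle", i) for i in range(n_sickle)]
    )


class TestSplit:
    def test_study_scale_arithmetic(self):
        ds = _stub_dataset(350, 350)
        tr, va = split_dataset(ds, 0.8, seed=0)
        assert len(tr) == 560 and len(va) == 140
        assert tr.class_counts == {"normal": 280, "sickle": 280}
        assert va.class_counts == {"normal": 70, "sickle": 70}

    def test_deterministic_given_seed(self):
        ds = _stub_dataset(20, 15)
        a = split_dataset(ds, 0.8, seed=5)
        b = split_dataset(ds, 0.8, seed=5)
        assert [im.seed for im in a[0]] == [im.seed for im in b[0]]
        assert [im.seed for im in a[1]] == [im.seed for im in b[1]]

    def test_partition_property(self):
        ds = _stub_dataset(13, 9)
        tr, va = split_dataset(ds, 0.75, seed=1)
        key = lambda im: (im.label, im.seed)
        all_keys = sorted(map(key, ds))
        assert sorted(map(key, list(tr) + list(va))) == all_keys
        assert not (set(map(key, tr)) & set(map(key, va)))

    def test_invalid_fraction_rejected(self):
        ds = _stub_dataset(4, 4)
        for f in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                split_dataset(ds, f)


class TestPlateau:
    def test_decays_after_patience_stalled_epochs(self):
        assert plateau_step([1.0, 1.01, 1.02, 1.03], 1e-4, 0.2, 3) == pytest.approx(2e-5)

    def test_improving_history_keeps_lr(self):
        assert plateau_step([1.0, 0.9, 0.8, 0.7], 1e-4, 0.2, 3) == 1e-4

    def test_improvement_resets_counter(self):
        assert plateau_step([1.0, 0.9, 0.95, 0.85], 1e-4, 0.2, 3) == 1e-4

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            plateau_step([], 1e-4)


class TestTrainContract:
    def test_zero_epochs_is_noop(self, separable_train):
        model = build_model("tinycnn", "embedding", seed=0)
        before = {k: v.copy() for k, v in model.net.state_dict().items()}
        model, history = train(model, separable_train, TrainConfig(loss="triplet", epochs=0))
        assert len(history) == 0
        after = model.net.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_head_loss_mismatch_rejected(self, separable_train):
        prob = build_model("tinycnn", "probability", seed=0)
        with pytest.raises(ValueError):
            train(prob, separable_train, TrainConfig(loss="triplet", epochs=1))
        emb = build_model("tinycnn", "embedding", seed=0)
        with pytest.raises(ValueError):
            train(emb, separable_train, TrainConfig(loss="bce", epochs=1))

    def test_default_batch_sizes_follow_loss(self):
        assert TrainConfig(loss="triplet").batch_size == 16
        assert TrainConfig(loss="bce").batch_size == 32
        assert TrainConfig(loss="focal").batch_size == 32

    def test_static_lr_without_plateau(self, separable_train):
        model = build_model("tinycnn", "embedding", seed=0)
        _, history = train(model, separable_train, TrainConfig(loss="triplet", epochs=3))
        assert history.lr == [1e-4] * 3

    def test_plateau_enabled_by_default_for_focal(self):
        assert TrainConfig(loss="focal").plateau is True
        assert TrainConfig(loss="triplet").plateau is False

    def test_validation_set_does_not_influence_weights(self, separable_train):
        """Weight updates must be a function of the training fold only."""
        tr, va = split_dataset(separable_train, 0.8, seed=0)
        other_val = LabeledDataset(list(va)[: len(va) // 2])
        cfg = TrainConfig(loss="triplet", epochs=2, seed=0)
        m1, _ = train(build_model("tinycnn", "embedding", seed=0), (tr, va), cfg)
        m2, _ = train(build_model("tinycnn", "embedding", seed=0), (tr, other_val), cfg)
        for k, v in m1.net.state_dict().items():
            np.testing.assert_array_equal(v, m2.net.state_dict()[k])


class TestLearningDynamics:
    def test_triplet_loss_decreases_on_separable_set(self):
        """Median final-epoch training loss below median first-epoch loss.

        A desk-scale learning rate is used: with 60 images there are only a
        few optimizer steps per epoch, and the check is that descending the
        mined-triplet objective actually reduces it.
        """
        firsts, finals = [], []
        for seed in (0, 1, 2):
            ds = generate_dataset(
                {"normal": 30, "sickle": 30}, jitter=JitterParams.separable(), seed=seed
            )
            model = build_model("tinycnn", "embedding", seed=seed)
            _, h = train(
                model, ds, TrainConfig(loss="triplet", epochs=5, seed=seed, lr0=5e-3)
            )
            firsts.append(h.train_loss[0])
            finals.append(h.train_loss[-1])
        assert np.median(finals) < np.median(firsts)

    def test_bce_training_improves_validation_accuracy(self):
        ds = generate_dataset(
            {"normal": 30, "sickle": 30}, jitter=JitterParams.separable(), seed=0
        )
        model = build_model("tinycnn", "probability", seed=0)
        _, h = train(model, ds, TrainConfig(loss="bce", epochs=5, seed=0))
        assert len(h) == 5
        assert h.val_accuracy[-1] >= 0.5
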