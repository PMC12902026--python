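import numpy as np
import pytest

from sicklenet.model import SmearClassificationModel
from sicklenet.synthetic import JitterParams, generate_dataset


@pytest.fixture(scope="session")
def separable_train():
    return generate_dataset(
        {"normal": 60, "sickle": 60}, jitter=JitterParams.separable(), seed=0
    )


@pytest.fixture(scope="session")
def separable_test():
    return generate_dataset(
        {"normal": 30, "sickle": 30}, jitter=JitterParams.separable(), seed=10_000
    )


@pytest.fixture(scope="session")
def triplet_runs():
    """Triplet-trained models at the scaled study size, one per seed."""
    out = {}
    for seed in (0, 1, 2):
        model = SmearClassificationModel.from_synthetic(
            n_train_per_class=60, n_test_per_class=30, seed=seed, loss="triplet"
        )
        out[seed] = model.fit(epochs=10, seed=seed)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
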