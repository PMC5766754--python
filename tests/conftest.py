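import numpy as np
import pytest

from lickmicro import LickTrain


def make_random_train(rng: np.random.Generator, n_licks: int,
                      duration: float = 3600.0, label: str = "spout") -> LickTrain:
    """Sorted, deduplicated uniform-random lick times on [0, duration]."""
    ts = np.unique(rng.uniform(0, duration, size=n_licks))
    return LickTrain(label, ts)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170501)


@pytest.fixture
def simple_train() -> LickTrain:
    # two clear clusters: [0, 0.1, 0.2] and [1.0, 1.1]
    return LickTrain("b1", np.array([0.0, 0.1, 0.2, 1.0, 1.1]))
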