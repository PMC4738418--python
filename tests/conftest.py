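import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # make oracles.py importable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_censored_data(rng, n, *, round_times=True, effect=0.7):
    """Small censored survival dataset with ties in times and predictions."""
    pi = np.round(rng.normal(size=n), 1)
    T = rng.exponential(np.exp(-effect * pi))
    C = rng.exponential(1.5, size=n)
    time = np.minimum(T, C)
    if round_times:
        time = np.round(time, 1) + 0.05
    event = (T <= C).astype(int)
    if event.sum() == 0:
        event[int(np.argmin(time))] = 1
    return pi, time, event


@pytest.fixture
def censored_data_factory():
    return random_censored_data
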