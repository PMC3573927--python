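import numpy as np
import pytest

from grangerclust.core import TimeSeriesMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tsm(values, lag_order: int = 1) -> TimeSeriesMatrix:
    values = np.asarray(values, dtype=float)
    ids = [f"g{i}" for i in range(values.shape[0])]
    return TimeSeriesMatrix(values, ids, lag_order)


def simulate_var(coeffs: np.ndarray, T: int, seed: int, burn_in: int = 200,
                 noise_sd: float = 1.0) -> np.ndarray:
    """Tiny VAR(1) simulator used as an independent data source in tests."""
    p = coeffs.shape[0]
    rng = np.random.default_rng(seed)
    x = np.zeros(p)
    out = np.empty((p, T))
    for t in range(burn_in + T):
        x = coeffs @ x + noise_sd * rng.standard_normal(p)
        if t >= burn_in:
            out[:, t - burn_in] = x
    return out


@pytest.fixture
def white_noise_tsm(rng):
    return make_tsm(rng.standard_normal((5, 120)))
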