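import numpy as np
import pytest

import permboost as pb


@pytest.fixture
def toy_outcome():
    return pb.encode_outcome([0, 1, 1, 0, 1, 0])


@pytest.fixture
def integer_design():
    """Fixed small design (n=6, p=3) with a fixed working response.

    Integer-valued so brute-force oracles are exact; column 1 is the best
    univariate predictor of u by construction.
    """
    X = np.array(
        [
            [1, 2, 0],
            [2, -1, 1],
            [0, 3, -1],
            [-1, 1, 2],
            [3, -2, 0],
            [-2, 0, 1],
        ],
        dtype=float,
    )
    u = np.array([0.4, -0.3, 0.5, -0.2, -0.5, 0.1])
    return X, u


@pytest.fixture
def small_dataset():
    """Seeded synthetic dataset, mildly informative (n=40, p=30)."""
    setting = pb.SimSetting.named("b", n=40, p=30)
    return pb.simulate_dataset(setting, seed=123)


@pytest.fixture
def zero_offset():
    def make(n):
        return pb.OffsetModel(
            mode="fixed_risk_score", coefficients=np.empty(0), offset=np.zeros(n)
        )

    return make
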