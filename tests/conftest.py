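import numpy as np
import pandas as pd
import pytest

from lurkit import GridSpec


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(n_rows=20, n_cols=20, cell_size=50.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_linear_design(n: int = 60, seed: int = 0,
                       beta=(1.0, 2.0, -3.0), noise_sd: float = 0.0):
    """Tiny deterministic regression dataset: pm25 = b0 + b1*a + b2*b (+ noise)."""
    g = np.random.default_rng(seed)
    df = pd.DataFrame({
        "a": g.normal(0, 1, n),
        "b": g.normal(0, 1, n),
        "c": g.normal(0, 1, n),
    })
    df["pm25"] = beta[0] + beta[1] * df["a"] + beta[2] * df["b"]
    if noise_sd:
        df["pm25"] += g.normal(0, noise_sd, n)
    return df
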