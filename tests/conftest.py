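import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_cloud():
    """A dense uniform single-return cloud on flat ground at elevation 100 m."""
    gen = np.random.default_rng(7)
    n = 4000
    return pd.DataFrame({
        "x": gen.uniform(0, 100, n),
        "y": gen.uniform(0, 100, n),
        "z": np.full(n, 100.0),
        "pulse": "single",
        "class": "ground",
    })


def make_cloud(heights, pulse="first", cls="vegetation"):
    """Tiny normalized cloud at the origin with the given heights."""
    heights = np.asarray(heights, dtype=float)
    return pd.DataFrame({
        "x": np.zeros_like(heights),
        "y": np.zeros_like(heights),
        "z": heights,
        "pulse": pulse,
        "class": cls,
    })


@pytest.fixture
def linear_dataset():
    """Plots whose AGB is an exact linear function of two predictors."""
    gen = np.random.default_rng(42)
    n = 40
    x1 = gen.normal(10, 3, n)
    x2 = gen.normal(5, 2, n)
    agb = 50.0 + 12.0 * x1 - 4.0 * x2
    return pd.DataFrame({
        "plot_id": [f"p{i}" for i in range(n)],
        "agb": agb, "f1": x1, "f2": x2,
    })
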