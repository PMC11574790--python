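import numpy as np
import pytest
from hypothesis import settings

from islandgame import ModelParams, TerritorySeries

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    """Default demographic/game parameters."""
    return ModelParams()


@pytest.fixture
def constant_series():
    """Factory for a constant-K annual territory series."""

    def make(K: float, years: int, t_start: float | None = None) -> TerritorySeries:
        t0 = float(years) if t_start is None else t_start
        times = t0 - np.arange(years + 1, dtype=float)
        return TerritorySeries(times_ybp=times, K=np.full(years + 1, float(K)))

    return make


@pytest.fixture
def piecewise_series():
    """Factory for an annual series built from (K, n_years) segments."""

    def make(segments) -> TerritorySeries:
        K = np.concatenate([np.full(n, float(k)) for k, n in segments])
        times = np.arange(len(K), dtype=float)[::-1]
        return TerritorySeries(times_ybp=times, K=K)

    return make
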