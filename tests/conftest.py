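import numpy as np
import pandas as pd
import pytest

from smite.climate import EmulatorConfig, emulate_climate
from smite.core import ClimateSeries, ProxyMatrix
from smite.forward import generate_pseudoproxies


@pytest.fixture(scope="session")
def century_climate():
    """A 101-year emulated climate record at a fixed seed."""
    return emulate_climate(EmulatorConfig(seed=1))


@pytest.fixture(scope="session")
def pseudoproxies(century_climate):
    """Noise-free pseudoproxies with baseline analytical sigmas."""
    return generate_pseudoproxies(century_climate, noise=None)


@pytest.fixture(scope="session")
def fixture_dataset():
    from smite.io import load_fixture

    return load_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def trailing_noise_instance():
    """Instance whose trailing singular directions carry only noise.

    Six near-duplicate proxies share one smooth signal; their differences
    (the trailing SVD components) are independent measurement noise, so
    truncation must trade in-sample fit for parameter stability.
    """
    rng = np.random.default_rng(7)
    n, p = 120, 6
    idx = pd.period_range("1990-01", periods=n, freq="M")
    t = np.arange(n)
    signal = np.sin(2 * np.pi * t / 12) + 0.3 * rng.standard_normal(n).cumsum() / np.sqrt(n)
    cols = {f"v{j}": signal + 0.15 * rng.standard_normal(n) for j in range(p)}
    A = ProxyMatrix(pd.DataFrame(cols, index=idx), {f"v{j}": 0.15 for j in range(p)})
    b = ClimateSeries("SST", pd.Series(25 + 2 * signal, index=idx), sigma=0.02)
    return A, b
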