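import numpy as np
import pytest

from tanhgrn.dataset import ExpressionDataset
from tanhgrn.dynamics import GeneParameters
from tanhgrn.simulate import benchmark_network, simulate_dataset


@pytest.fixture(scope="session")
def bench_net():
    return benchmark_network()


@pytest.fixture(scope="session")
def bench_data(bench_net):
    """Noise-free benchmark dataset (11 genes + 2 factor rows, T=59)."""
    return simulate_dataset(bench_net)


@pytest.fixture()
def toy_data():
    """Tiny 3-gene dataset generated by a known single-regulator chain.

    g2 is driven by g1 (alpha=1.5, beta=0.2, w=0.8); g1 and g3 are
    externally imposed sinusoid-like series.
    """
    rng = np.random.default_rng(42)
    T = 30
    t = np.arange(T)
    g1 = 0.8 * np.sin(2 * np.pi * t / 15)
    g3 = 0.6 * np.cos(2 * np.pi * t / 11)
    params = GeneParameters(alpha=1.5, beta=0.2, w={"g1": 0.8})
    g2 = np.empty(T)
    g2[0] = 0.1
    for k in range(T - 1):
        g2[k + 1] = g2[k] + params.alpha * np.tanh(params.w["g1"] * g1[k] - params.beta)
    values = np.vstack([g1, g2, g3])
    ds = ExpressionDataset.from_arrays(values, ["g1", "g2", "g3"])
    return ds, params
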