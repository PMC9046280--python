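import numpy as np
import pytest

from regulink import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One default-sized synthetic study shared by read-only tests."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_intervals(rng, n, n_chroms=2, span=100_000, wmin=50, wmax=800):
    """Random (chrom, start, end) triples for oracle comparisons."""
    chroms = rng.integers(1, n_chroms + 1, size=n)
    widths = rng.integers(wmin, wmax + 1, size=n)
    starts = rng.integers(0, span - wmax, size=n)
    return [
        (f"chr{c}", int(s), int(s + w))
        for c, s, w in zip(chroms, starts, widths)
    ]
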