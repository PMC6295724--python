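import numpy as np
import pytest

from intchem import gillespie_run, load_fixture


@pytest.fixture(scope="session")
def scheme1_trace():
    """A citric-acid-cycle run long enough to see linear end-product growth."""
    fx = load_fixture("scheme1")
    return gillespie_run(fx.config(seed=11, max_events=20_000))


@pytest.fixture(scope="session")
def scheme2_trace():
    """A formose run deep into the exponential regime."""
    fx = load_fixture("scheme2")
    return gillespie_run(fx.config(seed=7, max_events=40_000))


@pytest.fixture(scope="session")
def scheme5_trace():
    """An entropy-ledger run of the energy-climbing self-replicator."""
    fx = load_fixture("scheme5")
    return gillespie_run(fx.config(seed=3, max_events=30_000))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
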