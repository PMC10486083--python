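import numpy as np
import pytest

from retromir.simulate import SimConfig, simulate_all, write_outputs


@pytest.fixture(scope="session")
def sim_default():
    """One default simulation (seed 1), shared across the suite."""
    return simulate_all(SimConfig())


@pytest.fixture(scope="session")
def sim_dir(sim_default, tmp_path_factory):
    """The default simulation written to disk in every emulated format."""
    d = tmp_path_factory.mktemp("simdata")
    write_outputs(sim_default, d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
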