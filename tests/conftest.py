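import numpy as np
import pytest

import scrdens as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def tiny_traps():
    return sd.TrapArray(["T1", "T2", "T3"], np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]]))


@pytest.fixture(scope="session")
def small_array_traps():
    """One 7x7 snare array: small enough for fast repeated fitting."""
    return sd.gen_intensive_traps(n_arrays=1, dim=7, origins=[(0.0, 0.0)])


@pytest.fixture(scope="session")
def small_mask(small_array_traps):
    return sd.build_mask(small_array_traps, 12.0, nx=24)


@pytest.fixture(scope="session")
def small_sim(small_array_traps, small_mask):
    """A moderate simulated dataset on the small array (null truth)."""
    pop = sd.sim_population(8.0, small_mask, seed=101)
    data = sd.sim_captures(pop, small_array_traps, 0.15, 2.5, seed=102)
    return data


@pytest.fixture(scope="session")
def small_sim_bk(small_array_traps, small_mask):
    """Simulated data with a strong snare-specific learned response."""
    pop = sd.sim_population(8.0, small_mask, seed=103)
    return sd.sim_captures(pop, small_array_traps, 0.12, 2.5,
                           behavior=("bk", 1.5), seed=104)
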