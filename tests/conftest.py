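import numpy as np
import pytest

from dmsallo.genetics import DHFR_SEQ
from dmsallo.simulate import SimulationConfig, simulate_counts
from dmsallo.fitness import estimate_growth_rates
from dmsallo.structure import make_synthetic_chain


@pytest.fixture(scope="session")
def small_sim():
    """A 30-position selection simulation shared across tests.

    570 variants, moderate depth: large enough for the pipeline's
    categories and statistics to be populated, small enough to run in
    seconds.
    """
    config = SimulationConfig(
        n_positions=30,
        wt_protein=DHFR_SEQ[:30],
        depth=200_000,
        seed=11,
    )
    truth, counts = simulate_counts(config)
    return config, truth, counts


@pytest.fixture(scope="session")
def small_growth(small_sim):
    config, truth, counts = small_sim
    growth = estimate_growth_rates(counts, expected_variants=truth.variants)
    return truth, growth


@pytest.fixture(scope="session")
def toy_chain():
    """Synthetic 20-residue extended peptide covering all residue types."""
    return make_synthetic_chain()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_921 % 2**31)
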