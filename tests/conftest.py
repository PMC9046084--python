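import numpy as np
import pytest

from cellmix import (
    GibbsConfig,
    SimulationConfig,
    build_state_reference,
    deconvolve,
    simulate_cohort,
)


@pytest.fixture
def tiny_ref():
    """Hand-built reference: 2 types, malignant with 2 states, 4 genes."""
    counts = np.array(
        [
            [5, 5, 0, 0],   # mal state a
            [6, 4, 0, 0],
            [1, 9, 0, 0],   # mal state b
            [0, 10, 0, 0],
            [0, 0, 7, 3],   # stromal
            [0, 0, 6, 4],
        ]
    )
    states = ["malA", "malA", "malB", "malB", "str", "str"]
    types = ["mal", "mal", "mal", "mal", "stromal", "stromal"]
    genes = ["g1", "g2", "g3", "g4"]
    return build_state_reference(counts, states, types, genes, malignant_type="mal")


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort deconvolved end to end (shared across tests).

    Short chains keep this under ~10 s; the fixture returns
    (sim, bulk, truth, result).
    """
    cfg = SimulationConfig(
        n_genes=150,
        n_samples=6,
        bulk_depth=20_000,
        cells_per_state=20,
        noise_sigma=0.3,
        seed=7,
    )
    sim, bulk, truth = simulate_cohort(cfg)
    gcfg = GibbsConfig(chain_length=200, burn_in=100, thinning=2, seed=3)
    result = deconvolve(bulk, sim.ref, gcfg)
    return sim, bulk, truth, result
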