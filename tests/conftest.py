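import numpy as np
import pandas as pd
import pytest

from epilink.diffexpr import classify_de, test_two_group
from epilink.occupancy import MARKS, differential_occupancy
from epilink.simulate import SimulationConfig, simulate_study

FIXTURE_SEED = 23


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic study (shared across recovery tests)."""
    return simulate_study(SimulationConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def de_table(bundle):
    groups = [bundle.sample_groups[s] for s in bundle.counts.columns]
    return classify_de(test_two_group(bundle.counts, groups, control="control"))


@pytest.fixture(scope="session")
def occupancy_tables(bundle):
    return {
        mark: differential_occupancy(
            bundle.tracks[mark]["case"],
            bundle.tracks[mark]["control"],
            bundle.annotation,
            mark,
        )
        for mark in MARKS
    }


@pytest.fixture(scope="session")
def small_config():
    """A reduced study for pipeline-level tests (same structure, less data)."""
    return SimulationConfig(
        seed=5,
        n_genes=300,
        genome_length=6_000_000,
        n_background_enhancers=60,
    )


def nb_counts(rng, mean, dispersion, size):
    """NB sampler (gamma-Poisson) used by calibration tests."""
    if dispersion == 0:
        return rng.poisson(np.broadcast_to(mean, size))
    lam = rng.gamma(1.0 / dispersion, np.asarray(mean) * dispersion, size=size)
    return rng.poisson(lam)
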