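"""Shared fixtures: full-scale invasion ensembles used by the acceptance tests.

These are the expensive fixtures (a 2000-generation, N=1000 invasion takes
on the order of ten seconds per replicate); they are session-scoped so every
test reuses the same ensembles.
"""

import pytest

from tetrap.simulate import SelectionModel, SimulationConfig, run_ensemble
from tetrap.stats import region_counts

N_REPLICATES = 30
BASE_SEED = 2024


@pytest.fixture(scope="session")
def neutral_ensemble():
    """The standard neutral invasion scenario: u=0.1, N=1000, sampled at 2000."""
    return run_ensemble(SimulationConfig(), N_REPLICATES, base_seed=BASE_SEED)


@pytest.fixture(scope="session")
def neutral_matrix(neutral_ensemble):
    return region_counts(neutral_ensemble)


@pytest.fixture(scope="session")
def strong_selection_ensemble():
    """Same scenario under negative selection: x=0.01 at 40% of sites."""
    config = SimulationConfig(selection=SelectionModel.site_effects({0.01: 0.4}))
    return run_ensemble(config, N_REPLICATES, base_seed=BASE_SEED + 1)
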