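import numpy as np
import pytest

from bondsim import ModelParams, SimConfig, TraitConfig, run_simulation

#: trait values typical of an evolved small-neighborhood population,
#: used to freeze evolution for ecological test runs
EQUILIBRIUM_TRAITS = {"alpha": 1.2, "beta": 7.9, "dy_new": 2.0,
                      "h_a": 0.49, "h_s": 4.5}


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def eco_run():
    """A small ecological run (evolution frozen at evolved trait values).

    5 groups of 24 with 6 subgroups, 600 recorded days after a 200-day
    warm-up — large enough for bonds, associations and reciprocal helping
    to develop, small enough to share across the suite.
    """
    cfg = SimConfig(population_size=120, group_size=24, n_subgroups=6,
                    days=600, burn_in=200, seed=7,
                    traits=TraitConfig(frozen=dict(EQUILIBRIUM_TRAITS)))
    return run_simulation(cfg)
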