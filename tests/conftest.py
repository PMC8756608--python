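import numpy as np
import pytest
from hypothesis import settings

import mixedgambles as mg

# deterministic hypothesis runs
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard_conditions():
    """The default 2x2 design: maxima {20, 40}, 20 levels, 400 gambles each."""
    return mg.standard_design()


@pytest.fixture(scope="session")
def small_conditions():
    """A cheap 2x2 design: 8 levels, 64 gambles per condition."""
    return mg.standard_design(n_levels=8)


@pytest.fixture(scope="session")
def common_standard(standard_conditions):
    return mg.common_gambles(standard_conditions)


def by_label(conditions, label):
    return next(c for c in conditions if c.label == label)


@pytest.fixture(scope="session")
def small_dbs_records(small_conditions):
    """12 DbS agents, all in the LL condition, 256 trials each (4 reps x 64)."""
    pop = mg.sample_population(mg.PopulationSpec(n_agents=12, generator="dbs", seed=7))
    ll = by_label(small_conditions, "LL")
    return mg.simulate_experiment(pop, [ll], n_reps=4, seed=7)
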