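import numpy as np
import pytest

import nnsurv as ns


@pytest.fixture
def grid3():
    """The worked 3-interval grid [0,10), [10,20), [20,30)."""
    return ns.TimeGrid(np.array([10.0, 20.0, 30.0]))


@pytest.fixture(scope="session")
def two_group_cohort():
    """Default two-group exponential cohort (n=5000, medians 200/400 d)."""
    return ns.simulate_two_group(n=5000, seed=20240)


@pytest.fixture(scope="session")
def two_group_fit(two_group_cohort):
    """Flexible model (no hidden layer, 39 uniform intervals to 1780 d)
    fitted once and shared by the tests that inspect it."""
    cohort = two_group_cohort
    grid = ns.TimeGrid(np.linspace(1780 / 39, 1780, 39))
    surv_s, surv_f = ns.encode_dataset(cohort.times, cohort.events, grid)
    model = ns.SurvivalNetwork(grid, 1, (), "flexible")
    history = model.fit(cohort.covariates, surv_s, surv_f,
                        ns.TrainingConfig(seed=1, epochs=1000))
    return cohort, grid, model, history
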