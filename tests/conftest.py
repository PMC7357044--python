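import numpy as np
import pytest

import ogttscan as og
from ogttscan.simulate import SolverSettings

#: Looser tolerances for tests that run hundreds of simulations; the
#: achieved accuracy (~1e-6 mg/dL vs the tight default) is far below
#: every threshold asserted here.
COARSE = SolverSettings(rtol=1e-6, atol=1e-8)

#: Standard sampling grid of the synthetic cohorts (min).
GRID = np.array([10.0, 20.0, 30.0, 40.0, 60.0, 90.0, 120.0])


@pytest.fixture(scope="session", params=["PND21", "PND26", "PND60"])
def age(request):
    return request.param


@pytest.fixture(scope="session")
def setup(age):
    """(params, initial state, physiology) control fixture for one age."""
    return (
        og.fixtures.get_parameters(age),
        og.fixtures.get_initial_state(age),
        og.fixtures.get_physiology(age),
    )


@pytest.fixture(scope="session")
def pnd21():
    return (
        og.fixtures.get_parameters("PND21"),
        og.fixtures.get_initial_state("PND21"),
        og.fixtures.get_physiology("PND21"),
    )


@pytest.fixture(scope="session")
def pnd26():
    return (
        og.fixtures.get_parameters("PND26"),
        og.fixtures.get_initial_state("PND26"),
        og.fixtures.get_physiology("PND26"),
    )


def noiseless_dataset(k, s0, phys, grid=GRID, age="PND21", group="noiseless",
                      settings=None):
    """Cohort with no animal variability and no measurement noise: the
    means equal the model curve exactly (variances are floored).

    ``settings`` must match the settings the dataset will be scored
    with: the floored variances amplify even solver-level residuals.
    """
    kw = {} if settings is None else {"settings": settings}
    spec = og.CohortSpec(
        params=k, init=s0, phys=phys, n_animals=2, grid=tuple(grid),
        param_cv={}, obs_sd=0.0, seed=0, group=group, age=age, **kw,
    )
    return og.generate_cohort(spec)
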