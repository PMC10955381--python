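import numpy as np
import pandas as pd
import pytest

from ordcausal.model import ModelSpec, SingleDraw, fit
from ordcausal.simulate import ScmParams, simulate_population

# Ground truth shared by the fitted-posterior fixtures: a visible
# food-insecurity effect so effect-recovery tests have signal.
RECOVERY_PARAMS = ScmParams(n_sites=8, n_per_site=250, seed=20,
                            beta_m_on_y=0.8)
SMALL_PARAMS = ScmParams(n_sites=4, n_per_site=100, seed=22, beta_m_on_y=0.8)


@pytest.fixture(scope="session")
def recovery_table():
    return simulate_population(RECOVERY_PARAMS)


@pytest.fixture(scope="session")
def recovery_fit(recovery_table):
    """The big parameter-recovery fit (8 sites x 250, 4 x 1000+1000).

    Session-scoped: this is the single most expensive computation in the
    suite and is shared by the acceptance tests.
    """
    spec = ModelSpec.from_table(recovery_table, "think_freq")
    return fit(recovery_table, spec, chains=4, warmup=1000, draws=1000,
               seed=1)


@pytest.fixture(scope="session")
def small_table():
    return simulate_population(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_fit(small_table):
    """A cheaper fitted posterior for integration-style tests."""
    spec = ModelSpec.from_table(small_table, "think_freq")
    return fit(small_table, spec, chains=2, warmup=300, draws=300, seed=5)


@pytest.fixture()
def toy_spec():
    return ModelSpec(outcome="think_freq", d_age=4, d_children=3,
                     d_education=5)


@pytest.fixture()
def toy_draw(toy_spec):
    """A hand-set parameter configuration over two sites."""
    site_effects = np.zeros((6, 2))
    site_effects[0] = [0.3, -0.3]       # intercepts
    site_effects[2] = [0.1, -0.1]       # food coefficient offsets
    return SingleDraw(
        kappa=np.array([-1.0, 0.0, 1.0, 2.0]),
        beta=np.array([0.5, 0.8, -0.2, 0.1, 0.3]),
        zeta_edu=np.array([0.4, 0.3, 0.1, 0.1, 0.1]),
        zeta_age=np.array([0.25, 0.25, 0.25, 0.25]),
        zeta_children=np.array([0.5, 0.3, 0.2]),
        site_effects=site_effects,
        sites=("A", "B"),
    )


@pytest.fixture()
def toy_table():
    return pd.DataFrame({
        "site": ["A", "A", "B"],
        "sex": [1, 0, 1],
        "age": [20, 17, 21],
        "education": [3, 0, 5],
        "children": [1, 0, 3],
        "food_insecure": [1, 0, 0],
        "think_freq": [4, 2, 5],
        "ritual_freq": [3, 1, 5],
    })
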