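import numpy as np
import pytest
from hypothesis import strategies as st

from neurogen import CellState, Parameters, S52_INIT, S52_PARAMS, derived_rates


def params_strategy():
    """Valid kinetic parameter vectors across the admissible box."""
    return st.builds(
        Parameters,
        a1=st.floats(0.5, 1.0), theta1=st.floats(0.0, 1.0),
        p1=st.floats(0.05, 3.0), kappa=st.floats(0.0, 1.0),
        a2=st.floats(0.5, 1.0), theta2=st.floats(0.0, 1.0),
        p2=st.floats(0.05, 3.0), d2=st.floats(0.0, 1.0),
        p3=st.floats(0.05, 3.0), d3=st.floats(0.0, 1.0),
        d4=st.floats(0.0, 1.0), d5=st.floats(0.0, 1.0),
    )


@pytest.fixture(scope="session")
def s52_params() -> Parameters:
    return S52_PARAMS


@pytest.fixture(scope="session")
def s52_init() -> CellState:
    return S52_INIT


@pytest.fixture(scope="session")
def grid30() -> np.ndarray:
    return np.linspace(0.0, 30.0, 3001)


def random_declining_params(rng: np.random.Generator) -> Parameters:
    """Rejection-sample a parameter set in the declining regime.

    Requires a shrinking stem pool (a1*theta1 < 1/2, with margin) and a
    strictly faster net progenitor depletion (lambda2 < lambda1, with
    margin), the regime in which the analytic sign results hold.
    """
    while True:
        p = Parameters(
            a1=rng.uniform(0.5, 0.85), theta1=rng.uniform(0.15, 0.9),
            p1=rng.uniform(0.3, 1.5), kappa=rng.uniform(0.2, 0.9),
            a2=rng.uniform(0.5, 0.9), theta2=rng.uniform(0.1, 0.8),
            p2=rng.uniform(0.5, 3.0), d2=rng.uniform(0.0, 0.3),
            p3=rng.uniform(0.3, 2.0), d3=rng.uniform(0.0, 0.5),
            d4=rng.uniform(0.0, 0.1), d5=rng.uniform(0.0, 0.1),
        )
        r = derived_rates(p)
        if 0.5 - p.a1 * p.theta1 > 0.01 and r.lambda1 - r.lambda2 > 0.05:
            return p
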