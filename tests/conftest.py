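import numpy as np
import pytest

from ehkin import RateSet, ReactionConditions, kinetic_fixture


@pytest.fixture(scope="session")
def wt_ssa_rates() -> RateSet:
    """Wild-type rates for the (S,S) methylstyrene-oxide substrate."""
    return kinetic_fixture("wild_type", "SS-1a").rate_set()


@pytest.fixture(scope="session")
def wt_ssa_linear(wt_ssa_rates) -> RateSet:
    """Same, reduced to the linear three-step scheme (no conformer exchange)."""
    return wt_ssa_rates.reduced_linear()


@pytest.fixture
def mt_conditions() -> ReactionConditions:
    return ReactionConditions(E_total=1.0, S_total=1500.0)


@pytest.fixture
def short_grid() -> np.ndarray:
    return np.concatenate([[0.0], np.geomspace(1e-5, 0.5, 400)])
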