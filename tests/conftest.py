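import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from satgamble import cohort
from satgamble.core import (
    PROBABILITY_GRID_LABELS,
    Context,
    Decision,
    LadderResponse,
    adjacent_gamble,
    State,
)

_DECISION = {
    "a": Decision.ACCEPT,
    "r": Decision.REJECT,
    "c": Decision.CANT_CHOOSE,
}


def build_ladder(gamble, pattern: str) -> LadderResponse:
    """Ladder from a compact decision pattern, e.g. 'rra' = reject 1/2,
    reject 1/5, accept 1/10."""
    decisions = tuple(
        (PROBABILITY_GRID_LABELS[i], _DECISION[ch])
        for i, ch in enumerate(pattern)
    )
    return LadderResponse(gamble=gamble, decisions=decisions)


@pytest.fixture
def make_ladder():
    return build_ladder


@pytest.fixture
def personal_gamble():
    return adjacent_gamble(State.E, Context.PERSONAL)


@pytest.fixture(scope="session")
def det_cohort():
    """Deterministic heterogeneous cohort: noise-free agents, no
    can't-choose, no order violations."""
    pop = cohort.PopulationSpec(
        deterministic=True, cant_choose_rate=0.0, order_violation_rate=0.0
    )
    return cohort.simulate_cohort(120, pop, seed=11)


@pytest.fixture(scope="session")
def stoch_cohort():
    """Default stochastic cohort (study-condition population)."""
    return cohort.simulate_cohort(60, seed=12)
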