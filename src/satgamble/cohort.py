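"""Synthetic respondents with known ground truth.

Agents hold a true utility curve over the six life states and decide each
ladder step either deterministically (accept whenever the gamble's expected
utility is at least the baseline's; ties accept) or stochastically through
the same binomial logit used by the choice model, at a known sensitivity
σ. Societal-context caution is modelled by inflating the utility loss side
of the comparison by a fixed multiplier, and small-probability distortion
by an optional probability-weighting parameter pair. Every piece of
randomness flows from one seed through per-agent substreams, so an agent's
responses do not change when the cohort grows.

The default population mirrors the study conditions the analysis was built
for: 300 respondents, per-participant risk aversion λ′ centred near 0.33
with spread 0.34, a societal caution multiplier around 2.8, a 5.1% vignette
order-violation rate, and occasional can't-choose behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CHAIN_BASELINES,
    LIVING_STATES,
    PROBABILITY_GRID,
    PROBABILITY_GRID_LABELS,
    Block,
    Context,
    Decision,
    GambleSpec,
    LadderResponse,
    Respondent,
    State,
    ValidationError,
    adjacent_gamble,
)
from .weighting import CPTParams, effective_probability

#: Expected median vignette ratings for states A..E.
VIGNETTE_TARGETS: dict[State, int] = {
    State.A: 10,
    State.B: 8,
    State.C: 6,
    State.D: 4,
    State.E: 2,
}

#: Party shares matching the recruitment quotas (out of 300).
PARTY_SHARES: dict[str, float] = {
    "Conservative": 54 / 300,
    "Green": 22 / 300,
    "Labour": 141 / 300,
    "LibDem": 26 / 300,
    "Reform": 37 / 300,
    "SNP": 10 / 300,
    "Other": 10 / 300,
}

AGE_BANDS = ("18-24", "25-34", "35-44", "45-54", "55+")


@dataclass(frozen=True)
class AgentSpec:
    """Ground-truth description of one simulated respondent."""

    true_utilities: Mapping[State, float]
    sensitivity: float = math.inf  # sigma; inf = deterministic
    cpt: CPTParams | None = None
    societal_multiplier: float = 1.0
    cant_choose_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_utilities", dict(self.true_utilities))
        vals = [self.true_utilities[s] for s in sorted(self.true_utilities)]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValidationError("true utilities must be strictly increasing")
        if not self.sensitivity > 0:
            raise ValidationError("sensitivity must be positive (or inf)")
        if self.societal_multiplier < 1.0:
            raise ValidationError("societal multiplier must be >= 1")
        if not (0.0 <= self.cant_choose_rate < 1.0):
            raise ValidationError("cant_choose_rate must lie in [0, 1)")

    @property
    def deterministic(self) -> bool:
        return math.isinf(self.sensitivity)


def utilities_from_lambda(lam: float) -> dict[State, float]:
    """Utility curve with a constant per-step loss aversion λ: increments
    between consecutive states shrink geometrically by 1/λ from the death→E
    step (which has size 1)."""
    if not (lam > 0 and math.isfinite(lam)):
        raise ValidationError(f"lambda must be finite positive, got {lam}")
    utilities = {State.F: 0.0}
    increment = 1.0
    for s in LIVING_STATES:
        utilities[s] = utilities[State(s.rank - 1)] + increment
        increment /= lam
    return utilities


def _effective_gamble_utilities(
    agent: AgentSpec, gamble: GambleSpec
) -> tuple[float, float, float]:
    """(U_baseline, U_win, U_lose_effective); societal context magnifies the
    loss relative to baseline by the agent's societal multiplier."""
    u = agent.true_utilities
    u_b, u_w, u_l = u[gamble.baseline], u[gamble.win], u[gamble.lose]
    if gamble.context is Context.SOCIETAL and agent.societal_multiplier != 1.0:
        u_l = u_b - agent.societal_multiplier * (u_b - u_l)
    return u_b, u_w, u_l


def true_indifference_probability(agent: AgentSpec, gamble: GambleSpec) -> float:
    """Loss probability at which the agent's (unweighted) expected utility of
    the gamble equals the baseline: p = (U_w − U_b)/(U_w − U_l) after any
    societal loss scaling."""
    u_b, u_w, u_l = _effective_gamble_utilities(agent, gamble)
    return (u_w - u_b) / (u_w - u_l)


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def simulate_ladder(
    agent: AgentSpec,
    gamble: GambleSpec,
    rng: np.random.Generator | None = None,
) -> LadderResponse:
    """Walk the probability grid downward recording the agent's decisions.

    At each presented step the gamble's expected utility uses the effective
    loss probability (weighted when the agent has probability-weighting
    parameters, raw otherwise). A deterministic agent accepts iff
    EU ≥ U_baseline (ties accept); a stochastic agent accepts with the
    logit probability at its sensitivity. Presentation stops after the
    first accept, the grid end, or two consecutive can't-choose events.
    """
    if rng is None:
        rng = np.random.default_rng(agent.seed)
    u_b, u_w, u_l = _effective_gamble_utilities(agent, gamble)
    decisions: list[tuple[str, Decision]] = []
    prev_cant = False
    for lbl, p in zip(PROBABILITY_GRID_LABELS, PROBABILITY_GRID):
        if agent.cant_choose_rate > 0 and rng.random() < agent.cant_choose_rate:
            decisions.append((lbl, Decision.CANT_CHOOSE))
            if prev_cant:
                break
            prev_cant = True
            continue
        prev_cant = False
        p_eff = effective_probability(p, agent.cpt) if agent.cpt else p
        eu = p_eff * u_l + (1.0 - p_eff) * u_w
        if agent.deterministic:
            accept = eu >= u_b
        else:
            prob = _logistic(agent.sensitivity * (eu - u_b))
            accept = rng.random() < prob
        decisions.append((lbl, Decision.ACCEPT if accept else Decision.REJECT))
        if accept:
            break
    return LadderResponse(gamble=gamble, decisions=tuple(decisions))


def nonadjacent_triples() -> list[tuple[State, State, State]]:
    """All (lose, baseline, win) triples with both arms within 3 rank steps
    of the baseline and at least one arm 2–3 steps away."""
    triples = []
    for lose, base, win in combinations(State, 3):
        up, down = win.rank - base.rank, base.rank - lose.rank
        if up <= 3 and down <= 3 and max(up, down) >= 2:
            triples.append((lose, base, win))
    return triples


@dataclass(frozen=True)
class PopulationSpec:
    """Distributions the cohort's agents are drawn from.

    ``lambda_prime_mean``/``sd`` describe personal risk aversion on the
    bounded λ′ scale; ``societal_multiplier_mu``/``sigma`` are log-normal
    parameters of the societal caution factor (median exp(mu) ≈ 2.8);
    ``sigma_mu``/``sigma_sd`` are log-normal parameters of the choice
    sensitivity, ignored when ``deterministic``.
    """

    lambda_prime_mean: float = 0.33
    lambda_prime_sd: float = 0.34
    societal_multiplier_mu: float = math.log(2.8)
    societal_multiplier_sigma: float = 0.4
    deterministic: bool = False
    sigma_mu: float = math.log(20.0)
    sigma_sd: float = 2.5
    cpt: CPTParams | None = None
    cant_choose_rate: float = 0.01
    vignette_noise_sd: float = 0.8
    order_violation_rate: float = 0.051
    attention_fail_rate: float = 0.07


def draw_agent(pop: PopulationSpec, rng: np.random.Generator, seed: int) -> AgentSpec:
    lam_prime = float(
        np.clip(
            rng.normal(pop.lambda_prime_mean, pop.lambda_prime_sd), -0.95, 0.995
        )
    )
    lam = (1.0 + lam_prime) / (1.0 - lam_prime)
    multiplier = max(
        1.0,
        float(rng.lognormal(pop.societal_multiplier_mu, pop.societal_multiplier_sigma)),
    )
    sensitivity = (
        math.inf
        if pop.deterministic
        else float(rng.lognormal(pop.sigma_mu, pop.sigma_sd))
    )
    return AgentSpec(
        true_utilities=utilities_from_lambda(lam),
        sensitivity=sensitivity,
        cpt=pop.cpt,
        societal_multiplier=multiplier,
        cant_choose_rate=pop.cant_choose_rate,
        seed=seed,
    )


def make_vignette_ratings(
    rng: np.random.Generator,
    noise_sd: float = 0.8,
    violation_rate: float = 0.051,
) -> dict[State, int]:
    """Integer vignette ratings centred on (A..E) = (10, 8, 6, 4, 2).

    Gaussian noise (sd ``noise_sd``, rounded, clipped to 0–10) is added to
    each target; ratings are then sorted into the expected monotone order
    unless an order-violation event (probability ``violation_rate``) fires,
    in which case two adjacent distinct ratings are swapped to force a
    violation.
    """
    states = [State.A, State.B, State.C, State.D, State.E]
    vals = []
    for s in states:
        v = VIGNETTE_TARGETS[s]
        if noise_sd > 0:
            v += int(round(rng.normal(0.0, noise_sd)))
        vals.append(int(np.clip(v, 0, 10)))
    vals.sort(reverse=True)  # enforce A >= B >= C >= D >= E
    if rng.random() < violation_rate:
        for i in range(len(vals) - 1):
            if vals[i] != vals[i + 1]:
                vals[i], vals[i + 1] = vals[i + 1], vals[i]
                break
        else:  # all equal: force a violation by nudging one rating
            if vals[0] < 10:
                vals[2] += 1
            else:
                vals[1] -= 1
    return dict(zip(states, vals))


def design_gambles(rng: np.random.Generator) -> list[GambleSpec]:
    """The 12-gamble layout: 4 adjacent personal, 4 adjacent societal, and 4
    personal gambles over random triples with a non-adjacent arm."""
    gambles = [adjacent_gamble(b, Context.PERSONAL) for b in CHAIN_BASELINES]
    gambles += [adjacent_gamble(b, Context.SOCIETAL) for b in CHAIN_BASELINES]
    triples = nonadjacent_triples()
    for idx in rng.choice(len(triples), size=4, replace=False):
        lose, base, win = triples[int(idx)]
        gambles.append(
            GambleSpec(
                baseline=base,
                win=win,
                lose=lose,
                context=Context.PERSONAL,
                block=Block.NONADJACENT_PERSONAL,
            )
        )
    return gambles


def simulate_cohort(
    n: int,
    population: PopulationSpec | None = None,
    seed: int = 0,
) -> tuple[list[Respondent], pd.DataFrame]:
    """Simulate ``n`` respondents plus their ground-truth table.

    Reproducible given ``seed``; each agent consumes an independent
    substream, so respondent k's data is identical for any cohort size > k.
    """
    if n < 1:
        raise ValidationError("cohort size must be at least 1")
    pop = population or PopulationSpec()
    root = np.random.SeedSequence(seed)
    agent_seeds = root.spawn(n)

    parties = list(PARTY_SHARES)
    party_p = np.array([PARTY_SHARES[k] for k in parties])
    party_p = party_p / party_p.sum()

    respondents: list[Respondent] = []
    truth_rows = []
    for k, ss in enumerate(agent_seeds):
        rng = np.random.default_rng(ss)
        agent_seed = int(ss.generate_state(1)[0] % (2**31))
        agent = draw_agent(pop, rng, seed=agent_seed)
        gambles = design_gambles(rng)
        ladders = tuple(simulate_ladder(agent, g, rng) for g in gambles)
        ratings = make_vignette_ratings(
            rng,
            noise_sd=pop.vignette_noise_sd,
            violation_rate=pop.order_violation_rate,
        )
        # item loading 0.73 yields scale reliability (Cronbach alpha) ~0.70
        # after rounding to the 1-5 Likert range
        trait = rng.normal()
        items = tuple(
            int(np.clip(round(3.0 + 0.73 * trait + rng.normal()), 1, 5))
            for _ in range(5)
        )
        pid = f"S{k:04d}"
        respondents.append(
            Respondent(
                id=pid,
                condition=("gambles_first" if rng.random() < 0.5 else "ls_first"),
                age_band=str(rng.choice(AGE_BANDS)),
                sex=str(rng.choice(["female", "male"])),
                party=str(rng.choice(parties, p=party_p)),
                political_items=items,
                vignette_ratings=ratings,
                ladders=ladders,
                attention_fail=bool(rng.random() < pop.attention_fail_rate),
            )
        )
        row = {
            "participant": pid,
            "sigma": agent.sensitivity,
            "societal_multiplier": agent.societal_multiplier,
            "cpt_delta": agent.cpt.delta if agent.cpt else np.nan,
            "cpt_gamma": agent.cpt.gamma if agent.cpt else np.nan,
            "cant_choose_rate": agent.cant_choose_rate,
        }
        for s in State:
            row[f"U_{s.name}"] = agent.true_utilities[s]
        inc = [
            agent.true_utilities[State(r + 1)] - agent.true_utilities[State(r)]
            for r in range(5)
        ]
        row["true_lambda"] = inc[0] / inc[1]  # constant across steps
        truth_rows.append(row)
    return respondents, pd.DataFrame(truth_rows)
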