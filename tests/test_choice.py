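"""Binomial-logit choice model: unrolling, likelihood, fit diagnostics and
parameter recovery."""

import math

import numpy as np
import pytest

from satgamble import cohort, elicit
from satgamble.choice import (
    ChoiceModelFit,
    ChoiceObservation,
    expand_ladders,
    fit_cohort,
    fit_participant,
    mcfadden_r2,
    null_loglik,
    pct_correct,
    predict_acceptance,
)
from satgamble.cohort import AgentSpec, simulate_ladder, utilities_from_lambda
from satgamble.core import Context, State, adjacent_gamble


class TestExpandLadders:
    def test_all_presented_steps_become_observations(
        self, det_cohort, make_ladder, personal_gamble
    ):
        import dataclasses

        r = det_cohort[0][0]
        ladders = tuple(
            make_ladder(lad.gamble, "rra")
            if lad.gamble is r.ladders[0].gamble
            else lad
            for lad in r.ladders
        )
        r2 = dataclasses.replace(r, ladders=ladders)
        obs = expand_ladders(r2)
        first = [o for o in obs if o.gamble == r.ladders[0].gamble][:3]
        assert [o.chose_gamble for o in first] == [False, False, True]
        assert [o.p_loss for o in first] == [0.5, 0.2, 0.1]
        # only personal gambles contribute
        assert all(o.gamble.context is Context.PERSONAL for o in obs)

    def test_cant_choose_steps_are_omitted(self, make_ladder, personal_gamble):
        import dataclasses

        from satgamble.core import Decision

        lad = make_ladder(personal_gamble, "rca")
        steps = [
            (lbl, d) for lbl, d in lad.decisions if d is not Decision.CANT_CHOOSE
        ]
        assert len(lad.decisions) == 3 and len(steps) == 2


def replicated_observations(agent, n_replicates, seed):
    """Observations from repeatedly presenting the 4 adjacent + 4 random
    nonadjacent personal gambles to a stochastic agent."""
    rng = np.random.default_rng(seed)
    gambles = cohort.design_gambles(rng)
    personal = [g for g in gambles if g.context is Context.PERSONAL]
    obs = []
    for _ in range(n_replicates):
        for g in personal:
            lad = simulate_ladder(agent, g, rng)
            for lbl, dec in lad.decisions:
                from satgamble.core import Decision, grid_probability

                if dec is Decision.CANT_CHOOSE:
                    continue
                obs.append(
                    ChoiceObservation(
                        gamble=g,
                        p_loss=grid_probability(lbl),
                        chose_gamble=dec is Decision.ACCEPT,
                    )
                )
    return obs


class TestFit:
    def test_parameter_recovery_from_replicated_ladders(self):
        true_curve = utilities_from_lambda(2.0)
        agent = AgentSpec(true_utilities=true_curve, sensitivity=3.0)
        obs = replicated_observations(agent, n_replicates=200, seed=31)
        fit = fit_participant(obs, participant="agent")
        assert fit.converged
        assert fit.sigma == pytest.approx(3.0, rel=0.2)
        for s in (State.D, State.C, State.B, State.A):
            assert fit.utilities[s] == pytest.approx(true_curve[s], abs=0.1)

    def test_coin_flip_likelihood_limit(self):
        # sigma -> 0 makes every choice probability 1/2
        agent = AgentSpec(true_utilities=utilities_from_lambda(2.0), sensitivity=1.0)
        obs = replicated_observations(agent, n_replicates=3, seed=5)
        fit = ChoiceModelFit(
            participant="x",
            sigma=1e-12,
            utilities={s: s.rank for s in (State.D, State.C, State.B, State.A)},
            loglik=0.0,
            mcfadden_r2=0.0,
            pct_correct=0.0,
            converged=True,
            monotone=True,
        )
        r2 = mcfadden_r2(fit, obs)
        assert r2 == pytest.approx(0.0, abs=1e-9)

    def test_tied_utilities_give_half_probability(self, personal_gamble):
        fit = ChoiceModelFit(
            participant="x",
            sigma=5.0,
            utilities={State.D: 2.0, State.C: 3.0, State.B: 4.0, State.A: 5.0},
            loglik=0.0,
            mcfadden_r2=0.0,
            pct_correct=0.0,
            converged=True,
            monotone=True,
        )
        # linear utilities, adjacent gamble at p=1/2: EU equals baseline
        obs = ChoiceObservation(gamble=personal_gamble, p_loss=0.5, chose_gamble=True)
        assert predict_acceptance(fit, obs) == pytest.approx(0.5)
        # the tie counts as incorrectly predicted
        assert pct_correct(fit, [obs]) == 0.0

    def test_replicating_the_dataset_leaves_mle_unchanged(self):
        """Doubling every observation scales the log likelihood by two and
        must not move the maximiser."""
        agent = AgentSpec(true_utilities=utilities_from_lambda(2.0), sensitivity=4.0)
        obs = replicated_observations(agent, n_replicates=40, seed=13)
        fit1 = fit_participant(obs, participant="a")
        fit2 = fit_participant(obs + obs, participant="a")
        for s in (State.D, State.C, State.B, State.A):
            assert fit2.utilities[s] == pytest.approx(fit1.utilities[s], abs=5e-3)
        assert fit2.sigma == pytest.approx(fit1.sigma, rel=5e-3)
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-6)

    def test_all_accept_data_flagged_unidentified(self, personal_gamble):
        obs = [
            ChoiceObservation(gamble=personal_gamble, p_loss=p, chose_gamble=True)
            for p in (0.5, 0.2, 0.1, 0.01, 1e-3, 1e-4, 1e-5, 1e-6)
        ]
        fit = fit_participant(obs, participant="x")
        assert not fit.converged

    def test_null_equivalent_fit_has_zero_r2(self, personal_gamble):
        obs = [
            ChoiceObservation(
                gamble=personal_gamble, p_loss=0.5, chose_gamble=bool(i % 2)
            )
            for i in range(10)
        ]
        fit = ChoiceModelFit(
            participant="x",
            sigma=1e-9,
            utilities={State.D: 2.0, State.C: 3.0, State.B: 4.0, State.A: 5.0},
            loglik=null_loglik(10),
            mcfadden_r2=0.0,
            pct_correct=0.0,
            converged=True,
            monotone=True,
        )
        assert mcfadden_r2(fit, obs) == pytest.approx(0.0, abs=1e-9)

    def test_high_sensitivity_cohort_fits_well(self):
        pop = cohort.PopulationSpec(sigma_mu=math.log(50.0), sigma_sd=0.3)
        respondents, _ = cohort.simulate_cohort(25, pop, seed=17)
        init = elicit.curves_for_cohort(respondents, reporting=False)
        fits, _ = fit_cohort(respondents, init_curves=init)
        share = np.mean([f.mcfadden_r2 > 0.2 for f in fits.values()])
        assert share > 0.8

    def test_choice_model_smooths_relative_to_chained(self):
        """Across a simulated cohort the discrete-choice utilities vary less
        between participants than the exactly-identified chained ones."""
        pop = cohort.PopulationSpec(sigma_mu=math.log(8.0), sigma_sd=0.5)
        respondents, _ = cohort.simulate_cohort(40, pop, seed=19)
        chained = elicit.curves_for_cohort(respondents, reporting=False)
        fits, _ = fit_cohort(respondents, init_curves=chained)
        common = sorted(set(chained) & set(fits))
        assert len(common) >= 20
        # compare on the reporting scale (divide by U_A) where curves are
        # commensurable across participants
        for state in (State.D, State.C, State.B):
            v_chained = np.var(
                [
                    chained[pid].utilities[state] / chained[pid].utilities[State.A]
                    for pid in common
                ]
            )
            v_choice = np.var(
                [
                    fits[pid].utilities[state] / fits[pid].utilities[State.A]
                    for pid in common
                    if fits[pid].utilities[State.A] > 0
                ]
            )
            assert v_choice <= v_chained
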