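"""Indifference points, chained utility solving, and λ statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from satgamble import cohort, elicit
from satgamble.core import (
    Anchoring,
    Context,
    IndifferencePoint,
    PointStatus,
    State,
    UtilityCurve,
    ValidationError,
    adjacent_gamble,
)
from satgamble.elicit import (
    chained_utilities,
    indifference_probability,
    inverse_lambda_prime,
    lambda_from_point,
    lambda_prime,
    participant_mean_lambda_prime,
    rescale_to_reporting,
    summarize_lambda,
)

#: Values elicited λ can take for decided ladders under grid snapping.
LAMBDA_LATTICE = [0.414214, 2.162278, 6.071068, 30.622777, 315.227766,
                  3161.277660, 31621.776602, 316226.766017]


def point(p, status=None):
    if status is None:
        status = (
            PointStatus.INFINITE_AVERSION if p == 0.0 else PointStatus.INTERIOR
        )
    return IndifferencePoint(p=p, status=status)


class TestIndifferenceProbability:
    def test_reject_half_accept_fifth(self, personal_gamble, make_ladder):
        pt = indifference_probability(make_ladder(personal_gamble, "ra"))
        assert pt.p == pytest.approx(math.sqrt(0.5 * 0.2))  # 0.31623
        assert pt.status is PointStatus.INTERIOR

    def test_reject_everything_is_infinite_aversion(
        self, personal_gamble, make_ladder
    ):
        pt = indifference_probability(make_ladder(personal_gamble, "rrrrrrrr"))
        assert pt.p == 0.0
        assert pt.status is PointStatus.INFINITE_AVERSION

    def test_accept_first_step_is_maximal_tolerance(
        self, personal_gamble, make_ladder
    ):
        pt = indifference_probability(make_ladder(personal_gamble, "a"))
        assert pt.p == pytest.approx(math.sqrt(0.5))  # 0.70711
        assert pt.status is PointStatus.MAXIMAL_TOLERANCE

    def test_undecidable_ladder_has_no_p(self, personal_gamble, make_ladder):
        pt = indifference_probability(make_ladder(personal_gamble, "rcc"))
        assert pt.p is None and pt.status is PointStatus.UNDECIDABLE

    def test_cant_choose_then_accept_is_interior(
        self, personal_gamble, make_ladder
    ):
        pt = indifference_probability(make_ladder(personal_gamble, "ca"))
        assert pt.status is PointStatus.INTERIOR
        assert pt.p == pytest.approx(math.sqrt(0.2))


class TestChainedUtilities:
    def chain(self, ps, include_death=True):
        pts = {
            b: point(p)
            for b, p in zip((State.E, State.D, State.C, State.B), ps)
        }
        return chained_utilities(pts, include_death=include_death)

    def test_risk_neutral_chain_is_equally_spaced(self):
        curve = self.chain([0.5] * 4)
        assert curve.as_vector() == pytest.approx([0, 1, 2, 3, 4, 5])
        rep = rescale_to_reporting(curve)
        assert rep.as_vector() == pytest.approx([0, 0.2, 0.4, 0.6, 0.8, 1.0])

    def test_risk_averse_chain_frozen_values(self):
        # sequential substitution with p = sqrt(0.1) at every step
        p = math.sqrt(0.5 * 0.2)
        curve = self.chain([p] * 4)
        # frozen from an independent exact symbolic substitution oracle
        assert curve.as_vector() == pytest.approx(
            [0.0, 1.0, 1.462475, 1.676359, 1.775274, 1.821021], abs=5e-7
        )
        rep = rescale_to_reporting(curve)
        assert rep.utilities[State.E] == pytest.approx(0.549143, abs=5e-7)

    def test_infinite_aversion_step_is_flat_and_chain_proceeds(self):
        curve = self.chain([0.0, 0.5, 0.5, 0.5])
        u = curve.utilities
        assert u[State.D] == u[State.E] == 1.0
        # once two consecutive states coincide, the indifference relation
        # U_b = p U_l + (1-p) U_w keeps the rest of the chain flat too
        assert u[State.A] == u[State.D]
        # a flat step later in the chain leaves the earlier states intact
        curve2 = self.chain([0.5, 0.5, 0.0, 0.5])
        u2 = curve2.utilities
        assert u2[State.D] == 2.0 and u2[State.B] == u2[State.C] == 3.0

    def test_undecidable_point_blocks_the_curve(self):
        pts = {
            State.E: point(0.5),
            State.D: IndifferencePoint(p=None, status=PointStatus.UNDECIDABLE),
            State.C: point(0.5),
            State.B: point(0.5),
        }
        with pytest.raises(ValidationError):
            chained_utilities(pts)

    def test_no_death_chain_anchors_on_living_states(self):
        curve = self.chain([0.5] * 4, include_death=False)
        assert State.F not in curve.utilities
        assert curve.utilities[State.E] == 0.0
        assert curve.utilities[State.D] == 1.0
        assert curve.as_vector() == pytest.approx([0, 1, 2, 3, 4])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=0.95, allow_nan=False),
            min_size=4,
            max_size=4,
        )
    )
    def test_equation_residual_is_machine_zero(self, ps):
        """At the solved utilities, U_b - (p U_l + (1-p) U_w) vanishes for
        every chained gamble."""
        curve = self.chain(ps)
        u = curve.utilities
        for b, p in zip((State.E, State.D, State.C, State.B), ps):
            lose, win = State(b.rank - 1), State(b.rank + 1)
            residual = u[b] - (p * u[lose] + (1 - p) * u[win])
            scale = max(1.0, abs(u[win]))
            assert abs(residual) <= 1e-12 * scale


class TestRescale:
    def test_idempotent(self):
        curve = UtilityCurve(
            participant="x",
            utilities={s: s.rank / 5 for s in State},
            anchoring=Anchoring.REPORTING,
        )
        assert rescale_to_reporting(curve) == curve

    def test_flat_living_states_unchanged(self):
        curve = UtilityCurve(
            participant="x",
            utilities={State.F: 0.0, **{s: 1.0 for s in State if s != State.F}},
            anchoring=Anchoring.ESTIMATION,
        )
        assert rescale_to_reporting(curve).as_vector() == [0, 1, 1, 1, 1, 1]


class TestLambda:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.5, 1.0),
            (math.sqrt(0.1), 2.1623),
            (math.sqrt(0.001), 30.623),
            (math.sqrt(1e-5), 315.23),
        ],
    )
    def test_lambda_closed_form(self, p, expected, personal_gamble):
        rec = lambda_from_point(point(p), personal_gamble)
        assert rec.lam == pytest.approx(expected, rel=1e-4)

    def test_infinite_aversion_gives_infinite_lambda(self, personal_gamble):
        rec = lambda_from_point(
            point(0.0, PointStatus.INFINITE_AVERSION), personal_gamble
        )
        assert math.isinf(rec.lam) and rec.lam_prime == 1.0

    def test_undecidable_gives_no_record(self, personal_gamble):
        pt = IndifferencePoint(p=None, status=PointStatus.UNDECIDABLE)
        assert lambda_from_point(pt, personal_gamble) is None

    @given(st.floats(min_value=-6, max_value=6))
    def test_round_trip_identity(self, log_lam):
        lam = math.exp(log_lam)
        assert inverse_lambda_prime(lambda_prime(lam)) == pytest.approx(
            lam, rel=1e-12
        )

    @given(st.floats(min_value=0.01, max_value=100))
    def test_symmetry_about_risk_neutrality(self, lam):
        assert lambda_prime(lam) == pytest.approx(-lambda_prime(1 / lam), abs=1e-12)

    def test_known_inverse_value(self):
        assert inverse_lambda_prime(0.5) == pytest.approx(3.0)
        assert lambda_prime(1.0) == 0.0


class TestSummaries:
    def test_risk_neutral_cohort_snaps_to_lattice_floor(self):
        """Agents indifferent at p=1/2 accept the first step; the midpoint
        rule then assigns p=sqrt(1/2), i.e. lambda 0.414 for everyone."""
        pop = cohort.PopulationSpec(
            deterministic=True,
            lambda_prime_mean=0.0,
            lambda_prime_sd=0.0,
            societal_multiplier_mu=0.0,
            societal_multiplier_sigma=0.0,
            cant_choose_rate=0.0,
            order_violation_rate=0.0,
        )
        respondents, _ = cohort.simulate_cohort(10, pop, seed=5)
        summary = summarize_lambda(respondents)
        gamble_rows = summary[summary["kind"] == "gamble"]
        assert np.allclose(
            gamble_rows["median_lambda_personal"], 0.414214, atol=1e-6
        )

    def test_mean_lambda_prime_back_transform(self):
        # mean lambda' of (0.2, 0.4) is 0.3 -> lambda = 1.3/0.7
        assert inverse_lambda_prime(np.mean([0.2, 0.4])) == pytest.approx(
            1.857142857
        )

    def test_undecidable_participant_dropped_from_summary_rows(
        self, det_cohort, make_ladder
    ):
        import dataclasses

        respondents, _ = det_cohort
        keep = list(respondents[:3])
        victim = keep[0]
        new_ladders = tuple(
            make_ladder(lad.gamble, "rcc")
            if lad.gamble.block.value == "adjacent_personal"
            and lad.gamble.baseline is State.D
            else lad
            for lad in victim.ladders
        )
        keep[0] = dataclasses.replace(victim, ladders=new_ladders)
        records = elicit.lambda_records(keep)
        lp = participant_mean_lambda_prime(records, Context.PERSONAL, "all")
        assert victim.id not in lp.index and len(lp) == 2
        summary = summarize_lambda(keep)
        all_row = summary[summary["row"] == "All gambles"].iloc[0]
        assert all_row["n_personal"] == 2
        # the participant's decidable gambles still count in per-gamble rows
        e_row = summary[summary["row"] == "E vs. D/Death"].iloc[0]
        assert e_row["n_personal"] == 3

    def test_lattice_membership_for_deterministic_cohort(self, det_cohort):
        respondents, _ = det_cohort
        records = elicit.lambda_records(respondents)
        decided = records[records["lam"].notna() & np.isfinite(records["lam"])]
        for lam in decided["lam"]:
            assert any(
                math.isclose(lam, v, rel_tol=1e-5) for v in LAMBDA_LATTICE
            ), lam
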