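"""Per-participant binomial-logit choice model over the personal gambles.

Every presented accept/reject ladder step is one Bernoulli observation of

    P(accept) = exp(σ·EU_gamble) / (exp(σ·EU_gamble) + exp(σ·U_baseline)),

with EU_gamble = p·U_lose + (1−p)·U_win. The participant's utilities for
states D, C, B, A and the choice-sensitivity σ are estimated jointly by
maximum likelihood with U_F = 0, U_E = 1 held fixed (the estimation
anchoring). Fitting the 8 personal gambles (4 adjacent + 4 non-adjacent)
over-identifies the 4 free utilities, giving a fit diagnostic that the
exactly-identified chained solution lacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import (
    Context,
    Decision,
    GambleSpec,
    Respondent,
    State,
    UtilityCurve,
    ValidationError,
    grid_probability,
)

SIGMA_BOUNDS = (1e-6, 1e6)
LOGLIK_TOL = 1e-8

#: Free states estimated by the model (U_F = 0, U_E = 1 fixed).
FREE_STATES: tuple[State, ...] = (State.D, State.C, State.B, State.A)


@dataclass(frozen=True)
class ChoiceObservation:
    """One presented accept/reject ladder step."""

    gamble: GambleSpec
    p_loss: float
    chose_gamble: bool


@dataclass(frozen=True)
class ChoiceModelFit:
    participant: str
    sigma: float
    utilities: Mapping[State, float]  # D, C, B, A on the estimation scale
    loglik: float
    mcfadden_r2: float
    pct_correct: float
    converged: bool
    monotone: bool

    def utility_vector(self) -> np.ndarray:
        """Utilities of all six states (F..A) on the estimation scale."""
        u = np.empty(6)
        u[State.F.rank] = 0.0
        u[State.E.rank] = 1.0
        for s in FREE_STATES:
            u[s.rank] = self.utilities[s]
        return u


def expand_ladders(
    respondent: Respondent, contexts: Iterable[Context] = (Context.PERSONAL,)
) -> list[ChoiceObservation]:
    """Unroll every presented accept/reject step of the requested contexts
    into observations; can't-choose steps are omitted. Ordering follows the
    respondent's ladder and step order (deterministic)."""
    contexts = set(contexts)
    obs: list[ChoiceObservation] = []
    for lad in respondent.ladders:
        if lad.gamble.context not in contexts:
            continue
        for lbl, dec in lad.decisions:
            if dec is Decision.CANT_CHOOSE:
                continue
            obs.append(
                ChoiceObservation(
                    gamble=lad.gamble,
                    p_loss=grid_probability(lbl),
                    chose_gamble=dec is Decision.ACCEPT,
                )
            )
    return obs


def _design_arrays(
    observations: Sequence[ChoiceObservation],
    prob_transform: Callable[[float], float] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    p = np.array(
        [
            prob_transform(o.p_loss) if prob_transform else o.p_loss
            for o in observations
        ]
    )
    lose = np.array([o.gamble.lose.rank for o in observations])
    win = np.array([o.gamble.win.rank for o in observations])
    base = np.array([o.gamble.baseline.rank for o in observations])
    y = np.array([1.0 if o.chose_gamble else -1.0 for o in observations])
    return p, lose, win, base, y


def _negloglik(
    theta: np.ndarray,
    p: np.ndarray,
    lose: np.ndarray,
    win: np.ndarray,
    base: np.ndarray,
    y: np.ndarray,
) -> float:
    sigma = math.exp(theta[0])
    u = np.empty(6)
    u[0], u[1] = 0.0, 1.0
    u[2:] = theta[1:]
    delta = p * u[lose] + (1.0 - p) * u[win] - u[base]
    # log P = -log(1 + exp(-y * sigma * delta))
    return float(np.logaddexp(0.0, -y * sigma * delta).sum())


def null_loglik(n_obs: int) -> float:
    """Log likelihood of the coin-flip null model (P = 1/2 everywhere)."""
    return n_obs * math.log(0.5)


def fit_participant(
    observations: Sequence[ChoiceObservation],
    init: UtilityCurve | None = None,
    participant: str = "",
    prob_transform: Callable[[float], float] | None = None,
) -> ChoiceModelFit:
    """Maximum-likelihood fit of (σ, U_D, U_C, U_B, U_A) to the ladder-step
    observations, multi-started from the chained-gamble curve (when given)
    and from the linear (risk-neutral) curve; the best likelihood wins.

    Utilities are unconstrained during optimisation; monotonicity violations
    are flagged post hoc, not hidden. All-accept or all-reject data leaves σ
    unidentified: the fit is returned with ``converged=False``.
    """
    if len(observations) < 8:
        raise ValidationError(
            f"need at least 8 observations to fit, got {len(observations)}"
        )
    p, lose, win, base, y = _design_arrays(observations, prob_transform)
    one_sided = len(set(y.tolist())) < 2

    starts: list[np.ndarray] = []
    linear = np.array([0.0, 2.0, 3.0, 4.0, 5.0])  # log sigma = 0, linear curve
    starts.append(linear)
    if init is not None:
        u0 = [init.utilities.get(s, float("nan")) for s in FREE_STATES]
        if all(math.isfinite(v) for v in u0):
            starts.append(np.array([0.0, *u0]))

    log_bounds = (math.log(SIGMA_BOUNDS[0]), math.log(SIGMA_BOUNDS[1]))
    best = None
    any_success = False
    for x0 in starts:
        res = minimize(
            _negloglik,
            x0,
            args=(p, lose, win, base, y),
            method="L-BFGS-B",
            bounds=[log_bounds] + [(None, None)] * 4,
            options={"ftol": LOGLIK_TOL, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or bool(res.success)

    sigma = math.exp(best.x[0])
    utilities = {s: float(v) for s, v in zip(FREE_STATES, best.x[1:])}
    loglik = -float(best.fun)
    at_bound = sigma <= SIGMA_BOUNDS[0] * (1 + 1e-9) or sigma >= SIGMA_BOUNDS[1] * (
        1 - 1e-9
    )
    u_sorted = [1.0] + [utilities[s] for s in FREE_STATES]
    monotone = all(b >= a - 1e-9 for a, b in zip(u_sorted, u_sorted[1:]))

    fit = ChoiceModelFit(
        participant=participant,
        sigma=sigma,
        utilities=utilities,
        loglik=loglik,
        mcfadden_r2=float("nan"),
        pct_correct=float("nan"),
        converged=any_success and not one_sided and not at_bound,
        monotone=monotone,
    )
    return ChoiceModelFit(
        participant=fit.participant,
        sigma=fit.sigma,
        utilities=fit.utilities,
        loglik=fit.loglik,
        mcfadden_r2=mcfadden_r2(fit, observations, prob_transform),
        pct_correct=pct_correct(fit, observations, prob_transform),
        converged=fit.converged,
        monotone=fit.monotone,
    )


def predict_acceptance(
    fit: ChoiceModelFit,
    obs: ChoiceObservation,
    prob_transform: Callable[[float], float] | None = None,
) -> float:
    """Model probability of accepting the gamble at one observation."""
    u = fit.utility_vector()
    p = prob_transform(obs.p_loss) if prob_transform else obs.p_loss
    eu = p * u[obs.gamble.lose.rank] + (1.0 - p) * u[obs.gamble.win.rank]
    x = fit.sigma * (eu - u[obs.gamble.baseline.rank])
    if x >= 0:
        return float(1.0 / (1.0 + math.exp(-x)))
    z = math.exp(x)
    return float(z / (1.0 + z))


def mcfadden_r2(
    fit: ChoiceModelFit,
    observations: Sequence[ChoiceObservation],
    prob_transform: Callable[[float], float] | None = None,
) -> float:
    """McFadden pseudo-r² = 1 − loglik / loglik_null (null = coin flip)."""
    if not observations:
        raise ValidationError("cannot compute pseudo-r2 on zero observations")
    p, lose, win, base, y = _design_arrays(observations, prob_transform)
    theta = np.array(
        [math.log(fit.sigma), *[fit.utilities[s] for s in FREE_STATES]]
    )
    ll = -_negloglik(theta, p, lose, win, base, y)
    return float(1.0 - ll / null_loglik(len(observations)))


def pct_correct(
    fit: ChoiceModelFit,
    observations: Sequence[ChoiceObservation],
    prob_transform: Callable[[float], float] | None = None,
) -> float:
    """Fraction of observations whose choice the model predicts (P > 0.5
    for accept, P < 0.5 for reject); exact ties P = 0.5 count as incorrect."""
    if not observations:
        raise ValidationError("cannot compute pct_correct on zero observations")
    correct = 0
    for obs in observations:
        pred = predict_acceptance(fit, obs, prob_transform)
        if (pred > 0.5 and obs.chose_gamble) or (pred < 0.5 and not obs.chose_gamble):
            correct += 1
    return correct / len(observations)


def fit_cohort(
    respondents: Sequence[Respondent],
    init_curves: Mapping[str, UtilityCurve] | None = None,
    prob_transform: Callable[[float], float] | None = None,
    min_observations: int = 8,
) -> tuple[dict[str, ChoiceModelFit], dict[str, list[ChoiceObservation]]]:
    """Fit every respondent with enough personal-gamble observations;
    returns (fits, observations) keyed by participant id."""
    fits: dict[str, ChoiceModelFit] = {}
    observations: dict[str, list[ChoiceObservation]] = {}
    for r in respondents:
        obs = expand_ladders(r)
        observations[r.id] = obs
        if len(obs) < min_observations:
            continue
        init = init_curves.get(r.id) if init_curves else None
        fits[r.id] = fit_participant(
            obs, init=init, participant=r.id, prob_transform=prob_transform
        )
    return fits, observations
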