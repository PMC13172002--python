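"""Probability weighting sensitivity analysis (cumulative prospect theory).

Small loss probabilities may be over-weighted by decision makers. The
linear-in-log-odds weighting function

    w(p) = δ·p^γ / (δ·p^γ + (1−p)^γ)

is affine in log-odds: log(w/(1−w)) = γ·log(p/(1−p)) + log δ. With value
functions fixed to the identity, a standard gamble decided under weighted
probabilities is equivalent to one decided under the effective probability

    p* = w⁻(p) / (w⁻(p) + w⁺(1−p)),

so the whole elicitation pipeline can be re-run with p replaced by p*.
Parameter presets follow empirically measured weighting curves: a median
decision maker (δ=0.77, γ=0.44) and the single most extreme overweighter
observed (δ=1.19, γ=0.27); both are extrapolations below p = 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import partial
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Context,
    IndifferencePoint,
    LadderResponse,
    PointStatus,
    Respondent,
    UtilityCurve,
    ValidationError,
)
from . import elicit


@dataclass(frozen=True)
class CPTParams:
    """Parameters of the linear-in-log-odds weighting; (δ=1, γ=1) is the
    identity (no weighting)."""

    delta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.delta)
            and math.isfinite(self.gamma)
            and self.delta > 0
            and self.gamma > 0
        ):
            raise ValidationError(
                f"delta and gamma must be finite positive, got "
                f"({self.delta}, {self.gamma})"
            )

    @property
    def is_identity(self) -> bool:
        return self.delta == 1.0 and self.gamma == 1.0


IDENTITY = CPTParams(delta=1.0, gamma=1.0)

#: Named presets: median decision maker and most extreme overweighter.
PRESETS: dict[str, CPTParams] = {
    "identity": IDENTITY,
    "median": CPTParams(delta=0.77, gamma=0.44),
    "extreme": CPTParams(delta=1.19, gamma=0.27),
}


def weight(p: float, params: CPTParams) -> float:
    """Weighted probability w(p) = δp^γ / (δp^γ + (1−p)^γ)."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"probability out of [0, 1]: {p}")
    if params.is_identity:
        return p
    if p in (0.0, 1.0):
        return p
    num = params.delta * p**params.gamma
    return num / (num + (1.0 - p) ** params.gamma)


def effective_probability(
    p: float, params_loss: CPTParams, params_gain: CPTParams | None = None
) -> float:
    """Effective loss probability p* = w⁻(p)/(w⁻(p)+w⁺(1−p)) under which an
    unweighted expected-utility comparison reproduces the weighted one.

    Degenerate p ∈ {0, 1} passes through unchanged; identity parameters
    return ``p`` exactly (bit-identical downstream results).
    """
    if params_gain is None:
        params_gain = params_loss
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"probability out of [0, 1]: {p}")
    if p in (0.0, 1.0):
        return p
    if params_loss.is_identity and params_gain.is_identity:
        return p
    w_lose = weight(p, params_loss)
    w_win = weight(1.0 - p, params_gain)
    return w_lose / (w_lose + w_win)


def weighted_indifference_probability(
    ladder: LadderResponse,
    params: CPTParams,
    mode: str = "indifference",
) -> IndifferencePoint:
    """Indifference point of a ladder with probability weighting applied.

    ``mode="indifference"`` (default) transforms the log-midpoint
    indifference probability; ``mode="endpoints"`` transforms the bracketing
    grid probabilities before taking the log midpoint. Identity parameters
    return the unweighted point unchanged.
    """
    pt = elicit.indifference_probability(ladder)
    if params.is_identity or pt.status in (
        PointStatus.UNDECIDABLE,
        PointStatus.INFINITE_AVERSION,
    ):
        return pt
    if mode == "indifference":
        p_star = effective_probability(pt.p, params)
    elif mode == "endpoints":
        accepted = ladder.accepted_probabilities()
        rejected = ladder.rejected_probabilities()
        hi = effective_probability(max(accepted), params)
        lo = effective_probability(min(rejected), params) if rejected else 1.0
        p_star = math.sqrt(hi * lo)
    else:
        raise ValidationError(f"unknown weighting mode {mode!r}")
    status = (
        PointStatus.MAXIMAL_TOLERANCE
        if pt.status is PointStatus.MAXIMAL_TOLERANCE
        and math.isclose(p_star, math.sqrt(0.5))
        else PointStatus.INTERIOR
    )
    return IndifferencePoint(p=p_star, status=status)


def weighted_point_fn(params: CPTParams, mode: str = "indifference"):
    """A drop-in ``point_fn`` for the elicitation pipeline."""
    return partial(weighted_indifference_probability, params=params, mode=mode)


def weighted_lambda_records(
    respondents: Sequence[Respondent],
    params: CPTParams,
    mode: str = "indifference",
) -> pd.DataFrame:
    return elicit.lambda_records(respondents, point_fn=weighted_point_fn(params, mode))


def weighted_summarize_lambda(
    respondents: Sequence[Respondent],
    params: CPTParams,
    mode: str = "indifference",
    quantile_method: str = elicit.DEFAULT_QUANTILE_METHOD,
) -> pd.DataFrame:
    return elicit.summarize_lambda(
        respondents,
        quantile_method=quantile_method,
        point_fn=weighted_point_fn(params, mode),
    )


def weighted_curves_for_cohort(
    respondents: Sequence[Respondent],
    params: CPTParams,
    context: Context = Context.PERSONAL,
    include_death: bool = True,
    reporting: bool = True,
    mode: str = "indifference",
) -> dict[str, UtilityCurve]:
    return elicit.curves_for_cohort(
        respondents,
        context=context,
        include_death=include_death,
        reporting=reporting,
        point_fn=weighted_point_fn(params, mode),
    )


def residuals_by_probability(
    fits: Mapping[str, "ChoiceModelFit"],
    observations: Mapping[str, Sequence["ChoiceObservation"]],
    params: CPTParams | None = None,
) -> pd.DataFrame:
    """Mean acceptance residual (observed − predicted) per grid probability.

    ``params`` selects the model variant: ``None`` evaluates the plain
    expected-utility choice model, a ``CPTParams`` evaluates the same model
    with each loss probability replaced by its effective weighted value.
    Returns one row per grid probability with n and the residual (NaN for
    empty bins), plus the share of observations at p ≥ 0.01.
    """
    from .choice import predict_acceptance  # local import to avoid a cycle

    transform = (
        None if params is None else (lambda p: effective_probability(p, params))
    )
    rows: dict[float, list[float]] = {}
    total = 0
    at_least_001 = 0
    for pid, obs_list in observations.items():
        fit = fits.get(pid)
        if fit is None:
            continue
        for obs in obs_list:
            pred = predict_acceptance(fit, obs, prob_transform=transform)
            rows.setdefault(obs.p_loss, []).append(
                (1.0 if obs.chose_gamble else 0.0) - pred
            )
            total += 1
            if obs.p_loss >= 0.01:
                at_least_001 += 1
    share = at_least_001 / total if total else np.nan
    from .core import PROBABILITY_GRID

    out = []
    for p in PROBABILITY_GRID:
        resid = rows.get(p, [])
        out.append(
            {
                "p_loss": p,
                "n": len(resid),
                "mean_residual": float(np.mean(resid)) if resid else np.nan,
                "share_p_ge_0.01": share,
                "model": "cpt" if params is not None else "eum",
            }
        )
    return pd.DataFrame(out)
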