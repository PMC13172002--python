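"""From decision ladders to indifference points, chained utilities and
loss/inequality-aversion statistics.

The chained standard gamble solves U_b = p·U_l + (1−p)·U_w upward through
the adjacent gambles (baselines E, D, C, B) from the estimation anchors
U_F = 0, U_E = 1. Loss aversion at an indifference probability p is
λ = (1−p)/p — the ratio of the utility drop to the worse state over the
utility gain to the better state — and λ′ = (λ−1)/(λ+1) maps it to a
symmetric bounded scale with 0 at risk neutrality.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    CHAIN_BASELINES,
    adjacent_gamble,
    LIVING_STATES,
    Anchoring,
    Context,
    Decision,
    GambleSpec,
    IndifferencePoint,
    LadderResponse,
    LossAversionRecord,
    PointStatus,
    Respondent,
    State,
    UtilityCurve,
    ValidationError,
)

#: Quantile rule used for Table-style [Q1, Q3] summaries (median-unbiased).
DEFAULT_QUANTILE_METHOD = "median_unbiased"

#: Named adjacent-gamble subsets used in summaries.
SUBSETS: dict[str, tuple[State, ...]] = {
    "all": CHAIN_BASELINES,
    "no_death": (State.D, State.C, State.B),
    "phys_health": (State.C, State.B),
}


def indifference_probability(ladder: LadderResponse) -> IndifferencePoint:
    """Log-scale midpoint indifference probability of one ladder.

    p = sqrt(p_accept_max · p_reject_min) where p_accept_max is the highest
    accepted grid probability (0 if every step was rejected) and
    p_reject_min the lowest rejected one (1 if the first step was accepted).
    """
    if ladder.undecidable:
        return IndifferencePoint(p=None, status=PointStatus.UNDECIDABLE)
    accepted = ladder.accepted_probabilities()
    rejected = ladder.rejected_probabilities()
    p_accept_max = max(accepted) if accepted else 0.0
    p_reject_min = min(rejected) if rejected else 1.0
    if p_accept_max == 0.0:
        return IndifferencePoint(p=0.0, status=PointStatus.INFINITE_AVERSION)
    p = math.sqrt(p_accept_max * p_reject_min)
    first_accepted = ladder.decisions[0][1] is Decision.ACCEPT
    status = (
        PointStatus.MAXIMAL_TOLERANCE if first_accepted else PointStatus.INTERIOR
    )
    return IndifferencePoint(p=p, status=status)


def chained_utilities(
    points: Mapping[State, IndifferencePoint],
    participant: str = "",
    include_death: bool = True,
) -> UtilityCurve:
    """Solve the chained adjacent gambles into a utility curve (estimation
    anchoring: U_F = 0, U_E = 1).

    ``points`` maps each chain baseline (E, D, C, B) to its indifference
    point. Each step solves U_b = p·U_l + (1−p)·U_w for the win state:
    U_w = (U_b − p·U_l)/(1−p); p = 0 (infinite aversion) collapses to a
    flat step U_w = U_b. With ``include_death=False`` the death-anchored
    gamble (baseline E) is dropped; the remaining three gambles determine
    the living states up to location and scale, anchored as U_E = 0,
    U_D = 1.
    """
    baselines = CHAIN_BASELINES if include_death else CHAIN_BASELINES[1:]
    for b in baselines:
        if b not in points:
            raise ValidationError(f"missing indifference point for baseline {b.name}")
        pt = points[b]
        if pt.status is PointStatus.UNDECIDABLE:
            raise ValidationError(
                f"gamble at baseline {b.name} is undecidable; curve not estimable"
            )
        if pt.p is not None and pt.p >= 1.0:
            raise ValidationError("indifference p = 1 is not solvable")

    if include_death:
        utilities: dict[State, float] = {State.F: 0.0, State.E: 1.0}
    else:
        utilities = {State.E: 0.0, State.D: 1.0}
    for b in baselines:
        p = points[b].p
        win = State(b.rank + 1)
        lose = State(b.rank - 1)
        utilities[win] = (utilities[b] - p * utilities[lose]) / (1.0 - p)
    return UtilityCurve(
        participant=participant, utilities=utilities, anchoring=Anchoring.ESTIMATION
    )


def rescale_to_reporting(curve: UtilityCurve) -> UtilityCurve:
    """Rescale an estimation-anchored curve to the reporting scale by
    dividing through by U_A (so U_A = 1; U_F stays 0 where present)."""
    if curve.anchoring is Anchoring.REPORTING:
        return curve
    u_a = curve.utilities[State.A]
    if u_a <= 0:
        raise ValidationError("cannot rescale: U_A <= 0 (degenerate flat chain)")
    return UtilityCurve(
        participant=curve.participant,
        utilities={s: u / u_a for s, u in curve.utilities.items()},
        anchoring=Anchoring.REPORTING,
    )


def lambda_prime(lam: float) -> float:
    """Bounded symmetric transform λ′ = (λ−1)/(λ+1) ∈ (−1, 1]."""
    if not lam > 0:
        raise ValidationError(f"lambda must be positive, got {lam}")
    if math.isinf(lam):
        return 1.0
    return (lam - 1.0) / (lam + 1.0)


def inverse_lambda_prime(lam_prime: float) -> float:
    """Inverse transform λ = (1+λ′)/(1−λ′); λ′ = 1 maps to +inf."""
    if not (-1.0 < lam_prime <= 1.0):
        raise ValidationError(f"lambda_prime must lie in (-1, 1], got {lam_prime}")
    if lam_prime == 1.0:
        return math.inf
    return (1.0 + lam_prime) / (1.0 - lam_prime)


def lambda_from_point(
    point: IndifferencePoint, gamble: GambleSpec
) -> LossAversionRecord | None:
    """Loss aversion λ = (1−p)/p at an indifference point; ``None`` when the
    gamble was undecidable. p = 0 gives λ = +inf (λ′ = 1)."""
    if point.status is PointStatus.UNDECIDABLE:
        return None
    p = point.p
    lam = math.inf if p == 0.0 else (1.0 - p) / p
    return LossAversionRecord(gamble=gamble, lam=lam, lam_prime=lambda_prime(lam))


def gamble_label(gamble: GambleSpec) -> str:
    def name(s: State) -> str:
        return "Death" if s.is_death else s.name

    return f"{gamble.baseline.name} vs. {name(gamble.win)}/{name(gamble.lose)}"


def lambda_records(
    respondents: Sequence[Respondent],
    point_fn=indifference_probability,
) -> pd.DataFrame:
    """Per-(participant, gamble) loss-aversion table for every ladder.

    Columns: participant, context, block, baseline, label, involves_death,
    phys_health_only, status, lam, lam_prime. Undecidable ladders appear
    with status ``undecidable`` and NaN λ.
    """
    rows = []
    for r in respondents:
        for lad in r.ladders:
            pt = point_fn(lad)
            rec = lambda_from_point(pt, lad.gamble)
            rows.append(
                {
                    "participant": r.id,
                    "context": lad.gamble.context.value,
                    "block": lad.gamble.block.value,
                    "baseline": lad.gamble.baseline.name,
                    "label": gamble_label(lad.gamble),
                    "involves_death": lad.gamble.involves_death,
                    "phys_health_only": lad.gamble.phys_health_only,
                    "status": pt.status.value,
                    "lam": rec.lam if rec else np.nan,
                    "lam_prime": rec.lam_prime if rec else np.nan,
                    "political_score": r.political_score,
                }
            )
    return pd.DataFrame(rows)


def _quartiles(values: np.ndarray, method: str) -> tuple[float, float, float]:
    """Median and [Q1, Q3]; +inf entries are handled by rank position."""
    if len(values) == 0:
        return (np.nan, np.nan, np.nan)
    finite = np.isfinite(values)
    if finite.all():
        q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method=method)
        return float(med), float(q1), float(q3)
    # np.quantile cannot interpolate with infinities; fall back to a
    # monotone transform that the quantile positions commute with.
    lp = np.array([lambda_prime(v) for v in values])
    q1, med, q3 = np.quantile(lp, [0.25, 0.5, 0.75], method=method)
    return (
        inverse_lambda_prime(float(med)),
        inverse_lambda_prime(float(q1)),
        inverse_lambda_prime(float(q3)),
    )


def _pearson(x: pd.Series, y: pd.Series) -> tuple[float, float]:
    mask = x.notna() & y.notna()
    if mask.sum() < 3 or x[mask].nunique() < 2 or y[mask].nunique() < 2:
        return (np.nan, np.nan)
    r, p = sps.pearsonr(x[mask], y[mask])
    return float(r), float(p)


def participant_mean_lambda_prime(
    records: pd.DataFrame, context: Context, subset: str = "all"
) -> pd.Series:
    """Mean λ′ per participant over a named adjacent-gamble subset,
    dropping participants who could not decide on every relevant gamble."""
    baselines = {s.name for s in SUBSETS[subset]}
    block = (
        "adjacent_personal" if context is Context.PERSONAL else "adjacent_societal"
    )
    sel = records[
        (records["block"] == block) & (records["baseline"].isin(baselines))
    ]
    out = {}
    for pid, grp in sel.groupby("participant", sort=True):
        if len(grp) < len(baselines) or grp["lam_prime"].isna().any():
            continue  # undecidable somewhere in the subset -> dropped
        out[pid] = float(grp["lam_prime"].mean())
    return pd.Series(out, dtype=float, name=f"mean_lam_prime_{context.value}")


def summarize_lambda(
    respondents: Sequence[Respondent],
    quantile_method: str = DEFAULT_QUANTILE_METHOD,
    point_fn=indifference_probability,
) -> pd.DataFrame:
    """Median [Q1, Q3] loss/inequality aversion per adjacent gamble plus
    subset summary rows, with aversion proportions and correlations.

    Per-gamble rows report the λ distribution over participants for the
    personal and societal versions of each adjacent gamble. Summary rows
    ("All gambles", "… (no death)", "… (phys health)") first average λ′
    within participant over the subset (dropping participants with any
    undecidable gamble in it), back-transform the mean λ′ to λ, and report
    the median/quartiles of those per-participant values. Percentage
    columns give the share of participants with personal λ > 1, societal
    λ > 1, and societal ≥ personal aversion; correlation columns are
    Pearson r (with p) between λ′ values and the political-alignment score.
    """
    records = lambda_records(respondents, point_fn=point_fn)
    politics = records.groupby("participant")["political_score"].first()
    rows = []

    def correlation_block(lp_p: pd.Series, lp_s: pd.Series) -> dict:
        both = lp_p.index.intersection(lp_s.index)
        r_ps, p_ps = _pearson(lp_p[both], lp_s[both])
        r_pp, p_pp = _pearson(lp_p, politics.reindex(lp_p.index))
        r_sp, p_sp = _pearson(lp_s, politics.reindex(lp_s.index))
        pct_ge = (
            float((lp_s[both] >= lp_p[both]).mean()) if len(both) else np.nan
        )
        return {
            "pct_societal_ge_personal": pct_ge,
            "r_personal_societal": r_ps,
            "p_personal_societal": p_ps,
            "r_personal_politics": r_pp,
            "p_personal_politics": p_pp,
            "r_societal_politics": r_sp,
            "p_societal_politics": p_sp,
        }

    for baseline in CHAIN_BASELINES:
        label = gamble_label(adjacent_gamble(baseline, Context.PERSONAL))
        row: dict = {"row": label, "kind": "gamble"}
        lp_by_ctx = {}
        for ctx in Context:
            block = (
                "adjacent_personal"
                if ctx is Context.PERSONAL
                else "adjacent_societal"
            )
            sel = records[
                (records["block"] == block)
                & (records["baseline"] == baseline.name)
                & records["lam"].notna()
            ].set_index("participant")
            med, q1, q3 = _quartiles(
                sel["lam"].to_numpy(dtype=float), quantile_method
            )
            row[f"median_lambda_{ctx.value}"] = med
            row[f"q1_lambda_{ctx.value}"] = q1
            row[f"q3_lambda_{ctx.value}"] = q3
            row[f"n_{ctx.value}"] = int(len(sel))
            row[f"pct_{ctx.value}_averse"] = (
                float((sel["lam"] > 1).mean()) if len(sel) else np.nan
            )
            lp_by_ctx[ctx] = sel["lam_prime"]
        row.update(
            correlation_block(lp_by_ctx[Context.PERSONAL], lp_by_ctx[Context.SOCIETAL])
        )
        rows.append(row)

    summary_labels = {
        "phys_health": "All gambles (phys health)",
        "no_death": "All gambles (no death)",
        "all": "All gambles",
    }
    for subset, label in summary_labels.items():
        row = {"row": label, "kind": "summary"}
        lp_by_ctx = {}
        for ctx in Context:
            lp = participant_mean_lambda_prime(records, ctx, subset)
            lams = np.array([inverse_lambda_prime(v) for v in lp])
            med, q1, q3 = _quartiles(lams, quantile_method)
            row[f"median_lambda_{ctx.value}"] = med
            row[f"q1_lambda_{ctx.value}"] = q1
            row[f"q3_lambda_{ctx.value}"] = q3
            row[f"n_{ctx.value}"] = int(len(lp))
            row[f"pct_{ctx.value}_averse"] = (
                float((lp > 0).mean()) if len(lp) else np.nan
            )
            lp_by_ctx[ctx] = lp
        row.update(
            correlation_block(lp_by_ctx[Context.PERSONAL], lp_by_ctx[Context.SOCIETAL])
        )
        rows.append(row)
    return pd.DataFrame(rows)


def curves_for_cohort(
    respondents: Sequence[Respondent],
    context: Context = Context.PERSONAL,
    include_death: bool = True,
    reporting: bool = True,
    point_fn=indifference_probability,
) -> dict[str, UtilityCurve]:
    """Chained utility curves for every respondent whose relevant adjacent
    gambles were all decidable; others are omitted."""
    curves: dict[str, UtilityCurve] = {}
    for r in respondents:
        points = {
            lad.gamble.baseline: point_fn(lad)
            for lad in r.adjacent_ladders(context)
        }
        try:
            curve = chained_utilities(
                points, participant=r.id, include_death=include_death
            )
            if reporting:
                curve = rescale_to_reporting(curve)
        except ValidationError:
            continue
        curves[r.id] = curve
    return curves
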