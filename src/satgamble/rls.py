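"""Representative Life Satisfaction (RLS).

A participant's state utilities, placed at the cohort's mean vignette
rating for each state, define a monotone piecewise-linear utility function
of the 0–10 life-satisfaction scale. RLS is the constant scale value that
is, under those utilities, equivalent to an observed binned population
distribution — an equally-distributed-equivalent statistic whose curvature
comes from measured choices rather than an assumed inequality-aversion
parameter. Two aggregation readings are provided: the median-participant
certainty equivalent (the highest constant that at least half the cohort
weakly prefers to the distribution) and the mean-utility equivalent over
SD-normalised curves (equal "voting power" per participant).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    LIVING_STATES,
    BinnedLSDistribution,
    Respondent,
    State,
    UtilityCurve,
    ValidationError,
)

BISECTION_TOL = 1e-9


@dataclass(frozen=True)
class LSUtilityFunction:
    """Monotone nondecreasing piecewise-linear utility of life satisfaction.

    Below the lowest knot the lowest segment's slope extrapolates linearly;
    above the highest knot the function is constant. The inverse returns
    the lowest scale value attaining a utility.
    """

    xs: tuple[float, ...]
    us: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.xs) != len(self.us) or len(self.xs) < 2:
            raise ValidationError("need >= 2 (ls, utility) knots")
        if any(b <= a for a, b in zip(self.xs, self.xs[1:])):
            raise ValidationError("knot ls values must be strictly increasing")
        if any(b < a - 1e-12 for a, b in zip(self.us, self.us[1:])):
            raise ValidationError("knot utilities must be nondecreasing")

    @property
    def flat(self) -> bool:
        return self.us[-1] - self.us[0] <= 0.0

    def __call__(self, x: float) -> float:
        xs, us = self.xs, self.us
        if x <= xs[0]:
            slope = (us[1] - us[0]) / (xs[1] - xs[0])
            return us[0] + slope * (x - xs[0])
        if x >= xs[-1]:
            return us[-1]
        return float(np.interp(x, xs, us))

    def inverse(self, u: float, lo: float = 0.0, hi: float = 10.0) -> float:
        """Lowest ls in [lo, hi] with fn(ls) = u (bisection to 1e-9 ls).

        Utilities outside the attainable range are clamped to the nearest
        endpoint with a warning.
        """
        f_lo, f_hi = self(lo), self(hi)
        if u <= f_lo:
            if u < f_lo - 1e-12:
                warnings.warn(
                    f"utility {u} below range [{f_lo}, {f_hi}]; clamped to {lo}"
                )
            return lo
        if u > f_hi:
            warnings.warn(
                f"utility {u} above range [{f_lo}, {f_hi}]; clamped to {hi}"
            )
            return hi
        a, b = lo, hi
        while b - a > BISECTION_TOL:
            mid = 0.5 * (a + b)
            if self(mid) >= u:
                b = mid
            else:
                a = mid
        return b

    def rescaled(self, factor: float) -> "LSUtilityFunction":
        return LSUtilityFunction(
            xs=self.xs, us=tuple(u / factor for u in self.us)
        )


def vignette_x_positions(respondents: Sequence[Respondent]) -> dict[State, float]:
    """Cohort mean vignette rating per living state — the scale positions at
    which each state's utility is plotted."""
    out = {}
    for s in LIVING_STATES:
        out[s] = float(np.mean([r.vignette_ratings[s] for r in respondents]))
    return out


def curve_to_ls_function(
    curve: UtilityCurve, x_positions: Mapping[State, float]
) -> LSUtilityFunction:
    """Piecewise-linear utility of life satisfaction through the five living
    states (E..A) at their cohort scale positions."""
    pairs = sorted(
        ((x_positions[s], curve.utilities[s]) for s in LIVING_STATES),
        key=lambda t: t[0],
    )
    xs = tuple(p[0] for p in pairs)
    us = tuple(p[1] for p in pairs)
    return LSUtilityFunction(xs=xs, us=us)


def expected_utility(fn: LSUtilityFunction, dist: BinnedLSDistribution) -> float:
    """Share-weighted utility Σ share·fn(representative ls)."""
    return float(
        sum(s * fn(r) for s, r in zip(dist.shares, dist.representatives))
    )


def reference_sd(fn: LSUtilityFunction, ref: BinnedLSDistribution) -> float:
    """Population (share-weighted) standard deviation of fn under the
    reference distribution."""
    vals = np.array([fn(r) for r in ref.representatives])
    shares = np.array(ref.shares)
    mean = float(shares @ vals)
    return float(math.sqrt(shares @ (vals - mean) ** 2))


def normalize_by_reference(
    fn: LSUtilityFunction, ref: BinnedLSDistribution
) -> LSUtilityFunction:
    """Divide utilities by their SD under the reference distribution, so
    each participant's curve has unit spread over the reference population."""
    sd = reference_sd(fn, ref)
    if sd <= 0.0:
        raise ValidationError(
            "utility function is flat over the reference distribution; "
            "cannot normalise"
        )
    return fn.rescaled(sd)


def certainty_equivalent(fn: LSUtilityFunction, u: float) -> float:
    """Scale value whose utility equals ``u`` (lowest such value)."""
    return fn.inverse(u)


def median_curve(
    functions: Sequence[LSUtilityFunction], grid_points: int = 1001
) -> LSUtilityFunction:
    """Pointwise median of the cohort's utility functions on a fine grid
    (the median of nondecreasing functions is nondecreasing)."""
    xs = np.linspace(0.0, 10.0, grid_points)
    values = np.median(
        np.array([[fn(x) for x in xs] for fn in functions]), axis=0
    )
    values = np.maximum.accumulate(values)  # guard against fp ripple
    return LSUtilityFunction(xs=tuple(xs), us=tuple(values))


def rls(
    functions: Sequence[LSUtilityFunction],
    dist: BinnedLSDistribution,
    method: str = "median_participant",
) -> float:
    """Representative Life Satisfaction of ``dist`` for a cohort of utility
    functions.

    ``median_participant``: median over participants of each one's
    certainty equivalent of the distribution (invariant to any increasing
    transform of individual utilities). ``mean_utility``: the constant c
    solving Σᵢ fnᵢ(c) = Σᵢ E_dist[fnᵢ] over SD-normalised curves (flat
    curves are excluded as non-normalisable). ``median_curve``: certainty
    equivalent of the pointwise median curve.
    """
    if not functions:
        raise ValidationError("empty cohort")
    if method == "median_participant":
        ces = [certainty_equivalent(fn, expected_utility(fn, dist)) for fn in functions]
        return float(np.median(ces))
    if method == "median_curve":
        m = median_curve(functions)
        return certainty_equivalent(m, expected_utility(m, dist))
    if method == "mean_utility":
        degenerate_ref = sum(s > 0 for s in dist.shares) < 2
        if degenerate_ref:
            # every curve has zero spread over a one-point reference; the
            # equation below is solved on the raw curves (its solution is
            # the support point regardless of scaling)
            normalised = list(functions)
        else:
            normalised = []
            for fn in functions:
                try:
                    normalised.append(normalize_by_reference(fn, dist))
                except ValidationError:
                    continue  # flat curve: no preference information
            if not normalised:
                raise ValidationError("no normalisable (non-flat) curves")
        target = sum(expected_utility(fn, dist) for fn in normalised)

        def total(c: float) -> float:
            return sum(fn(c) for fn in normalised)

        lo, hi = 0.0, 10.0
        if total(lo) >= target:
            return lo
        if total(hi) <= target:
            return hi
        while hi - lo > BISECTION_TOL:
            mid = 0.5 * (lo + hi)
            if total(mid) >= target:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)
    raise ValidationError(f"unknown RLS method {method!r}")


def rls_table(
    curves_by_context: Mapping[str, Mapping[str, UtilityCurve]],
    x_positions: Mapping[State, float],
    dist: BinnedLSDistribution,
    methods: Sequence[str] = ("mean_utility", "median_participant"),
) -> "pd.DataFrame":
    """RLS per (context, method) with the difference from the distribution
    mean, mirroring the headline four-cell layout."""
    import pandas as pd

    mean_ls = dist.mean_ls
    rows = []
    for context, curves in curves_by_context.items():
        functions = [
            curve_to_ls_function(c, x_positions) for c in curves.values()
        ]
        for method in methods:
            value = rls(functions, dist, method=method)
            rows.append(
                {
                    "context": context,
                    "method": method,
                    "rls": value,
                    "difference_from_mean": value - mean_ls,
                    "n_curves": len(functions),
                }
            )
    return pd.DataFrame(rows)
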