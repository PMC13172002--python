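"""Response-validation and inference statistics.

Cronbach's alpha for the political attitude scale, Mann-Whitney U and
Pearson correlation wrappers with the conventions used throughout the
package, and minimum-detectable-effect (MDE) calculations: the analytic
critical correlation at a given sample size, and a simulated MDE for a
median shift on the bounded λ′ scale detected by the Mann-Whitney test.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core import ValidationError


def cronbach_alpha(items: np.ndarray, standardize: bool = False) -> float:
    """Cronbach's alpha of an n×k item matrix:
    α = k/(k−1) · (1 − Σ item variances / total-score variance),
    with sample (ddof=1) variances. ``standardize`` rescales each item to
    unit variance first (making α invariant to per-item rescaling)."""
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise ValidationError("need an n x k matrix with k >= 2 items")
    if np.isnan(items).any():
        raise ValidationError("missing values are not supported")
    if standardize:
        sd = items.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValidationError("zero-variance item cannot be standardised")
        items = items / sd
    k = items.shape[1]
    item_vars = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U, p) with U the statistic of
    the first sample (U = 0 when every x is below every y).

    Uses exact enumeration when the smaller group has at most 8
    observations and there are no ties, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t distribution
    on n−2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need paired samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in an input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def mde_correlation(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| that is two-sided significant at level ``alpha`` with
    sample size ``n`` (critical value of the t test, i.e. 50% power)."""
    if n < 4:
        raise ValidationError("need n >= 4")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    df = n - 2
    t = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / math.sqrt(df + t * t))


def mde_median_lambda(
    group_sizes: tuple[int, int],
    dispersion: float,
    alpha: float = 0.05,
    power: float = 0.5,
    n_sims: int = 400,
    seed: int = 0,
    max_shift: float | None = None,
    tol: float = 0.005,
) -> float:
    """Minimum detectable shift in median λ′ between two groups under the
    Mann-Whitney test.

    Groups are simulated as normal with SD ``dispersion`` (the observed
    spread of λ′) and a location shift; common random numbers across shifts
    make the simulated power monotone, so the smallest shift reaching the
    target ``power`` at level ``alpha`` is found by bisection. Stochastic
    but fully seed-controlled.
    """
    n1, n2 = group_sizes
    if n1 < 2 or n2 < 2:
        raise ValidationError("group sizes must be >= 2")
    rng = np.random.default_rng(seed)
    xs = rng.normal(0.0, dispersion, size=(n_sims, n1))
    ys = rng.normal(0.0, dispersion, size=(n_sims, n2))

    def simulated_power(shift: float) -> float:
        rejections = 0
        for i in range(n_sims):
            _, p = sps.mannwhitneyu(
                xs[i], ys[i] + shift, alternative="two-sided", method="asymptotic"
            )
            if p <= alpha:
                rejections += 1
        return rejections / n_sims

    hi = max_shift if max_shift is not None else 6.0 * dispersion
    if simulated_power(hi) < power:
        raise ValidationError(
            f"power {power} not reached even at shift {hi}; raise max_shift"
        )
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if simulated_power(mid) >= power:
            hi = mid
        else:
            lo = mid
    return hi


def validation_report(respondents) -> dict:
    """Validation summary for a respondent set: counts of quality flags,
    undecidable gambles, and the political-scale reliability."""
    items = np.array([r.political_items for r in respondents], dtype=float)
    n = len(respondents)
    return {
        "n": n,
        "n_order_violation": int(sum(r.order_violation for r in respondents)),
        "n_attention_fail": int(sum(r.attention_fail for r in respondents)),
        "n_undecidable_ladders": int(
            sum(lad.undecidable for r in respondents for lad in r.ladders)
        ),
        "cronbach_alpha_political": cronbach_alpha(items) if n >= 2 else None,
    }
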