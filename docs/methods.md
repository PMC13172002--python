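# Methods

This note states the models the package implements, the conventions and
numerical choices behind them, and what the synthetic-data generator does
and does not emulate.

## Ladder protocol and indifference points

Each gamble walks the loss probability down the fixed grid
{1/2, 1/5, 1/10, 1/100, 10⁻³, 10⁻⁴, 10⁻⁵, 10⁻⁶}. Presentation stops at the
first accept or at the grid's end; a can't-choose response is followed by
the next lower probability, and two consecutive can't-choose responses mark
the gamble undecidable. A single can't-choose at the lowest grid value is
also treated as undecidable, since no lower probability exists to resolve
it.

A decided ladder brackets the indifference probability between the highest
accepted and the lowest rejected grid value; the point estimate is their
**geometric (log-scale) midpoint**. Two boundary conventions close the
scale: rejecting every step sets p = 0 (infinite aversion, λ = ∞), and
accepting the very first step sets the unrejected side to 1, giving
p = √(1/2) ≈ 0.707 (maximal tolerance, λ ≈ 0.414). Because of the
bracketing, elicited λ can only take the lattice values
0.414, 2.162, 6.071, 30.62, 315.2, … — quartiles of λ across any cohort are
forced onto this lattice, which is a design property, not a data feature.

## Chained utilities and anchorings

With indifference probability p, the standard-gamble relation
U_b = p·U_l + (1−p)·U_w is solved for the win state,
U_w = (U_b − p·U_l)/(1−p), sequentially through the adjacent gambles with
baselines E, D, C, B. Estimation anchors U_F = 0 (death), U_E = 1; this
keeps the solve well conditioned and the lower states far from the upper
anchor, where rounding would otherwise mask strong aversion. Reporting
rescales by U_A so that U_F = 0, U_A = 1. p = 0 produces an exactly flat
step (U_w = U_b); once two states coincide, the relation forces the rest of
the chain flat as well. The solver leaves a residual of at most 1e-12
(relative) in every solved equation.

When gambles involving death are excluded — necessary for respondents with
infinite aversion to mortal risk, and for aggregation over living states —
the three remaining gambles determine the living states only up to location
and scale; the package anchors that chain as U_E = 0, U_D = 1. All
downstream uses are either ordinal (median-participant RLS) or
location/scale-free after normalisation (mean-utility RLS), so this choice
is inconsequential.

## Loss aversion and its transform

At indifference, λ = (U_b − U_l)/(U_w − U_b) = (1−p)/p: substituting
U_b = p·U_l + (1−p)·U_w gives U_b − U_l = (1−p)(U_w − U_l) and
U_w − U_b = p(U_w − U_l), whose ratio is (1−p)/p. The bounded transform
λ′ = (λ−1)/(λ+1) maps (0, ∞] onto (−1, 1] symmetrically: λ = x and
λ = 1/x land at ±the same distance from 0. Summaries average λ′ within
participant over a gamble subset (participants with any undecidable gamble
in the subset are dropped from that summary), then back-transform the mean
to λ and report the median and quartiles across participants. Infinite-λ
gambles enter these averages as λ′ = 1 and aversion proportions as λ > 1;
they are excluded only where a finite curve is required.

Subsets: *all* (four adjacent gambles), *no death* (baselines D, C, B),
*physically healthy* (gambles entirely within states A–D, i.e. baselines
C and B).

## Discrete-choice model

Every presented accept/reject step is one Bernoulli observation with
P(accept) = logistic(σ(EU_gamble − U_baseline)), EU computed from the step's
loss probability. σ and the four free utilities (U_F = 0, U_E = 1 fixed)
are estimated by L-BFGS-B on the log likelihood (tolerance 1e-8), with
σ optimised on the log scale within [1e-6, 1e6] and two starts: the
participant's chained curve and the linear (risk-neutral) curve; the better
likelihood wins. Utilities are deliberately unconstrained — monotonicity
violations are flagged, not hidden. One-sided data (all accept or all
reject) leaves σ unidentified and is flagged non-converged rather than
raising. McFadden pseudo-r² uses the coin-flip null; in
percent-correctly-predicted, an exact P = 0.5 tie counts as incorrect
(conservative and deterministic). Treating each step as an independent
observation is a modelling choice; the alternative of using only each
ladder's final bracket would discard most of the information in long
ladders.

## Probability weighting

The linear-in-log-odds family w(p) = δp^γ/(δp^γ+(1−p)^γ) satisfies
log(w/(1−w)) = γ·log(p/(1−p)) + log δ. With value functions fixed to the
identity, a weighted standard gamble is equivalent to an unweighted one at
the effective probability p* = w(p)/(w(p)+w(1−p)); the sensitivity analysis
re-runs the elicitation with the indifference probability replaced by p*.
Applying the weight at the indifference point (rather than to each grid
endpoint before the midpoint) is the package default; an endpoint-wise mode
exists behind a flag and gives nearly identical results since the transform
is smooth in log-odds. Identity parameters (δ = γ = 1) short-circuit to the
raw probability so that the weighted pipeline is bit-identical to the
unweighted one. Presets cover a median decision maker (δ = 0.77, γ = 0.44;
w(10⁻⁶) ≈ 0.002, overweighting by ~2×10³) and the most extreme overweighter
measured (δ = 1.19, γ = 0.27; w(10⁻⁶) ≈ 0.03, ~3×10⁴). Both are
extrapolations: the family has only been measured down to p = 0.01.
δ and γ are never estimated from ladder data.

## Representative Life Satisfaction

Each participant's living-state utilities, placed at the cohort's mean
vignette rating per state, define a monotone piecewise-linear utility of
the 0–10 scale (linear extrapolation below the lowest knot with the lowest
segment's slope; constant above the highest). The population distribution
enters as four bins (0–4, 5–6, 7–8, 9–10) with configurable within-bin
representative values, defaulting to midpoints (2.0, 5.5, 7.5, 9.5) — the
neutral choice where no convention is given; a sensitivity sweep over
representatives is supported because low-utility bins dominate the result.
The distribution mean reported alongside RLS is computed from the same
representatives, so RLS − mean comparisons are internally consistent.

* **median_participant** (default "median" reading): each participant's
  certainty equivalent of the distribution, then the cohort median — the
  highest constant that at least half the cohort weakly prefers to the
  distribution. Needs no cross-participant normalisation and is invariant
  to per-participant positive affine rescaling.
* **mean_utility**: curves are divided by their share-weighted standard
  deviation under the reference distribution (equal "voting power"; SD
  only, no centring — location cancels in the defining equation), then the
  constant c solving Σᵢfnᵢ(c) = ΣᵢE[fnᵢ] is found by bisection. Flat
  curves carry no preference information and are excluded; a degenerate
  one-bin reference skips normalisation (the solution is the support point
  regardless).
* **median_curve** (alternative reading): certainty equivalent of the
  pointwise-median curve, evaluated on a 1001-point grid.

All certainty equivalents invert the monotone function by bisection to
1e-9 on the scale, returning the lowest scale value attaining the utility;
utilities outside the attainable range are clamped with a warning.

## Validation statistics

Cronbach's α uses sample (ddof = 1) variances, with an optional
standardised variant. Mann-Whitney U is reported for the first sample
(U = 0 when every x lies below every y), exact for min(n) ≤ 8 without
ties, otherwise tie-corrected asymptotic. Pearson r carries a two-sided
t-test p-value. The minimum detectable correlation is the critical value
of that test — the smallest |r| significant at the given α and n, i.e. the
50%-power convention; at n = 263 it is 0.12. The minimum detectable median
λ′ shift is simulated: normal groups at the observed λ′ dispersion, common
random numbers across candidate shifts (making power monotone), bisection
to the smallest shift reaching the target power (default 50%) under the
Mann-Whitney test.

## Synthetic cohort

Agents hold a true utility curve with constant per-step loss aversion λ
(increments shrinking geometrically by 1/λ), drawn via
λ′ ~ Normal(0.33, 0.34) truncated to (−0.95, 0.995). Societal caution is a
multiplier on the loss side of the comparison, log-normal with median 2.8,
so an agent's societal aversion is its personal aversion scaled up.
Stochastic agents accept each step with the same logit probability the
choice model assumes, at sensitivity σ ~ lognormal(ln 20, 2.5) — a
heterogeneous mix of near-deterministic and noisy responders. Each step is
redrawn independently (no within-ladder consistency), can't-choose fires
independently per step at rate 0.01, vignette ratings are integer-noised
around (10, 8, 6, 4, 2) with a 5.1% order-violation rate, the five
political items load 0.73 on a latent trait (scale reliability ≈ 0.70
after Likert rounding), and party shares follow UK-style quotas. All
randomness descends from one seed through per-agent substreams, so agent
k's data is identical in any cohort of size > k.

What the generator does **not** emulate: within-ladder response
consistency (real respondents rarely flip within one ladder; simulated
noisy agents can), any dependence of aversion on demographics or politics
(by construction the political-alignment correlations are null), dropped
connections or partial completions, and the empirical relationship between
choice-model fit quality and aversion coherence — under per-step
independent noise, any noise level low enough to preserve the
personal–societal aversion correlation also produces better pseudo-r²
shares than real data shows. Passing tests therefore demonstrate correct
recovery of known data-generating processes of this family, not that real
survey data meets these assumptions. Deterministic mode (σ = ∞, ties
accept) is exact: elicited points land on the bracketing lattice and the
personal–societal correlation reflects only the multiplier spread.

## Numerical conventions

Quartiles use the median-unbiased (type-8) rule, configurable. Quantiles
of sets containing ∞ are computed through the λ′ transform, which commutes
with rank order. Exact indifference ties accept (fixing the risk-neutral
reference: accept at 1/2). Logistic probabilities are evaluated in
overflow-safe form. Bisections (RLS, certainty equivalents, MDE) run to
1e-9 on the scale variable or 0.005 on a simulated shift. JSON and CSV
outputs are byte-deterministic for a fixed config; every pipeline artifact
directory records the config, its hash, the master seed and per-filter
retention counts.

## Problem sizes

Default analyses run at the design size of 300 synthetic respondents;
parameter-recovery tests use 200 replicated ladders per agent and
simulation-based power calculations use 300–400 replicates, sizes at which
the full pipeline completes in well under a minute on a single CPU.
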