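# satgamble

Standard-gamble elicitation of life-satisfaction utilities, with tools for
measuring personal risk aversion and societal inequality aversion, testing
sensitivity to small-probability weighting, and aggregating a population's
life-satisfaction distribution into a single **Representative Life
Satisfaction (RLS)** value.

The package is aimed at well-being economists and survey methodologists who
want to move beyond averaging 0–10 life-satisfaction scores — which
implicitly assumes every scale point is worth the same to everyone — and
instead aggregate with empirically measured utility curves.

## The model

Respondents face a ladder of standard gambles: keep a certain life state
*b*, or gamble between a better state *w* and a worse state *l* (possibly
death) with loss probability *p* walked down the grid
1/2, 1/5, 1/10, 1/100, …, 1/1 000 000 until they accept. At the
indifference probability the expected-utility relation

    U_b = p·U_l + (1−p)·U_w

links the three states' utilities. Chaining this equation over the four
adjacent-state gambles (anchoring U_F = 0 for death and U_E = 1 for the
worst living state during estimation) yields a nonparametric utility curve
over the six ordinal states F (death) < E < D < C < B < A. The observed
ladder brackets the indifference point between the last rejected and first
accepted grid probability; the point estimate is their log-scale midpoint.

Loss aversion for each gamble is

    λ = (U_b − U_l)/(U_w − U_b) = (1−p)/p,      λ′ = (λ−1)/(λ+1),

with λ′ a symmetric bounded transform (0 = risk neutral, 1 = infinite
aversion). The same gambles posed from a policy-maker's perspective (choose
between an equal and an unequal distribution of outcomes, behind a veil of
uncertainty about one's own position) measure *inequality* aversion with
the identical machinery.

Three further components complete the analysis:

* **Discrete-choice model** — every presented ladder step is a Bernoulli
  observation of P(accept) = exp(σU_gamble)/(exp(σU_gamble)+exp(σU_base)),
  fitted per participant by maximum likelihood over the 8 personal gambles;
  the over-identified fit supplies McFadden pseudo-r² and
  percent-correctly-predicted diagnostics.
* **Probability weighting** — the linear-in-log-odds family
  w(p) = δp^γ/(δp^γ+(1−p)^γ) re-runs the whole pipeline with each
  probability replaced by its weighted effective value, quantifying how
  much measured aversion could be small-probability distortion
  (presets: median δ=0.77, γ=0.44; extreme δ=1.19, γ=0.27).
* **RLS** — each participant's state utilities, placed at the cohort's mean
  vignette rating per state, define a piecewise-linear utility of the 0–10
  scale; RLS is the constant scale value equivalent (by median participant,
  or by total SD-normalised utility) to a binned population distribution —
  an equally-distributed-equivalent statistic with measured curvature.

A synthetic-respondent module generates cohorts from agents with known
utility curves, choice noise, societal-caution multipliers and can't-choose
behaviour, so every stage supports parameter-recovery testing without any
survey data.

## Worked example

```python
from satgamble import cohort, elicit, rls
from satgamble.core import BinnedLSDistribution, Context

respondents, truth = cohort.simulate_cohort(300, seed=7)
kept = [r for r in respondents if not r.order_violation]

summary = elicit.summarize_lambda(kept)
print(summary[["row", "median_lambda_personal", "median_lambda_societal",
               "pct_personal_averse", "pct_societal_averse"]].round(2))
```

```
                      row  median_lambda_personal  median_lambda_societal  pct_personal_averse  pct_societal_averse
            E vs. D/Death                    2.16                    6.07                 0.73                 0.91
                D vs. C/E                    2.16                    6.07                 0.65                 0.84
                C vs. B/D                    2.16                    2.16                 0.61                 0.84
                B vs. A/C                    2.16                    2.16                 0.58                 0.76
All gambles (phys health)                    1.36                    2.16                 0.56                 0.79
   All gambles (no death)                    1.58                    2.51                 0.67                 0.88
              All gambles                    1.70                    2.73                 0.68                 0.90
```

Per-gamble medians land on the grid lattice (2.16, 6.07, …) because a
ladder can only bracket indifference between adjacent grid values; summary
rows average λ′ within participant first and therefore move off the
lattice. Societal medians sit above personal ones — the simulated agents,
like survey respondents, are more cautious with other people's outcomes —
and most of the cohort is averse in both senses (λ > 1).

```python
dist = BinnedLSDistribution(shares=(0.06, 0.10, 0.50, 0.34))  # 0-4, 5-6, 7-8, 9-10
x_pos = rls.vignette_x_positions(kept)
curves = {ctx.value: elicit.curves_for_cohort(kept, context=ctx, include_death=False)
          for ctx in Context}
print(rls.rls_table(curves, x_pos, dist).round(2))
```

```
 context             method  rls  difference_from_mean  n_curves
personal       mean_utility 7.53                 -0.12       288
personal median_participant 7.01                 -0.64       288
societal       mean_utility 6.59                 -1.06       288
societal median_participant 5.83                 -1.82       288
```

The distribution's mean is 7.65, but its *representative* value is lower
under every elicited curve: the societal median-participant reading says a
uniform life satisfaction of 5.83 would be judged as good as the unequal
status quo — the cohort would trade 1.8 scale points of average well-being
for full equality.

The same stages are available from the command line:

```sh
satgamble simulate -n 300 --seed 7 -o cohort.csv --truth truth.csv
satgamble elicit cohort.csv -o lambda_summary.csv
satgamble rls cohort.csv -o rls.csv
satgamble run --seed 7 -o artifacts/        # full pipeline
```

## Layout

| module | contents |
| --- | --- |
| `satgamble.core` | states, gambles, ladders, respondents, distributions |
| `satgamble.io` | long-format respondent CSV, distribution CSV, JSON |
| `satgamble.cohort` | synthetic agents and cohort simulation |
| `satgamble.elicit` | indifference points, chained curves, λ summaries |
| `satgamble.choice` | per-participant binomial-logit fits and diagnostics |
| `satgamble.weighting` | probability weighting and weighted re-analysis |
| `satgamble.rls` | life-satisfaction utility functions and RLS |
| `satgamble.stats` | Cronbach's α, Mann-Whitney, Pearson r, MDEs |
| `satgamble.pipeline` / `satgamble.cli` | end-to-end runs and the CLI |

See `docs/methods.md` for the full statement of the model, the numerical
conventions, and known limitations of the synthetic generator.
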