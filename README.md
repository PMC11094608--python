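# idiolm — individual-level Bayesian linear models for daily stress and sleep

`idiolm` is an idiographic (N-of-1) analysis toolkit for intensive
longitudinal data: a full academic year of actigraphy-derived nightly sleep
durations paired with brief evening self-reports of perceived stress and
sleep quality on 1–5 Likert scales.  Instead of pooling everyone into one
group model, it fits **each participant their own linear model** — treating
that person's days as the observations — and summarizes the result with
Bayesian decision rules, so that the direction and strength of the
stress–sleep relationship can differ from person to person.

## The model

For one participant, with `y_t` the sleep duration (minutes) of the night
ending on day *t* and `x` the Likert predictor (stress or sleep quality) on
day *t* or *t−1*:

```
y_t = β₀ + β₁ · x_{t or t−1} + β₂′ · DayOfWeek_t + ε_t,    ε_t ~ N(0, σ²)
```

`DayOfWeek_t` is a 7-level categorical (ordered Saturday→Friday) absorbing
the weekly sleep rhythm; β₁ is in **minutes per Likert unit**.  Four preset
regressions cover both variables and both lags; the two stress models share
units (the lag-0 stress model *back-predicts* last night's sleep from
today's report), so a person's two cross-lagged slopes are directly
comparable and define their lead–lag phenotype: `stress_then_sleep`,
`sleep_then_stress`, `bidirectional`, or `none`.

Estimation uses weakly informative gaussian priors (mean 0, scale 2.5,
autoscaled by the data SDs) and a Gibbs sampler over the exact conjugate
conditionals — 4 chains × 5000 iterations, the first 2500 discarded, i.e.
10,000 retained draws — validated against the closed-form
normal–inverse-gamma posterior and against OLS in the flat-prior limit.
Each fitted slope is reported as the posterior median with its 95%
equal-tailed uncertainty interval, the probability of direction
(significant when pd > 0.975), a person-specific ROPE half-width
`0.1 · sd(y)/sd(x)`, the percentage of the UI inside the ROPE, and
split-chain R-hat / ESS convergence diagnostics.  A hierarchical
(multilevel) model with correlated random intercepts and slopes provides
the contrast case: partial pooling systematically attenuates individual
slopes — and can flip their sign — for participants who deviate from the
majority pattern or contribute few days.

Because no per-day data from such studies are generally shareable, the
package includes a calibrated synthetic cohort generator (`idiolm.simulate`)
that reproduces the study structure — two 16-week semesters around a 5-week
winter break (≤223 usable days), weekend and break sleep-ins, AR(1) stress
chains, Likert discretization, person-specific cross-lagged coupling, and
survey/actigraphy missingness — together with ground-truth oracle slopes for
end-to-end validation.

## Worked example

```python
from idiolm import (PersonParams, default_calendar, simulate_person,
                    apply_missingness, filter_on_time_surveys, exclude_break,
                    build_model_data, PRESETS, fit_mcmc, summarize)

params = PersonParams(
    mu_sleep=420.0, sigma_sleep=80.0,
    weekday_profile=(45, 35, -16, -16, -16, -16, -16),   # Saturday-first
    mu_stress=2.9, phi_stress=0.4, sigma_stress=0.9,
    gamma_pre=-30.0,          # stress -> next-night sleep, min per latent unit
    p_miss_survey=0.10, p_miss_actigraphy=0.07, p_late_survey=0.02,
    seed=42,
)
cal = default_calendar()
series = apply_missingness(simulate_person(params, cal, "demo"), params)
prepped = exclude_break(filter_on_time_surveys(series), cal)
md = build_model_data(prepped, PRESETS["stress_day_before"])
s = summarize(fit_mcmc(md, seed=1), md)
```

which prints, via the fields of the returned `SlopeSummary`:

```
n = 165 usable day pairs
slope  = -20.59 min per stress unit
95% UI = [-33.96, -7.59]
pd     = 0.999   significant: True
ROPE   = +/-9.28   % UI in ROPE = 2.11
R-hat  = 1.000   ESS = 10000
```

A one-point higher evening stress rating predicts about 21 minutes less
sleep that night for this (synthetic) person; the interval excludes zero
(pd > 0.975) and sits almost entirely outside the ±9.3-minute region of
practically negligible effects.  The injected coupling was −30 min per
*latent* stress unit; Likert rounding attenuates the observable slope, and
the generator's own large-n oracle slope (−28.2 for these parameters) is
inside the interval.

The same pipeline is scriptable from the shell:

```bash
idiolm simulate --n 49 --seed 7 --out cohort.csv
idiolm validate --input cohort.csv
idiolm fit --input cohort.csv --preset stress_day_before
idiolm report --n 49 --seed 7 --outdir run/
```

`report` writes one summary CSV per preset (the decision-rule table above,
one row per participant), a phenotype table with prevalence counts, residual
diagnostics, the multilevel shrinkage comparison, and a JSON run manifest;
everything is byte-reproducible from the seed.

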