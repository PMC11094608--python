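# Methods

This note documents the statistical machinery in `idiolm`: the person-level
model and its priors, the sampler and its analytic oracles, the decision
rules, the diagnostics, the multilevel comparison model, and — because the
package validates itself on simulated cohorts — exactly what the synthetic
data generator does and does not emulate.

## The person-level model

Each participant's daily series is modeled as a gaussian linear regression

y_t = β₀ + β₁ x_{t or t−1} + β₂′ DayOfWeek_t + ε_t,  ε_t ~ N(0, σ²),

with y_t the actigraphy-derived duration (minutes) of the sleep episode
ending the morning of day *t*, x the 1–5 Likert predictor, and DayOfWeek a
7-level categorical ordered Saturday→Friday (Saturday is the reference
level; the slope β₁ is invariant to that choice, which is tested).  A daily
observation runs from the nighttime sleep episode to the evening survey, so
lag conventions are causal: the day-*t−1* stress report precedes the night
ending on day *t*, and that night precedes the day-*t* report.  Four presets
instantiate the model: sleep quality concurrent / lagged one day
(proof-of-concept and rebound probes), stress the day before (stress
leading sleep), and stress the same day (sleep leading stress, fitted as
back-prediction so both stress slopes are in minutes per Likert unit).

Data preparation applies three filters before any fit: surveys are kept
only if submitted between 17:00 on the survey day and 06:00 the next
morning (both boundaries inclusive — the boundary rule is a documented
choice, the source convention being ambiguous at exactly 06:00);
participants qualify with at least 100 on-time surveys; and winter-break
days are excluded, inclusively on both boundary days.  Lag-1 pairs require
strict calendar adjacency — a gap or the winter break is never bridged,
since a bridged pair would mix multi-day lags into a 1-day-lag estimate.
A preset needs at least 10 complete observations to fit.

## Priors, sampler, and oracles

Coefficients get weakly informative gaussian priors (location 0, scale 2.5)
autoscaled by the data, as in mainstream applied-Bayes regression defaults:
working prior SD 2.5·sd(y) for the intercept and 2.5·sd(y)/sd(x_j) for
slope j.  Two implementation details matter:

* **Centering.**  Predictors are centered internally and the intercept
  prior applies to the centered intercept (the expected outcome at average
  predictor values); the fitted intercept is translated back.  Without
  this, a mean-zero prior on an intercept of ~400 minutes leaks shrinkage
  into the slope through the intercept–predictor correlation.
* **Normal–inverse-gamma form.**  The coefficient prior is carried as
  β | σ² ~ N(0, σ²V₀) with V₀ = diag(working_sd²)/sd(y)², and σ² gets a
  vague inverse-gamma IG(2, sd(y)²) (prior mean sd(y)², infinite
  variance).  At the prior-mean residual variance the implied coefficient
  prior SD equals the working SD, and the joint posterior is available in
  closed form.  An exponential prior on σ (another common default) was
  considered and set aside: it destroys conjugacy, and with ~100–220
  observations per fit the residual-scale prior is immaterial — both
  choices are overwhelmed by the likelihood.

The sampler (`BayesianILM`) is Gibbs over the exact conditionals —
coefficients | σ² multivariate normal, σ² | coefficients inverse gamma — so
its stationary distribution is *identical* to the closed-form posterior
(`ConjugateILM`), not merely asymptotically similar.  This buys an unusual
level of checkability: the test suite asserts that posterior medians from
10,000 retained draws (4 chains × 5000 iterations, 2500 warmup each,
overdispersed σ² starts from the prior) sit within 3 Monte-Carlo standard
errors of the analytic means, and that the flat-prior closed form equals
OLS to 3 decimals.  Because the conditionals reduce to 8-dimensional
quadratic forms after precomputation, a full default fit takes a fraction
of a second.  Runs are deterministic given the seed (chains use spawned
child streams).

Convergence is monitored with the split-chain potential scale reduction
factor (adequacy R-hat < 1.1; rank-normalization available but off by
default) and an effective sample size that combines within-chain
autocorrelations with the between-chain variance, truncated by Geyer's
initial monotone positive sequence, capped at the total draw count, with
zero-variance draws defined as R-hat 1 and ESS = total.  Both are
cross-checked against an independent reference implementation in the test
suite.

## Decision rules

For the slope: posterior median; 95% equal-tailed uncertainty interval
(2.5% and 97.5% quantiles, linear-interpolation); probability of direction
pd = posterior mass on the sign of the point estimate (draws at exactly
zero split evenly; pd ∈ [0.5, 1]); significance iff pd > 0.975, which for
unimodal posteriors coincides with the 95% UI excluding zero (agreement is
asserted at ≥99% over simulated fits).  The region of practical
equivalence is person-specific: a standardized effect of 0.1 (half a
conventional "small" effect) converted to raw units as
0.1·sd(y)/sd(x), computed from the exact observation set entering the fit
— not the person's full series — which is why table values can deviate by
a percent or so from arithmetic on full-series SDs.  The %UI-in-ROPE is
the share of draws inside the equal-tailed UI that also fall in
[−rope, +rope] (an HDI variant is available but ETI is the default, for
internal consistency with the UI itself).  A participant's pair of
cross-lagged stress models maps to a lead–lag phenotype: only the
stress-day-before model significant → `stress_then_sleep`; only the
stress-day-after model → `sleep_then_stress`; both → `bidirectional`;
neither → `none`.  No multiplicity correction is applied across
participants — each person-level model is its own independent test.

## Diagnostics

* **Posterior predictive checks**: 100 replicate outcome vectors (default),
  each simulated from one randomly selected posterior draw of
  (coefficients, σ) over the observed design; the observed mean should sit
  inside the central 95% envelope of replicate means, and the pooled
  replicate distribution should be closer (in KS distance) to the data
  than that of a deliberately misspecified fit.
* **Residuals** are taken at the posterior-median coefficients and paired
  with fitted values for homoscedasticity inspection.
* **Autocorrelation** is date-aware: lag-k pairs are observations exactly
  k calendar days apart, so missing days and the winter break never
  corrupt lag semantics.  Two estimators are provided.  The *pairwise*
  estimator (default for descriptive profiles) is the Pearson correlation
  of the k-day-apart pairs and is verified against a brute-force double
  loop.  The *sample* estimator is the standard Box–Jenkins ACF with
  missing data — products of deviations from the single series mean,
  normalized by the total count times the series variance — and matches
  the mainstream time-series implementation exactly.  The residual
  adequacy flag (all lags 1–14 with |r| < 0.2) uses the sample estimator:
  it is what an autocorrelation plot of residuals displays, and at
  ~100–200 pairs per lag the pairwise estimator's per-lag noise (SE ≈
  0.07–0.09) would flag roughly a quarter of perfectly well-specified fits
  across a 14-lag window, turning the check into a coin flip about noise
  rather than structure.
* **Descriptive aggregates**: between-person means of within-person means
  (with between-person SEs) by academic period (fall / winter break /
  spring) and by Saturday-first weekday.

## The multilevel comparison

The contrast model pools all participants: fixed effects for intercept,
predictor slope and weekday contrasts, plus correlated per-person random
intercepts and random slopes on the main predictor (weekday effects stay
fixed).  Priors: autoscaled gaussians on fixed effects (centered as
above), inverse-Wishart(ν₀ = 3, identity scale) on the 2×2 random-effect
covariance — the minimal-df conditionally conjugate choice; with ≥ 10
participants the posterior for the covariance is data-dominated, and
doubling ν₀ moves the estimated slope SD by far less than its posterior
spread — and IG(2, sd(y)²) on σ².  Estimation is Gibbs over the four
conditionally conjugate blocks; defaults 4 chains × 2000 iterations
(warmup 1000), which suffices because the blocks are nearly independent;
an R-hat ≥ 1.1 on the fixed slope flags (but does not discard) the fit.

The shrinkage report compares each person's independently fitted slope
with their multilevel counterpart (fixed slope + random deviation):
attenuation ratio (mlm − pooled)/(ilm − pooled), reported as 1 when the
person-level slope coincides with the pool, and a sign-reversal flag.  The
partial-pooling contract — every estimate at least as close to the pool as
its person-level counterpart, more strongly for fewer days, with sign
reversal possible for a low-n minority-phenotype participant — is asserted
in the tests.

## The synthetic cohort generator

One synthetic participant is a mutually recursive pair of daily processes
over an academic calendar (16-week fall and spring semesters around a
5-week winter break; 223 in-semester days by default, starting Monday
2017-09-04):

* sleep: y_t = μ_sleep + weekday_profile[dow_t] + bonus·1[break] +
  γ_pre·(s*_{t−1} − μ_s) + e_t, truncated to [0, 1440) minutes, with an
  optional "no detected sleep episode" probability recording 0 minutes
  (default off; the value such days carry in real pipelines is a
  convention, so it is exposed as configuration);
* latent stress: s*_t = μ_s − drop·1[break] + φ(s*_{t−1} − μ_s) +
  γ_post·z_t + u_t, where z_t is the standardized deficit of the night
  ending on day t — the same-night sleep feeds the same-evening report;
* observations: stress is round(s*) clamped to 1–5; quality is a noisy
  monotone function of the night's standardized sleep deviation, also
  clamped; surveys and actigraphy drop out MCAR at person-specific rates
  (an MNAR stress-dependent switch exists, default off), retained surveys
  get uniform on-time timestamps with a small late fraction.

Because the analysis regresses on the *rounded* stress value,
discretization and clamping attenuate the injected coupling; the recovery
target is therefore the generator's own **oracle slope**: each participant
is regenerated over 200,000 break-free days without missingness and the
observed-scale OLS slope (with weekday dummies) is recorded per preset.
Break-free, because fitted models exclude the break and its mean shifts
would otherwise bias the large-n slope.

Default cohort calibration (uniform ranges per person) targets the
population the generator emulates: person mean sleep 370–480 min, residual
sleep SD 55–115 min, weekend sleep-in 25–55 min, break bonus 20–60 min,
latent stress mean 1.9–3.5 with AR(1) φ 0.25–0.55 and innovation SD
0.65–1.15 (yielding observed stress SDs ≈ 0.7–1.15, matching the published
per-participant range), break stress drop 0.2–0.7, and missingness leaving
a median of ≈ 175 usable days out of 223.  Couplings are heterogeneous:
85% of participants get a negative stress→sleep coupling (latent −45 to
−5 min/unit, observable span ≈ −40 to −5 after attenuation) and 15% a
positive one (5–20); the sleep→stress direction is present in 25% of
participants (0.1–0.3 latent units per deficit SD) and absent otherwise,
matching its reported minority prevalence — giving every participant strong
feedback would both create a lag-1 sleep autocorrelation that contradicts
the weekly-dominant pattern the generator is supposed to emulate and
induce predictor endogeneity in the lag-0 model.

What the generator does **not** emulate: raw accelerometry and
sleep-episode detection, circadian phase, daylight-saving and timezone
arithmetic beyond dates, exam-period stress spikes, non-gaussian sleep
(naps, split nights), floor/ceiling response styles beyond symmetric
rounding, and systematic (non-MCAR) missingness unless switched on.
Passing recovery tests therefore demonstrates that the estimator and
decision rules behave correctly when the model family matches the
generating process up to Likert discretization — not that real cohorts
satisfy those assumptions; the residual and posterior-predictive
diagnostics are the tools for interrogating that on real data.

## Numerical choices and problem sizes

Quantiles are linear-interpolation sample quantiles; sample SDs use ddof 1.
Degenerate designs: a constant predictor raises a rank-deficiency error
(OLS) while the proper prior keeps Bayesian fits defined; never-observed
weekday contrasts are dropped with a warning in OLS.  The test suite runs
everything at the scale it asserts about: 10,000-day single-person series
for structure checks, 20 participants × n = 178 at full default MCMC for
oracle-equivalence and convergence rates, four 49-person cohorts (196
fits, oracle at 200,000 days each) for recovery and coverage — pooling
cohorts keeps the binomial noise of a ≥90% coverage assertion well below
its margin — 200 null replicates at reduced MCMC (2 × 1000) for
type-I-error calibration, and a 12-person constructed cohort for shrinkage
and sign reversal.  End-to-end pipeline runs are byte-reproducible given
the seed: every fit seed derives from the run seed, participant index and
preset index.

## Known limitations

The Gibbs sampler covers the linear-gaussian family only — there is no
HMC, so extending to non-gaussian likelihoods means new conditionals, not
a config change.  The ESS estimator is near-unbiased for these nearly
independent draws but, like all initial-sequence estimators, can exceed
the true value on short, strongly anticorrelated chains (hence the cap).
The multilevel model fixes weekday effects and random effects at
intercept + main slope; crossed or deeper groupings are out of scope.
ROPE half-widths depend on the realized observation set, so re-filtering
data changes them slightly.  The attenuation ratio is undefined when a
person-level slope equals the pooled slope and is reported as 1 by
convention; with MCMC noise, ratios for participants very close to the
pool are unstable even though the underlying shrinkage contract holds.
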