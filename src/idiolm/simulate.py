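"""Synthetic academic-year cohorts of daily stress and sleep records.

Generates person-level daily time series with the structure an idiographic
stress/sleep analysis assumes: nightly sleep duration in minutes with a
weekly (lag-7) rhythm and longer sleep during the winter break and weekends,
a latent AR(1) stress process reported each evening on a 1-5 Likert scale,
and person-specific cross-lagged coupling in both directions:

* ``gamma_pre``  — yesterday-evening stress shifts tonight's sleep duration
  (minutes per latent stress unit);
* ``gamma_post`` — last night's standardized sleep deficit shifts today's
  evening stress report (latent stress units per deficit SD).

The causal ordering is explicit: the sleep episode recorded on day *t* ends
the morning of day *t* and therefore precedes that evening's stress report,
while the stress report of day *t-1* precedes the night ending on day *t*.

Because the analysis regresses observed sleep on the *rounded* 1-5 stress
report, Likert discretization attenuates the injected coupling.  The
recovery target for every participant is therefore the generator's own
large-n least-squares slope on the observed (rounded) scale — the "oracle
slope" stored in :class:`CohortTruth` — not ``gamma_pre`` verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from datetime import date, timedelta
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .calendars import StudyCalendar, make_calendar, weekday_index

__all__ = [
    "PersonParams",
    "CohortSampler",
    "CohortTruth",
    "simulate_person",
    "apply_missingness",
    "simulate_cohort",
    "default_sampler",
    "write_cohort_csv",
    "write_truth_csv",
]

#: upper bound (exclusive) for a nightly sleep duration, minutes
MAX_SLEEP_MIN = 1440.0

#: columns of the long-format daily-record table
RECORD_COLUMNS = [
    "participant_id",
    "date",
    "sleep_duration_min",
    "sleep_quality",
    "stress",
    "survey_submit_time",
    "actigraphy_usable",
]


@dataclass(frozen=True)
class PersonParams:
    """Generative parameters for one synthetic participant.

    ``mu_sleep``/``weekday_profile``/``sigma_sleep`` are the generative
    counterparts of the fitted model's intercept, weekday contrasts and
    residual SD; ``gamma_pre``/``gamma_post`` of the cross-lagged slopes.
    """

    mu_sleep: float = 430.0  # minutes
    sigma_sleep: float = 90.0  # minutes
    weekday_profile: tuple[float, ...] = (0.0,) * 7  # minutes, Saturday-first
    break_sleep_bonus: float = 40.0  # minutes
    mu_stress: float = 2.8  # latent Likert units
    phi_stress: float = 0.4  # AR(1) coefficient
    sigma_stress: float = 0.8  # latent innovation SD
    break_stress_drop: float = 0.5  # latent units
    gamma_pre: float = 0.0  # min per latent stress unit (stress -> sleep)
    gamma_post: float = 0.0  # latent units per deficit SD (sleep -> stress)
    quality_gain: float = 1.2  # quality units per sleep-deviation SD
    p_miss_survey: float = 0.0
    p_miss_actigraphy: float = 0.0
    p_late_survey: float = 0.0  # fraction of retained surveys submitted late
    p_no_sleep: float = 0.0  # "no detected sleep episode" day, recorded as 0
    mnar_survey_coef: float = 0.0  # stress-dependent missingness (off: MCAR)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_sleep <= 0 or self.sigma_stress <= 0:
            raise ValueError("sigma_sleep and sigma_stress must be > 0")
        if not abs(self.phi_stress) < 1:
            raise ValueError("phi_stress must lie in (-1, 1)")
        if len(self.weekday_profile) != 7:
            raise ValueError("weekday_profile must have 7 entries (Saturday-first)")
        for name in ("p_miss_survey", "p_miss_actigraphy", "p_late_survey", "p_no_sleep"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")


def simulate_person(
    params: PersonParams,
    calendar: StudyCalendar,
    participant_id: str = "P1",
) -> pd.DataFrame:
    """Simulate one participant's complete daily record over the calendar.

    Returns one row per calendar day (semesters *and* break; missingness is
    applied separately).  The generative recursion, per day ``t``:

    1. sleep  ``y_t = mu + profile[dow_t] + bonus*1[break] +
       gamma_pre*(s*_{t-1} - mu_s) + e_t``, truncated to ``[0, 1440)``;
    2. deficit ``z_t = -(y_t - E[y_t | dow, break]) / sigma_sleep``;
    3. latent stress ``s*_t = mu_s - drop*1[break] +
       phi*(s*_{t-1} - mu_s) + gamma_post*z_t + u_t``;
    4. observed ``stress_t = clamp(round(s*_t), 1, 5)`` and
       ``quality_t = clamp(round(3 + quality_gain*(y_t - E[y_t])/sigma_sleep
       + q_t), 1, 5)``.

    Output is fully determined by ``params.seed``.
    """
    days = calendar.all_days()
    n = len(days)
    dow = np.fromiter((weekday_index(d) for d in days), dtype=np.intp, count=n)
    is_break = np.fromiter((calendar.in_break(d) for d in days), dtype=bool, count=n)

    profile = np.asarray(params.weekday_profile, dtype=float)
    base_mean = params.mu_sleep + profile[dow] + params.break_sleep_bonus * is_break

    rng = np.random.default_rng(params.seed)
    # fixed draw order: stationary init, stress innovations, sleep noise,
    # quality noise, no-sleep indicators
    s_init = rng.normal(
        0.0, params.sigma_stress / math.sqrt(1.0 - params.phi_stress**2)
    )
    u = rng.normal(0.0, params.sigma_stress, size=n)
    e = rng.normal(0.0, params.sigma_sleep, size=n)
    q = rng.normal(0.0, 0.5, size=n)
    no_sleep = (
        rng.random(n) < params.p_no_sleep if params.p_no_sleep > 0 else np.zeros(n, bool)
    )

    y = np.empty(n)
    s_latent = np.empty(n)
    # tight scalar loop: the two series are mutually recursive
    mu_s = params.mu_stress
    phi = params.phi_stress
    g_pre = params.gamma_pre
    g_post = params.gamma_post
    drop = params.break_stress_drop
    sig_y = params.sigma_sleep
    y_hi = math.nextafter(MAX_SLEEP_MIN, 0.0)
    s_prev = s_init  # deviation of s*_{t-1} from mu_stress
    bm = base_mean
    for t in range(n):
        m = bm[t]
        yt = m + g_pre * s_prev + e[t]
        if no_sleep[t]:
            yt = 0.0
        elif yt < 0.0:
            yt = 0.0
        elif yt > y_hi:
            yt = y_hi
        z = -(yt - m) / sig_y
        s_dev = phi * s_prev + g_post * z + u[t]
        if is_break[t]:
            s_dev -= drop
        y[t] = yt
        s_latent[t] = mu_s + s_dev
        s_prev = s_dev

    stress = np.clip(np.rint(s_latent), 1, 5)
    quality = np.clip(
        np.rint(3.0 + params.quality_gain * (y - base_mean) / sig_y + q), 1, 5
    )

    # second resolution: day counts beyond the nanosecond datetime range are
    # legitimate for large-n oracle regeneration
    dates64 = np.array(days, dtype="datetime64[D]").astype("datetime64[s]")
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "date": pd.Series(dates64),
            "sleep_duration_min": y,
            "sleep_quality": quality,
            "stress": stress,
            "survey_submit_time": pd.NaT,
            "actigraphy_usable": np.ones(n, dtype=int),
        }
    )


def apply_missingness(
    series: pd.DataFrame,
    params: PersonParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Drop survey/actigraphy fields at the person's missingness rates.

    Each day independently loses its survey fields with ``p_miss_survey``
    (optionally shifted by the day's stress level when the MNAR coefficient
    is nonzero) and its sleep fields with ``p_miss_actigraphy``.  Retained
    surveys get a submission timestamp drawn uniformly in the on-time window
    (17:00 to 06:00 the next day); a ``p_late_survey`` fraction instead get
    a late timestamp (next day, after 06:00).
    """
    if rng is None:
        rng = np.random.default_rng([params.seed, 104729])
    out = series.copy()
    n = len(out)

    p_survey = np.full(n, params.p_miss_survey)
    if params.mnar_survey_coef != 0.0:
        p_survey = np.clip(
            p_survey + params.mnar_survey_coef * (out["stress"].to_numpy() - 3.0),
            0.0,
            1.0,
        )
    miss_survey = rng.random(n) < p_survey
    miss_act = rng.random(n) < params.p_miss_actigraphy
    late = rng.random(n) < params.p_late_survey
    frac = rng.random(n)

    dates = out["date"]
    keep_survey = ~miss_survey
    # on-time window spans 13 h (17:00 -> 30:00); late spans 06:00 -> 12:00 next day
    on_time = dates + pd.to_timedelta(17.0 * 60 + frac * 13.0 * 60, unit="m")
    late_time = dates + pd.to_timedelta(30.0 * 60 + frac * 6.0 * 60, unit="m")
    submit = on_time.where(~late, late_time)
    out["survey_submit_time"] = submit.where(keep_survey, pd.NaT)
    out.loc[miss_survey, ["sleep_quality", "stress"]] = np.nan
    out.loc[miss_act, "sleep_duration_min"] = np.nan
    out.loc[miss_act, "actigraphy_usable"] = 0
    return out


# ---------------------------------------------------------------------------
# cohort-level sampling


@dataclass(frozen=True)
class CohortSampler:
    """Uniform-range sampler over :class:`PersonParams` for a cohort.

    Defaults are calibrated to the study population the generator emulates:
    undergraduate participants with person-mean sleep of roughly 350-500 min,
    person sleep SDs of roughly 55-130 min, stress reported on a 1-5 Likert
    scale with 1-2-day autocorrelation chains, a weekend sleep-in, longer
    sleep and lower stress over the winter break, and survey/actigraphy
    missingness leaving a median of about 175 usable days out of 223.
    ``p_negative_coupling`` controls the share of participants whose
    stress->sleep coupling is negative (higher stress, shorter sleep),
    mirroring the predominance of negative associations in this population.
    """

    mu_sleep: tuple[float, float] = (370.0, 480.0)
    sigma_sleep: tuple[float, float] = (55.0, 115.0)
    weekend_boost: tuple[float, float] = (25.0, 55.0)  # Sat morning sleep-in, min
    break_sleep_bonus: tuple[float, float] = (20.0, 60.0)
    mu_stress: tuple[float, float] = (1.9, 3.5)
    phi_stress: tuple[float, float] = (0.25, 0.55)
    sigma_stress: tuple[float, float] = (0.65, 1.15)
    break_stress_drop: tuple[float, float] = (0.2, 0.7)
    gamma_pre_negative: tuple[float, float] = (-45.0, -5.0)
    gamma_pre_positive: tuple[float, float] = (5.0, 20.0)
    p_negative_coupling: float = 0.85
    # sleep -> next-day stress: the rarer direction, present in roughly a
    # quarter of the population and absent otherwise
    p_post_coupling: float = 0.25
    gamma_post: tuple[float, float] = (0.1, 0.3)
    quality_gain: tuple[float, float] = (0.8, 1.6)
    p_miss_survey: tuple[float, float] = (0.06, 0.18)
    p_miss_actigraphy: tuple[float, float] = (0.04, 0.14)
    p_late_survey: tuple[float, float] = (0.0, 0.04)

    def sample(self, rng: np.random.Generator, seed: int) -> PersonParams:
        def u(lohi: tuple[float, float]) -> float:
            return float(rng.uniform(*lohi))

        boost = u(self.weekend_boost)
        # Sat/Sun mornings long, school-day mornings short; profile sums to ~0
        profile = (
            boost,
            0.8 * boost,
            *(-(1.8 * boost) / 5.0 for _ in range(5)),
        )
        negative = rng.random() < self.p_negative_coupling
        gamma_pre = u(self.gamma_pre_negative if negative else self.gamma_pre_positive)
        gamma_post = u(self.gamma_post) if rng.random() < self.p_post_coupling else 0.0
        return PersonParams(
            mu_sleep=u(self.mu_sleep),
            sigma_sleep=u(self.sigma_sleep),
            weekday_profile=profile,
            break_sleep_bonus=u(self.break_sleep_bonus),
            mu_stress=u(self.mu_stress),
            phi_stress=u(self.phi_stress),
            sigma_stress=u(self.sigma_stress),
            break_stress_drop=u(self.break_stress_drop),
            gamma_pre=gamma_pre,
            gamma_post=gamma_post,
            quality_gain=u(self.quality_gain),
            p_miss_survey=u(self.p_miss_survey),
            p_miss_actigraphy=u(self.p_miss_actigraphy),
            p_late_survey=u(self.p_late_survey),
            seed=seed,
        )


def default_sampler() -> CohortSampler:
    return CohortSampler()


@dataclass
class CohortTruth:
    """Generator ground truth for a synthetic cohort.

    ``oracle_slopes`` holds, for every (participant, preset), the large-n
    ordinary-least-squares slope of observed sleep duration on the observed
    (rounded) predictor plus weekday indicators — the quantity a
    correctly-specified individual model should recover on the observed
    Likert scale.
    """

    params: dict[str, PersonParams]
    oracle_slopes: pd.DataFrame  # columns: participant_id, preset, slope

    def oracle_slope(self, participant_id: str, preset: str) -> float:
        df = self.oracle_slopes
        row = df[(df.participant_id == participant_id) & (df.preset == preset)]
        if len(row) != 1:
            raise KeyError(f"no oracle slope for ({participant_id}, {preset})")
        return float(row.slope.iloc[0])


def _oracle_series(params: PersonParams, n_days: int, seed: int) -> pd.DataFrame:
    """Regenerate a participant on a long break-free calendar, no missingness."""
    weeks = max(2, math.ceil(n_days / 14))
    cal = make_calendar(date(2000, 1, 1), semester_weeks=weeks, break_weeks=0)
    clean = replace(
        params,
        p_miss_survey=0.0,
        p_miss_actigraphy=0.0,
        p_late_survey=0.0,
        break_sleep_bonus=0.0,
        break_stress_drop=0.0,
        seed=seed,
    )
    return simulate_person(clean, cal).iloc[:n_days]


def _oracle_slopes_for(
    params: PersonParams, participant_id: str, n_days: int, seed: int
) -> list[dict]:
    from .prep import PRESETS, build_model_data  # deferred: avoid import cycle

    series = _oracle_series(params, n_days, seed)
    rows = []
    for name, spec in PRESETS.items():
        md = build_model_data(series, spec)
        X = md.design_matrix()
        beta, *_ = np.linalg.lstsq(X, md.y, rcond=None)
        rows.append(
            {"participant_id": participant_id, "preset": name, "slope": float(beta[1])}
        )
    return rows


def simulate_cohort(
    n_participants: int,
    param_sampler: CohortSampler | Sequence[PersonParams] | Callable | None = None,
    calendar: StudyCalendar | None = None,
    seed: int = 0,
    oracle_n: int = 200_000,
    compute_oracle: bool = True,
) -> tuple[list[pd.DataFrame], CohortTruth]:
    """Simulate a cohort of daily records plus its ground truth.

    Deterministic given ``seed``.  ``param_sampler`` may be a
    :class:`CohortSampler`, an explicit sequence of :class:`PersonParams`
    (seeds are overridden for determinism), or a callable
    ``(rng, seed) -> PersonParams``.  Oracle slopes are computed by
    regenerating each participant over ``oracle_n`` break-free days with no
    missingness and running OLS per model preset.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    from .calendars import default_calendar

    if calendar is None:
        calendar = default_calendar()
    if param_sampler is None:
        param_sampler = default_sampler()

    rng = np.random.default_rng(seed)
    person_seeds = rng.integers(0, 2**31 - 1, size=n_participants)
    oracle_seeds = rng.integers(0, 2**31 - 1, size=n_participants)

    params_list: list[PersonParams] = []
    for i in range(n_participants):
        s = int(person_seeds[i])
        if isinstance(param_sampler, CohortSampler):
            p = param_sampler.sample(rng, s)
        elif callable(param_sampler):
            p = param_sampler(rng, s)
        else:
            p = replace(param_sampler[i], seed=s)
        params_list.append(p)

    series_list = []
    truth_rows: list[dict] = []
    params_by_id: dict[str, PersonParams] = {}
    for i, p in enumerate(params_list):
        pid = f"S{i + 1:02d}"
        params_by_id[pid] = p
        s = apply_missingness(simulate_person(p, calendar, pid), p)
        series_list.append(s)
        if compute_oracle:
            truth_rows.extend(_oracle_slopes_for(p, pid, oracle_n, int(oracle_seeds[i])))

    oracle = pd.DataFrame(
        truth_rows, columns=["participant_id", "preset", "slope"]
    )
    return series_list, CohortTruth(params=params_by_id, oracle_slopes=oracle)


# ---------------------------------------------------------------------------
# CSV export


def write_cohort_csv(series_list: Sequence[pd.DataFrame], path) -> None:
    """Write a cohort to long-format CSV, one row per participant-day."""
    df = pd.concat(series_list, ignore_index=True)[RECORD_COLUMNS].copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df["survey_submit_time"] = df["survey_submit_time"].dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    df.to_csv(path, index=False)


def write_truth_csv(truth: CohortTruth, path) -> None:
    """Write ground-truth parameters and oracle slopes to a sidecar CSV."""
    rows = []
    wide = truth.oracle_slopes.pivot(
        index="participant_id", columns="preset", values="slope"
    )
    for pid, p in truth.params.items():
        row: dict = {"participant_id": pid}
        for f in fields(p):
            v = getattr(p, f.name)
            if f.name == "weekday_profile":
                for j, off in enumerate(v):
                    row[f"weekday_profile_{j}"] = off
            else:
                row[f.name] = v
        if pid in wide.index:
            for preset in wide.columns:
                row[f"oracle_slope_{preset}"] = wide.loc[pid, preset]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
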