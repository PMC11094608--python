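from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from idiolm import (
    PRESETS,
    ModelData,
    PersonParams,
    build_model_data,
    default_calendar,
    make_calendar,
    simulate_person,
)

WEEKEND_PROFILE = (40.0, 32.0, -14.4, -14.4, -14.4, -14.4, -14.4)


def make_params(**kw) -> PersonParams:
    """A realistic participant; overrides via keyword arguments."""
    base = dict(
        mu_sleep=430.0,
        sigma_sleep=90.0,
        weekday_profile=WEEKEND_PROFILE,
        break_sleep_bonus=40.0,
        mu_stress=2.8,
        phi_stress=0.4,
        sigma_stress=0.8,
        break_stress_drop=0.5,
        seed=0,
    )
    base.update(kw)
    return PersonParams(**base)


def long_calendar(n_days: int) -> "StudyCalendar":
    """A break-free calendar with at least n_days days."""
    weeks = max(2, -(-n_days // 14))
    return make_calendar(date(2015, 1, 3), semester_weeks=weeks, break_weeks=0)


def trim(md: ModelData, n: int) -> ModelData:
    return ModelData(
        participant_id=md.participant_id,
        spec=md.spec,
        y=md.y[:n],
        x=md.x[:n],
        weekday=md.weekday[:n],
        dates=md.dates[:n],
    )


def person_model_data(
    params: PersonParams, preset: str = "stress_day_before", n: int | None = 178
) -> ModelData:
    """Complete (no missingness) semester data for one simulated person."""
    cal = default_calendar()
    series = simulate_person(params, cal)
    from idiolm import exclude_break

    md = build_model_data(exclude_break(series, cal), PRESETS[preset])
    return trim(md, n) if n is not None else md


@pytest.fixture(scope="session")
def calendar():
    return default_calendar()


@pytest.fixture(scope="session")
def coupled_person_md():
    """ModelData for a person with stress->sleep coupling of -25 min/unit."""
    return person_model_data(make_params(gamma_pre=-25.0, seed=11))
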