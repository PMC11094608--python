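from datetime import date
from io import StringIO

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idiolm import (
    PRESETS,
    InsufficientDataError,
    ValidationError,
    apply_inclusion,
    build_model_data,
    default_calendar,
    exclude_break,
    filter_on_time_surveys,
    read_daily_csv,
    simulate_person,
)

from conftest import make_params

HEADER = (
    "participant_id,date,sleep_duration_min,sleep_quality,stress,"
    "survey_submit_time,actigraphy_usable"
)


def _csv(rows: list[str]) -> StringIO:
    return StringIO("\n".join([HEADER, *rows]) + "\n")


def _series(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(df["date"])
    df["survey_submit_time"] = pd.to_datetime(df.get("survey_submit_time"))
    for c in ("sleep_duration_min", "sleep_quality", "stress"):
        df[c] = pd.to_numeric(df.get(c), errors="coerce")
    if "participant_id" not in df:
        df["participant_id"] = "P1"
    if "actigraphy_usable" not in df:
        df["actigraphy_usable"] = 1
    return df


def _day(i: int, **kw) -> dict:
    base = dict(
        participant_id="P1",
        date=f"2017-09-{i:02d}",
        sleep_duration_min=420.0,
        sleep_quality=3,
        stress=2,
        survey_submit_time=f"2017-09-{i:02d}T21:00:00",
        actigraphy_usable=1,
    )
    base.update(kw)
    return base


class TestReadDailyCsv:
    def test_two_participants_three_days(self):
        rows = [
            "A,2017-09-05,400,3,2,2017-09-05T21:00:00,1",
            "A,2017-09-06,410,3,2,2017-09-06T21:00:00,1",
            "A,2017-09-07,390,2,3,2017-09-07T21:00:00,1",
            "B,2017-09-05,500,4,1,2017-09-05T20:00:00,1",
            "B,2017-09-06,505,4,1,2017-09-06T20:00:00,1",
            "B,2017-09-07,490,5,1,2017-09-07T20:00:00,1",
        ]
        series = read_daily_csv(_csv(rows))
        assert [len(s) for s in series] == [3, 3]
        assert series[0]["participant_id"].iloc[0] == "A"

    def test_out_of_range_stress_rejected_with_line(self):
        rows = ["A,2017-09-05,400,3,7,2017-09-05T21:00:00,1"]
        with pytest.raises(ValidationError, match="line 2"):
            read_daily_csv(_csv(rows))

    def test_duplicate_participant_day_rejected(self):
        rows = [
            "A,2017-09-05,400,3,2,2017-09-05T21:00:00,1",
            "A,2017-09-05,410,3,2,2017-09-05T22:00:00,1",
        ]
        with pytest.raises(ValidationError, match="duplicate"):
            read_daily_csv(_csv(rows))

    def test_unsorted_dates_sorted_on_read(self):
        rows = [
            "A,2017-09-07,390,2,3,2017-09-07T21:00:00,1",
            "A,2017-09-05,400,3,2,2017-09-05T21:00:00,1",
        ]
        (s,) = read_daily_csv(_csv(rows))
        assert s["date"].is_monotonic_increasing


class TestOnTimeWindow:
    @pytest.mark.parametrize(
        "submit, kept",
        [
            ("2017-09-05T21:30:00", True),  # evening, inside window
            ("2017-09-06T06:00:00", True),  # boundary closed at 06:00
            ("2017-09-06T06:01:00", False),  # one minute late
            ("2017-09-05T16:59:00", False),  # before the window opens
            (None, False),  # untimestamped survey
        ],
    )
    def test_window_boundaries(self, submit, kept):
        s = _series([_day(5, survey_submit_time=submit)])
        out = filter_on_time_surveys(s)
        assert out["stress"].notna().iloc[0] == kept
        # sleep fields never touched
        assert out["sleep_duration_min"].iloc[0] == 420.0

    def test_idempotent(self):
        s = _series([_day(5), _day(6, survey_submit_time="2017-09-07T08:00:00")])
        once = filter_on_time_surveys(s)
        twice = filter_on_time_surveys(once)
        pd.testing.assert_frame_equal(once, twice)


class TestInclusion:
    @pytest.mark.parametrize("n, included", [(99, False), (100, True), (214, True)])
    def test_threshold_is_at_least_100(self, n, included):
        s = _series([_day(1)] * 1)
        s = pd.concat([s] * n, ignore_index=True)  # n on-time surveys
        assert apply_inclusion(s) == included


class TestExcludeBreak:
    def test_semester_days_survive(self, calendar):
        p = make_params(seed=0)
        s = simulate_person(p, calendar)
        out = exclude_break(s, calendar)
        assert len(s) == 223 + 35
        assert len(out) == 223

    def test_boundary_days_removed(self, calendar):
        rows = [
            dict(_day(1), date=str(calendar.break_start)),
            dict(_day(2), date=str(calendar.break_end)),
            dict(_day(3), date=str(calendar.fall_end)),
            dict(_day(4), date="2010-01-01"),  # outside the study entirely
        ]
        out = exclude_break(_series(rows), calendar)
        assert out["date"].dt.date.tolist() == [calendar.fall_end]

    def test_idempotent_and_monotone(self, calendar):
        p = make_params(p_miss_survey=0.2, seed=3)
        s = simulate_person(p, calendar)
        once = exclude_break(s, calendar)
        pd.testing.assert_frame_equal(exclude_break(once, calendar), once)
        assert len(once) <= len(s)


class TestBuildModelData:
    def test_three_consecutive_days_give_two_lag_pairs(self):
        s = _series([_day(i) for i in (5, 6, 7)])
        md = build_model_data(s, PRESETS["stress_day_before"], min_obs=1)
        assert md.n == 2

    def test_gap_breaks_lag_pairing(self):
        s = _series([_day(i) for i in (1, 2, 4, 5)])
        md = build_model_data(s, PRESETS["stress_day_before"], min_obs=1)
        assert md.n == 2  # pairs (1->2) and (4->5) only

    def test_break_severs_adjacency(self, calendar):
        rows = [
            dict(_day(1), date=str(calendar.fall_end)),
            dict(_day(2), date=str(calendar.spring_start)),
        ]
        s = exclude_break(_series(rows), calendar)
        with pytest.raises(InsufficientDataError):
            build_model_data(s, PRESETS["stress_day_before"], min_obs=1)

    def test_insufficient_data_names_participant_and_preset(self):
        s = _series([_day(i) for i in (5, 6, 7)])
        with pytest.raises(InsufficientDataError, match="P1.*stress_day_before"):
            build_model_data(s, PRESETS["stress_day_before"])

    def test_weekday_derives_from_outcome_day(self):
        s = _series([_day(i) for i in (1, 2)])  # 2017-09-01 Fri, 09-02 Sat
        md = build_model_data(s, PRESETS["stress_day_before"], min_obs=1)
        assert md.weekday.tolist() == [0]  # outcome day is the Saturday

    def test_preset_symmetry_on_complete_data(self, calendar):
        p = make_params(seed=1)
        s = exclude_break(simulate_person(p, calendar), calendar)
        n = {name: build_model_data(s, spec).n for name, spec in PRESETS.items()}
        assert n["stress_day_after"] == n["quality_concurrent"]
        assert n["stress_day_before"] == n["quality_lag1"]
        # one lag pair lost per semester start
        assert n["stress_day_before"] == n["stress_day_after"] - 2

    def test_unusable_actigraphy_excludes_outcome(self):
        rows = [_day(i) for i in range(1, 13)]
        rows[0]["actigraphy_usable"] = 0
        md = build_model_data(_series(rows), PRESETS["stress_day_after"], min_obs=1)
        assert md.n == 11


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    miss=st.lists(st.booleans(), min_size=12, max_size=40),
    late=st.lists(st.booleans(), min_size=12, max_size=40),
)
def test_filters_are_idempotent_and_never_grow_n(miss, late):
    """Property: each filter is a projection and n is monotone under it."""
    k = min(len(miss), len(late))
    rows = []
    for i in range(k):
        r = _day(1)
        r["date"] = str(date(2017, 9, 4 + i % 25))
        if miss[i]:
            r["stress"] = None
            r["sleep_quality"] = None
            r["survey_submit_time"] = None
        elif late[i]:
            r["survey_submit_time"] = r["date"] + "T10:00:00"
        rows.append(r)
    # unique dates only
    seen, uniq = set(), []
    for r in rows:
        if r["date"] not in seen:
            seen.add(r["date"])
            uniq.append(r)
    s = _series(uniq)
    cal = default_calendar()
    f1 = filter_on_time_surveys(s)
    pd.testing.assert_frame_equal(filter_on_time_surveys(f1), f1)
    assert f1["stress"].notna().sum() <= s["stress"].notna().sum()
    f2 = exclude_break(f1, cal)
    pd.testing.assert_frame_equal(exclude_break(f2, cal), f2)
    assert len(f2) <= len(f1)
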