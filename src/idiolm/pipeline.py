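"""End-to-end pipeline: ingest/generate, filter, fit, summarize, compare.

Orchestrates the full analysis for a cohort of daily records: read (or
simulate) the long-format CSV, apply the on-time-survey window, the
minimum-compliance inclusion rule and the winter-break exclusion, fit the
requested person-level model presets by MCMC, assemble decision-rule
summary tables, classify lead-lag phenotypes, run residual diagnostics,
fit the group multilevel model and quantify shrinkage, and write
everything to CSV plus a machine-readable run manifest.  A fixed seed
makes the whole run byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calendars import StudyCalendar, make_calendar
from .diagnostics import residual_acf_check
from .inference import (
    PD_THRESHOLD,
    ROPE_FACTOR,
    SlopeSummary,
    classify_phenotype,
    summarize,
)
from .mlm import compare_shrinkage, fit_mlm
from .model import PriorSpec, fit_mcmc
from .prep import (
    DEFAULT_MIN_SURVEYS,
    PRESETS,
    InsufficientDataError,
    apply_inclusion,
    build_model_data,
    exclude_break,
    filter_on_time_surveys,
    read_daily_csv,
    validate_records,
)
from .simulate import simulate_cohort, write_cohort_csv, write_truth_csv

__all__ = ["RunConfig", "run_pipeline", "validate_input"]

log = logging.getLogger("idiolm")

RHAT_THRESHOLD = 1.1
ESS_THRESHOLD = 1000.0


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    input: str | None = None  # CSV path; None -> simulate a cohort
    n_participants: int = 49
    sampler: dict = field(default_factory=dict)  # CohortSampler range overrides
    fall_start: str = "2017-09-04"
    semester_weeks: int = 16
    break_weeks: int = 5
    max_semester_days: int | None = 223
    presets: list[str] = field(
        default_factory=lambda: list(PRESETS)
    )
    mlm_presets: list[str] = field(default_factory=lambda: ["stress_day_before"])
    chains: int = 4
    iterations: int = 5000
    warmup: int = 2500
    prior_scale: float = 2.5
    prior_autoscale: bool = True
    pd_threshold: float = PD_THRESHOLD
    rhat_threshold: float = RHAT_THRESHOLD
    ess_threshold: float = ESS_THRESHOLD
    rope_factor: float = ROPE_FACTOR
    min_surveys: int = DEFAULT_MIN_SURVEYS
    oracle_n: int = 200_000
    compute_oracle: bool = False
    outdir: str = "idiolm_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.presets) - set(PRESETS)
        if unknown:
            raise ValueError(f"unknown presets: {sorted(unknown)}")
        for name in ("pd_threshold", "rhat_threshold", "ess_threshold", "rope_factor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def calendar(self) -> StudyCalendar:
        return make_calendar(
            date.fromisoformat(self.fall_start),
            semester_weeks=self.semester_weeks,
            break_weeks=self.break_weeks,
            max_semester_days=self.max_semester_days,
        )

    def prior(self) -> PriorSpec:
        return PriorSpec(scale=self.prior_scale, autoscale=self.prior_autoscale)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_input(path, calendar: StudyCalendar | None = None) -> list[dict]:
    """Schema/range/duplicate/coverage checks with per-issue line numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    from .simulate import RECORD_COLUMNS

    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        return [
            {"line": 1, "severity": "error", "message": f"missing columns: {missing}"}
        ]
    issues = validate_records(df)
    if calendar is not None:
        dates = pd.to_datetime(df["date"], errors="coerce")
        for idx in df.index[dates.notna()]:
            d = dates[idx].date()
            if not calendar.in_study(d):
                issues.append(
                    {
                        "line": int(idx) + 2,
                        "severity": "warning",
                        "message": f"date {d} outside the study calendar",
                    }
                )
    return issues


def _fit_seed(base: int, *path: int) -> int:
    return int(np.random.SeedSequence([base, *path]).generate_state(1)[0] % 2**31)


def _summary_frame(rows: list[SlopeSummary], config: RunConfig) -> pd.DataFrame:
    recs = []
    for s in rows:
        recs.append(
            {
                "participant_id": s.participant_id,
                "n_obs": s.n_obs,
                "median_slope": round(s.median_slope, 2),
                "ui_low": round(s.ui_low, 2),
                "ui_high": round(s.ui_high, 2),
                "pd": round(s.pd, 2),
                "rope_halfwidth": round(s.rope_halfwidth, 2),
                "pct_ui_in_rope": round(s.pct_ui_in_rope, 2),
                "rhat": round(s.rhat, 2),
                "ess": int(round(s.ess)),
                "significant": s.significant,
                "converged": (s.rhat < config.rhat_threshold)
                and (s.ess > config.ess_threshold),
            }
        )
    return pd.DataFrame(recs)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write artifacts under ``config.outdir``.

    Participant-level fit failures (too few observations, degenerate
    designs) are logged and skipped; validation errors on input are fatal.
    Returns a dict with the in-memory results and artifact paths.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calendar = config.calendar()
    prior = config.prior()

    if config.input is not None:
        cohort = read_daily_csv(config.input)
        truth = None
    else:
        from .simulate import CohortSampler

        sampler_kw = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in config.sampler.items()}
        cohort, truth = simulate_cohort(
            config.n_participants,
            param_sampler=CohortSampler(**sampler_kw),
            calendar=calendar,
            seed=config.seed,
            oracle_n=config.oracle_n,
            compute_oracle=config.compute_oracle,
        )
        write_cohort_csv(cohort, outdir / "cohort.csv")
        if config.compute_oracle:
            write_truth_csv(truth, outdir / "cohort_truth.csv")

    # filtering and inclusion
    included: list[pd.DataFrame] = []
    excluded_ids: list[str] = []
    for series in cohort:
        pid = str(series["participant_id"].iloc[0])
        filtered = filter_on_time_surveys(series)
        if not apply_inclusion(filtered, min_surveys=config.min_surveys):
            excluded_ids.append(pid)
            log.info("participant %s excluded (<%d on-time surveys)", pid, config.min_surveys)
            continue
        included.append(exclude_break(filtered, calendar))

    # per-preset fits
    summaries: dict[str, list[SlopeSummary]] = {p: [] for p in config.presets}
    model_data: dict[str, dict[str, object]] = {p: {} for p in config.presets}
    diag_rows: list[dict] = []
    for pi, series in enumerate(included):
        pid = str(series["participant_id"].iloc[0])
        for qi, preset in enumerate(config.presets):
            try:
                md = build_model_data(series, PRESETS[preset])
            except InsufficientDataError as err:
                log.warning("skipping fit: %s", err)
                continue
            seed = _fit_seed(config.seed, pi, qi)
            draws = fit_mcmc(
                md,
                prior=prior,
                chains=config.chains,
                iterations=config.iterations,
                warmup=config.warmup,
                seed=seed,
            )
            s = summarize(
                draws,
                md,
                pd_threshold=config.pd_threshold,
                rope_factor=config.rope_factor,
            )
            summaries[preset].append(s)
            model_data[preset][pid] = md
            prof = residual_acf_check(draws, md)
            diag_rows.append(
                {
                    "participant_id": pid,
                    "preset": preset,
                    "resid_acf_max_abs": round(
                        float(np.nanmax(np.abs(prof.values))), 3
                    ),
                    "resid_acf_adequate": prof.adequate,
                    "rhat": round(s.rhat, 3),
                    "ess": int(round(s.ess)),
                }
            )

    artifacts: dict[str, object] = {
        "outdir": str(outdir),
        "summaries": summaries,
        "excluded": excluded_ids,
        "truth": truth,
    }

    for preset, rows in summaries.items():
        tbl = _summary_frame(rows, config)
        tbl.to_csv(outdir / f"summary_{preset}.csv", index=False)

    # phenotypes from the two cross-lagged stress models
    if {"stress_day_before", "stress_day_after"} <= set(config.presets):
        pre_by_id = {s.participant_id: s for s in summaries["stress_day_before"]}
        post_by_id = {s.participant_id: s for s in summaries["stress_day_after"]}
        ph_rows = []
        for pid in pre_by_id.keys() & post_by_id.keys():
            label = classify_phenotype(pre_by_id[pid], post_by_id[pid])
            ph_rows.append(
                {
                    "participant_id": pid,
                    "phenotype": label.label,
                    "sign_pre": label.sign_pre,
                    "sign_post": label.sign_post,
                }
            )
        phenotypes = pd.DataFrame(ph_rows).sort_values("participant_id")
        phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
        counts = phenotypes["phenotype"].value_counts().rename_axis("phenotype")
        counts.to_frame("count").to_csv(outdir / "phenotype_prevalence.csv")
        artifacts["phenotypes"] = phenotypes

    pd.DataFrame(diag_rows).to_csv(outdir / "diagnostics.csv", index=False)

    # multilevel comparison
    shrinkage = {}
    for preset in config.mlm_presets:
        mds = list(model_data.get(preset, {}).values())
        if len(mds) < 3:
            log.warning("too few participants for the %s multilevel fit", preset)
            continue
        mlm = fit_mlm(
            mds,
            prior=prior,
            chains=config.chains,
            iterations=min(config.iterations, 2000),
            warmup=min(config.warmup, 1000),
            seed=_fit_seed(config.seed, 9000, config.mlm_presets.index(preset)),
        )
        report = compare_shrinkage(
            [s for s in summaries[preset] if s.participant_id in model_data[preset]],
            mlm,
        )
        tbl = report.table.copy()
        for c in ("ilm_slope", "mlm_slope", "attenuation_ratio"):
            tbl[c] = tbl[c].round(2)
        tbl.to_csv(outdir / f"shrinkage_{preset}.csv", index=False)
        shrinkage[preset] = report
    artifacts["shrinkage"] = shrinkage

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_participants_input": len(cohort),
        "n_included": len(included),
        "excluded": excluded_ids,
        "fits": {p: len(rows) for p, rows in summaries.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    artifacts["manifest"] = manifest
    return artifacts
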