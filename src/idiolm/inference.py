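"""Posterior decision rules: uncertainty intervals, pd, ROPE, phenotypes.

Turns posterior draws into the row of a results table: the median slope,
its 95% equal-tailed uncertainty interval (2.5% and 97.5% quantiles), the
probability of direction (pd — the posterior mass on the sign of the point
estimate), the person-specific region of practical equivalence (ROPE — a
standardized effect below 0.1, i.e. half of Cohen's small effect, rescaled
to the person's raw units as ``0.1 * sd(y) / sd(x)``), the percentage of
the 95% UI inside the ROPE, convergence diagnostics, and a significance
flag (pd > 0.975, which approximates a one-tailed frequentist p < .025).

A participant's pair of cross-lagged stress models is then classified into
a lead-lag phenotype: stress-then-sleep, sleep-then-stress, bidirectional,
or none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .convergence import ess as _ess
from .convergence import rhat as _rhat
from .model import PosteriorDraws
from .prep import ModelData

__all__ = [
    "SlopeSummary",
    "PhenotypeLabel",
    "ui",
    "prob_direction",
    "rope_halfwidth",
    "rope_from_sds",
    "pct_ui_in_rope",
    "summarize",
    "classify_phenotype",
    "PD_THRESHOLD",
    "ROPE_FACTOR",
]

PD_THRESHOLD = 0.975
ROPE_FACTOR = 0.1
MIN_DRAWS = 100


def _pooled(draws, parameter: str | None) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        return draws.pooled(parameter if parameter is not None else "slope")
    return np.asarray(draws, dtype=float).reshape(-1)


def ui(draws, parameter: str | None = None, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed uncertainty interval from posterior draws.

    The default 95% UI spans the 2.5% and 97.5% linear-interpolation
    quantiles of the pooled post-warmup draws.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = _pooled(draws, parameter)
    if x.size < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def hdi(draws, parameter: str | None = None, level: float = 0.95) -> tuple[float, float]:
    """Highest-density interval (shortest interval holding ``level`` mass)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(_pooled(draws, parameter))
    n = x.size
    if n < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws")
    m = max(1, int(np.floor(level * n)))
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def prob_direction(draws, parameter: str | None = None) -> float:
    """Probability of direction: posterior mass on the dominant sign.

    Draws exactly at zero are split evenly between the two signs, so pd
    always lies in [0.5, 1].
    """
    x = _pooled(draws, parameter)
    if x.size < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws")
    pos = np.count_nonzero(x > 0) + 0.5 * np.count_nonzero(x == 0)
    frac = pos / x.size
    return float(max(frac, 1.0 - frac))


def rope_from_sds(sd_y: float, sd_x: float, factor: float = ROPE_FACTOR) -> float:
    """ROPE half-width in raw units from outcome and predictor SDs.

    A standardized effect of ``factor`` (default 0.1) converted to the raw
    slope scale: ``factor * sd_y / sd_x`` (minutes per Likert unit here).
    """
    if not sd_y > 0:
        raise ValueError("sd_y must be > 0")
    if not sd_x > 0:
        raise ValueError("ROPE is undefined for a zero-variance predictor")
    return factor * sd_y / sd_x


def rope_halfwidth(model_data: ModelData, factor: float = ROPE_FACTOR) -> float:
    """Person-specific ROPE half-width from the observations entering a fit.

    Uses the sample SDs of the outcome and predictor vectors actually
    modeled, so each participant's equivalence region reflects their own
    variability.
    """
    return rope_from_sds(model_data.sd_y, model_data.sd_x, factor)


def pct_ui_in_rope(
    draws,
    parameter: str | None = None,
    rope_halfwidth: float = 1.0,
    level: float = 0.95,
    interval: str = "eti",
) -> float:
    """Percentage of the 95% UI that falls inside [-rope, +rope].

    Computed on draws: the share of draws lying inside the interval that
    also lie inside the ROPE, times 100.  ``interval`` may be ``"eti"``
    (equal-tailed, the default, matching the quantile-based UI) or
    ``"hdi"``.
    """
    if not rope_halfwidth > 0:
        raise ValueError("rope_halfwidth must be > 0")
    x = _pooled(draws, parameter)
    if interval == "eti":
        lo, hi = ui(x, level=level)
    elif interval == "hdi":
        lo, hi = hdi(x, level=level)
    else:
        raise ValueError("interval must be 'eti' or 'hdi'")
    in_ui = (x >= lo) & (x <= hi)
    n_ui = int(in_ui.sum())
    if n_ui == 0:
        return 0.0
    inside = in_ui & (np.abs(x) <= rope_halfwidth)
    return float(100.0 * inside.sum() / n_ui)


@dataclass
class SlopeSummary:
    """One results-table row for a fitted person-level model."""

    model_name: str
    participant_id: str
    median_slope: float  # minutes per Likert unit
    ui_low: float
    ui_high: float
    pd: float
    rope_halfwidth: float
    pct_ui_in_rope: float
    rhat: float
    ess: float
    n_obs: int
    significant: bool

    def __post_init__(self) -> None:
        if not self.ui_low <= self.median_slope <= self.ui_high:
            raise ValueError("median must lie inside its own UI")

    @property
    def sign(self) -> str:
        if not self.significant:
            return "0"
        return "-" if self.median_slope < 0 else "+"


def summarize(
    draws: PosteriorDraws,
    model_data: ModelData,
    parameter: str = "slope",
    level: float = 0.95,
    pd_threshold: float = PD_THRESHOLD,
    rope_factor: float = ROPE_FACTOR,
) -> SlopeSummary:
    """Assemble the full decision-rule summary for the predictor slope."""
    x = draws.pooled(parameter)
    lo, hi = ui(x, level=level)
    pd_val = prob_direction(x)
    rope = rope_halfwidth(model_data, factor=rope_factor)
    pct = pct_ui_in_rope(x, rope_halfwidth=rope, level=level)
    chains = draws.get(parameter)
    return SlopeSummary(
        model_name=model_data.spec.name,
        participant_id=model_data.participant_id,
        median_slope=float(np.median(x)),
        ui_low=lo,
        ui_high=hi,
        pd=pd_val,
        rope_halfwidth=rope,
        pct_ui_in_rope=pct,
        rhat=_rhat(chains),
        ess=_ess(chains),
        n_obs=model_data.n,
        significant=pd_val > pd_threshold,
    )


@dataclass(frozen=True)
class PhenotypeLabel:
    """Lead-lag phenotype of one participant's stress-sleep coupling."""

    label: str  # stress_then_sleep | sleep_then_stress | bidirectional | none
    sign_pre: str  # sign of the stress -> next-night-sleep slope: -, 0, +
    sign_post: str  # sign of the sleep -> next-day-stress slope


def classify_phenotype(
    summary_pre: SlopeSummary, summary_post: SlopeSummary
) -> PhenotypeLabel:
    """Classify a participant from the two cross-lagged stress models.

    ``summary_pre`` is the stress-day-before model (stress leading sleep);
    ``summary_post`` the stress-day-after model (sleep leading stress,
    fitted as back-prediction).  Bidirectional means both are significant;
    none means neither.
    """
    if summary_pre.participant_id != summary_post.participant_id:
        raise ValueError(
            "phenotype requires both summaries from the same participant "
            f"(got {summary_pre.participant_id!r} and {summary_post.participant_id!r})"
        )
    pre, post = summary_pre.significant, summary_post.significant
    if pre and post:
        label = "bidirectional"
    elif pre:
        label = "stress_then_sleep"
    elif post:
        label = "sleep_then_stress"
    else:
        label = "none"
    return PhenotypeLabel(
        label=label, sign_pre=summary_pre.sign, sign_post=summary_post.sign
    )
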