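"""Domain types for home-telemonitoring spirometry analysis.

The data model mirrors how a home spirometry protocol is actually recorded:
each *session* (one execution of the protocol, morning or evening) contains a
handful of spirometry *efforts* per test type (FEV1 and IC), one symptom score
(CAT, 0-40), one pulse-oximetry reading (SpO2, %) and one heart rate (bpm).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator


class Marker(str, Enum):
    """Spirometry test type."""

    FEV1 = "FEV1"
    IC = "IC"


class Half(str, Enum):
    """Half of the day a session belongs to (the AM/PM stream)."""

    AM = "AM"
    PM = "PM"


@dataclass(frozen=True)
class Effort:
    """A single spirometry manoeuvre value with its operator/device validity flag.

    ``order`` is the index of the manoeuvre within the session for its test
    type; the protocol asks for at least three manoeuvres and allows repeats.
    """

    test_type: Marker
    value: float  # volume, litres
    valid: bool
    order: int

    def __post_init__(self) -> None:
        if self.valid and not self.value > 0:
            raise ValueError(f"valid effort must have positive volume, got {self.value}")


@dataclass
class Session:
    """One execution of the monitoring protocol (CAT, pulse oximetry, spirometry)."""

    participant_id: str
    timestamp: dt.datetime
    half: Half
    efforts: list[Effort] = field(default_factory=list)
    cat: Optional[int] = None  # COPD Assessment Test total, 0-40
    spo2: Optional[float] = None  # oxygen saturation, %
    heart_rate: Optional[float] = None  # bpm

    def __post_init__(self) -> None:
        if self.cat is not None and not (0 <= self.cat <= 40):
            raise ValueError(f"cat must be in [0, 40], got {self.cat}")
        if self.spo2 is not None and not (50 <= self.spo2 <= 100):
            raise ValueError(f"spo2 must be in [50, 100], got {self.spo2}")

    @property
    def date(self) -> dt.date:
        return self.timestamp.date()

    def efforts_of(self, marker: Marker) -> list[Effort]:
        return [e for e in self.efforts if e.test_type == marker]


@dataclass(frozen=True)
class Participant:
    """Participant metadata from the supervised (lab) baseline examination."""

    participant_id: str
    sex: str  # "f" or "m"
    baseline_fev1: float  # L, supervised spirometry
    baseline_ic: float  # L
    predicted_fev1: float  # L, reference-equation value
    predicted_ic: float  # L
    enrolment_date: dt.date


class ExacerbationEvent(BaseModel):
    """A synthetic exacerbation episode injected into a generated cohort.

    The true (noise-free) lung-function values inside the window are reduced by
    a multiplicative factor that ramps linearly down over ``ramp_days``, holds
    at the nadir, and ramps back up over the final ``ramp_days``; the CAT score
    rises correspondingly. Used only to probe detector sensitivity.
    """

    participant_id: str
    onset_day: int = Field(ge=0)
    duration_days: int = Field(gt=0)
    fev1_drop_frac: float = Field(ge=0, lt=1)
    ic_drop_frac: float = Field(ge=0, lt=1)
    cat_rise: float = Field(ge=0)
    ramp_days: int = Field(ge=0)

    def severity(self, day: int) -> float:
        """Ramped severity in [0, 1] at study-day ``day`` (0 outside the window)."""
        end = self.onset_day + self.duration_days
        if not (self.onset_day <= day < end):
            return 0.0
        if self.ramp_days == 0:
            return 1.0
        up = (day - self.onset_day) / self.ramp_days
        down = (end - 1 - day) / self.ramp_days
        return float(max(0.0, min(1.0, up, down)))


class CohortSpec(BaseModel):
    """Parameters of the synthetic home-monitoring cohort generator.

    Defaults emulate the monitored cohort the analysis is designed for:
    11 participants measuring twice daily (AM/PM) on three days a week for
    about six months, ~90% adherence, day-to-day FEV1 noise calibrated so the
    between-measurement delta SD is ~105 mL (2-SD range ~±210 mL) and IC noise
    so the delta SD is ~160 mL, a small PM-minus-AM diurnal offset, and a weak
    negative coupling between IC deviations and the CAT symptom score.
    """

    n_participants: int = Field(default=11, gt=0)
    study_days: int = Field(default=182, gt=0)
    sessions_per_week: int = Field(default=6, gt=0)

    # Baselines; None -> drawn per participant from plausible COPD ranges.
    baseline_fev1: Optional[Sequence[float]] = None  # L
    baseline_ic: Optional[Sequence[float]] = None  # L
    predicted_fev1: Optional[Sequence[float]] = None  # L
    predicted_ic: Optional[Sequence[float]] = None  # L

    adherence_prob: float = Field(default=0.906, ge=0, le=1)

    # Within-session (per-effort) noise. IC manoeuvres are harder to perform
    # unsupervised, hence the larger default.
    effort_sd_fev1: float = Field(default=0.05, ge=0)  # L
    effort_sd_ic: float = Field(default=0.16, ge=0)  # L
    # Between-session (day-to-day) noise, shared by AM and PM of the same day.
    # Calibrated jointly with the effort noise so the between-measurement
    # delta SD is ~105 mL for FEV1 and ~160 mL for IC.
    day_sd_fev1: float = Field(default=0.064, ge=0)  # L
    day_sd_ic: float = Field(default=0.064, ge=0)  # L
    # Additive PM - AM shift.
    diurnal_offset_fev1: float = 0.04  # L
    diurnal_offset_ic: float = 0.04  # L
    # Weekly random-walk drift.
    drift_sd: float = Field(default=0.02, ge=0)  # L / week
    # Correlation between the FEV1 and IC day-noise draws. High by default:
    # both markers track the same day-to-day airway state, and the observed
    # session-level correlation is further diluted by effort noise.
    fev1_ic_day_corr: float = Field(default=0.8, ge=-1, le=1)

    p_invalid_effort: float = Field(default=0.02, ge=0, le=1)
    # Probability that an invalid manoeuvre is repeated (at most two retries
    # per test type, five manoeuvres in total).
    p_retry: float = Field(default=0.7, ge=0, le=1)

    cat_baseline: float = Field(default=18.0, ge=0, le=40)
    cat_sd: float = Field(default=2.0, ge=0)
    # Coefficient linking the standardized IC deviation to CAT (negative ->
    # lower IC, higher symptoms).
    ic_cat_coupling: float = -0.35

    spo2_baseline: float = Field(default=95.0, ge=50, le=100)
    spo2_sd: float = Field(default=1.2, ge=0)
    heart_rate_baseline: float = Field(default=72.0, gt=0)
    heart_rate_sd: float = Field(default=5.0, ge=0)

    exacerbations: list[ExacerbationEvent] = Field(default_factory=list)
    seed: int = 0
    start_date: dt.date = dt.date(2014, 1, 6)

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.sessions_per_week % 2 != 0:
            raise ValueError("sessions_per_week must be even (AM+PM pairs)")
        if self.sessions_per_week > 14:
            raise ValueError("sessions_per_week cannot exceed 14")
        for name in ("baseline_fev1", "baseline_ic", "predicted_fev1", "predicted_ic"):
            v = getattr(self, name)
            if v is not None:
                if len(v) != self.n_participants:
                    raise ValueError(f"{name} must have length n_participants")
                if any(x <= 0 for x in v):
                    raise ValueError(f"{name} entries must be positive")
        for ev in self.exacerbations:
            if ev.onset_day + ev.duration_days > self.study_days:
                raise ValueError("exacerbation window extends past study_days")
        return self


@dataclass(frozen=True)
class SessionQC:
    """Acceptability/repeatability verdicts and derived session-level values.

    ``session_fev1`` is the largest selected valid FEV1 effort; ``session_ic``
    the mean of the selected valid IC efforts. The repeatability flags carry
    both conventions found in practice: the strict ``< 0.150 L`` acceptability
    rule and the ``<=`` reporting buckets at 150/100 mL; IC quality is a
    coefficient of variation compared with the 5/8/10% thresholds.
    """

    participant_id: str
    timestamp: dt.datetime
    half: Half
    n_valid_fev1: int
    n_valid_ic: int
    fev1_diff_top2: Optional[float]  # L
    fev1_acceptable: Optional[bool]  # strict < 0.150 L
    fev1_within_150: Optional[bool]  # bucket, <= 0.150 L
    fev1_within_100: Optional[bool]  # bucket, <= 0.100 L
    ic_cv: Optional[float]  # fraction (sample SD / mean)
    ic_cv_le_5: Optional[bool]
    ic_cv_le_8: Optional[bool]
    ic_cv_le_10: Optional[bool]
    session_fev1: Optional[float]  # L
    session_ic: Optional[float]  # L
    complete_fev1: bool  # >= 3 valid efforts
    complete_ic: bool
    cat: Optional[int]
    spo2: Optional[float]
    heart_rate: Optional[float]


@dataclass
class StudyCalendar:
    """Scheduling frame for adherence accounting.

    The first ``learning_days`` calendar days from ``first_session_date`` are a
    learning phase excluded from the analysis, as are any agreed breaks or
    maintenance interruptions listed in ``exclusion_windows`` (inclusive date
    pairs). Scheduled sessions are pro-rated at ``scheduled_per_week`` per
    7-day block.
    """

    participant_id: str
    first_session_date: dt.date
    learning_days: int = 14
    exclusion_windows: list[tuple[dt.date, dt.date]] = field(default_factory=list)
    scheduled_per_week: int = 6
    study_end_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.learning_days < 0:
            raise ValueError("learning_days must be >= 0")
        wins = sorted(self.exclusion_windows)
        for (s1, e1), (s2, e2) in zip(wins, wins[1:]):
            if s2 <= e1:
                raise ValueError("exclusion windows must be non-overlapping")
        for s, e in wins:
            if e < s:
                raise ValueError("exclusion window end precedes start")


@dataclass(frozen=True)
class DeltaSeries:
    """Changes between consecutive recorded sessions of one stream.

    ``stream`` restricts the pairing: AM pairs successive morning sessions,
    PM successive evening sessions, ALL pairs successive sessions regardless
    of half. Missing session values are skipped so the nearest recorded
    neighbours are paired.
    """

    participant_id: str
    marker: Marker
    stream: str  # ALL / AM / PM
    deltas_ml: tuple[float, ...]
    deltas_pctpred: tuple[float, ...]
    paired_dates: tuple[tuple[dt.date, dt.date], ...]

    def __post_init__(self) -> None:
        if not (len(self.deltas_ml) == len(self.deltas_pctpred) == len(self.paired_dates)):
            raise ValueError("delta series fields must have equal length")

    def __len__(self) -> int:
        return len(self.deltas_ml)


@dataclass(frozen=True)
class WeeklySummary:
    """Mean of all session-level values in one 7-day block of the study."""

    participant_id: str
    week_index: int  # 1-based, from the first post-learning session
    mean_fev1_pctpred: Optional[float]
    mean_ic_pctpred: Optional[float]
    mean_spo2: Optional[float]
    mean_cat: Optional[float]
    n_sessions: int


@dataclass(frozen=True)
class DecreasePeriod:
    """A maximal run of successive significant decreases in one AM/PM stream.

    ``n_steps`` counts the qualifying decrease steps, so the period spans
    ``n_steps + 1`` measurements; ``termination`` records what the next value
    did: a rebound (increase > the step threshold), essentially unchanged, or
    censored at the end of the series.
    """

    participant_id: str
    marker: Marker
    stream: str
    start_index: int
    end_index: int
    start_date: Optional[dt.date]
    end_date: Optional[dt.date]
    n_steps: int
    total_decrease: float  # mL, positive
    onset_above_mean: Optional[bool]
    termination: str  # rebound / unchanged / censored
    exceeds_total: bool

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("a decrease period requires >= 2 steps")
        # plateau steps absorbed by the extend-through-unchanged variant can
        # make the span longer than the count of qualifying steps
        if self.end_index < self.start_index + self.n_steps:
            raise ValueError("end_index must be at least start_index + n_steps")
        if not self.total_decrease > 0:
            raise ValueError("total_decrease must be positive")
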