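"""Synthetic home-monitoring cohort generator.

Emulates the data structure of a home-telehealth COPD study: each participant
executes the protocol twice daily (morning and evening) on a fixed set of
weekdays, producing per-session spirometry efforts (FEV1 and IC), a CAT score,
one SpO2 value and one heart rate. The generative model is

    truth(participant, day, half) = baseline
                                    + drift(week)            # random walk
                                    + diurnal_offset * 1[PM]
                                    + day_noise(day)          # shared AM/PM

with per-effort Gaussian noise on top and Bernoulli missingness of whole
sessions at ``1 - adherence_prob``. FEV1 and IC day-noise draws are correlated
(``fev1_ic_day_corr``) so the two markers co-vary the way they do in real
cohorts; CAT is linearly coupled to the standardized IC deviation
(``ic_cat_coupling``), rounded and clipped to [0, 40].

Everything is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import copy
import datetime as dt
from typing import Optional, Sequence

import numpy as np

from .models import (
    CohortSpec,
    Effort,
    ExacerbationEvent,
    Half,
    Marker,
    Participant,
    Session,
)

AM_HOUR = 8
PM_HOUR = 19
MAX_EFFORTS = 5  # 3 required manoeuvres + up to 2 retries
N_REQUIRED = 3

# Ranges used when baselines are not supplied: moderate-to-very-severe COPD,
# supervised baseline FEV1 well below predicted, IC relatively preserved.
_BASELINE_FEV1_RANGE = (0.55, 2.05)  # L
_PREDICTED_FEV1_RANGE = (1.7, 3.5)  # L
_BASELINE_IC_RANGE = (1.35, 3.6)  # L
_PREDICTED_IC_RANGE = (1.5, 3.35)  # L


def measurement_weekdays(sessions_per_week: int) -> list[int]:
    """Weekday offsets (0-6 within each 7-day block) carrying AM+PM sessions."""
    n_days = sessions_per_week // 2
    return [round(i * 7 / n_days) for i in range(n_days)]


def generate_cohort(spec: CohortSpec) -> tuple[list[Participant], list[Session]]:
    """Generate a synthetic cohort of participants and their executed sessions.

    Returns the participant metadata table and the time-ordered session list
    (missed sessions are simply absent). Reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    weekdays = measurement_weekdays(spec.sessions_per_week)
    n_weeks = int(np.ceil(spec.study_days / 7))

    def _baselines(values: Optional[Sequence[float]], lo: float, hi: float) -> np.ndarray:
        if values is not None:
            return np.asarray(values, dtype=float)
        return rng.uniform(lo, hi, size=spec.n_participants)

    b_fev1 = _baselines(spec.baseline_fev1, *_BASELINE_FEV1_RANGE)
    p_fev1 = _baselines(spec.predicted_fev1, *_PREDICTED_FEV1_RANGE)
    b_ic = _baselines(spec.baseline_ic, *_BASELINE_IC_RANGE)
    p_ic = _baselines(spec.predicted_ic, *_PREDICTED_IC_RANGE)
    sexes = rng.choice(["f", "m"], size=spec.n_participants, p=[8 / 11, 3 / 11])

    participants = [
        Participant(
            participant_id=f"P{i + 1:02d}",
            sex=str(sexes[i]),
            baseline_fev1=float(b_fev1[i]),
            baseline_ic=float(b_ic[i]),
            predicted_fev1=float(p_fev1[i]),
            predicted_ic=float(p_ic[i]),
            enrolment_date=spec.start_date,
        )
        for i in range(spec.n_participants)
    ]

    sessions: list[Session] = []
    corr = spec.fev1_ic_day_corr
    for i, part in enumerate(participants):
        # One weekly random-walk drift per participant, shared by FEV1 and IC:
        # slow changes in lung function move both markers together.
        if n_weeks > 1:
            drift = np.concatenate([[0.0], np.cumsum(rng.normal(0, spec.drift_sd, n_weeks - 1))])
        else:
            drift = np.zeros(1)
        drift_fev1 = drift_ic = drift

        for day in range(spec.study_days):
            week, weekday = divmod(day, 7)
            if weekday not in weekdays:
                continue
            # Correlated day-noise draws shared by AM and PM.
            z1, z2 = rng.standard_normal(2)
            z_ic = corr * z1 + np.sqrt(max(0.0, 1 - corr**2)) * z2
            day_noise_fev1 = spec.day_sd_fev1 * z1
            day_noise_ic = spec.day_sd_ic * z_ic

            for half in (Half.AM, Half.PM):
                executed = rng.random() < spec.adherence_prob
                # All random draws for the session are consumed regardless of
                # execution so missingness does not perturb later values.
                truth_fev1 = (
                    b_fev1[i]
                    + drift_fev1[week]
                    + (spec.diurnal_offset_fev1 if half is Half.PM else 0.0)
                    + day_noise_fev1
                )
                truth_ic = (
                    b_ic[i]
                    + drift_ic[week]
                    + (spec.diurnal_offset_ic if half is Half.PM else 0.0)
                    + day_noise_ic
                )
                efforts = _draw_efforts(rng, Marker.IC, truth_ic, spec.effort_sd_ic, spec.p_invalid_effort, spec.p_retry)
                efforts += _draw_efforts(rng, Marker.FEV1, truth_fev1, spec.effort_sd_fev1, spec.p_invalid_effort, spec.p_retry)

                z_dev = (truth_ic - b_ic[i]) / spec.day_sd_ic if spec.day_sd_ic > 0 else 0.0
                cat_raw = spec.cat_baseline + spec.ic_cat_coupling * z_dev + rng.normal(0, spec.cat_sd)
                cat = int(np.clip(round(cat_raw), 0, 40))
                spo2 = float(np.clip(round(spec.spo2_baseline + rng.normal(0, spec.spo2_sd)), 50, 100))
                hr = float(round(spec.heart_rate_baseline + rng.normal(0, spec.heart_rate_sd)))

                if not executed:
                    continue
                ts = dt.datetime.combine(
                    spec.start_date + dt.timedelta(days=day),
                    dt.time(AM_HOUR if half is Half.AM else PM_HOUR, 0),
                )
                sessions.append(
                    Session(
                        participant_id=part.participant_id,
                        timestamp=ts,
                        half=half,
                        efforts=efforts,
                        cat=cat,
                        spo2=spo2,
                        heart_rate=hr,
                    )
                )

    for event in spec.exacerbations:
        sessions = inject_exacerbation(sessions, event, study_start=spec.start_date)
    return participants, sessions


def _draw_efforts(
    rng: np.random.Generator,
    marker: Marker,
    truth: float,
    effort_sd: float,
    p_invalid: float,
    p_retry: float,
) -> list[Effort]:
    """Draw the three required manoeuvres, retrying invalid ones probabilistically.

    An invalid manoeuvre is repeated with probability ``p_retry`` (the
    protocol allows repeats but participants do not always use them), up to
    two retries so a session holds at most five efforts per test type.
    """
    efforts: list[Effort] = []
    n_valid = 0
    order = 0
    pending = N_REQUIRED
    while pending > 0 and order < MAX_EFFORTS:
        value = truth + rng.normal(0, effort_sd)
        value = max(value, 0.05)
        invalid = rng.random() < p_invalid
        efforts.append(Effort(test_type=marker, value=float(value), valid=not invalid, order=order))
        order += 1
        if invalid:
            retry = rng.random() < p_retry and order < MAX_EFFORTS
            if not retry:
                pending -= 1  # manoeuvre abandoned, session stays incomplete
        else:
            n_valid += 1
            pending -= 1
    return efforts


def inject_exacerbation(
    sessions: list[Session],
    event: ExacerbationEvent,
    study_start: Optional[dt.date] = None,
) -> list[Session]:
    """Apply an exacerbation episode to a generated session list.

    Effort volumes of the affected participant inside the event window are
    scaled by ``1 - drop_frac * severity(day)`` (marker-specific) and CAT is
    raised by ``round(cat_rise * severity)``, clipped to 40. Sessions outside
    the window are returned unchanged (same objects).

    ``study_start`` anchors ``onset_day``; when omitted, the earliest session
    date in the cohort is used.
    """
    known = {s.participant_id for s in sessions}
    if event.participant_id not in known:
        raise ValueError(f"unknown participant_id {event.participant_id!r}")
    if study_start is None:
        study_start = min(s.date for s in sessions)

    out: list[Session] = []
    for s in sessions:
        if s.participant_id != event.participant_id:
            out.append(s)
            continue
        day = (s.date - study_start).days
        sev = event.severity(day)
        if sev == 0.0:
            out.append(s)
            continue
        f_fev1 = 1.0 - event.fev1_drop_frac * sev
        f_ic = 1.0 - event.ic_drop_frac * sev
        new = copy.deepcopy(s)
        new.efforts = [
            Effort(
                test_type=e.test_type,
                value=e.value * (f_fev1 if e.test_type is Marker.FEV1 else f_ic),
                valid=e.valid,
                order=e.order,
            )
            for e in s.efforts
        ]
        if new.cat is not None:
            new.cat = int(min(40, new.cat + round(event.cat_rise * sev)))
        out.append(new)
    return out


def scheduled_sessions(spec: CohortSpec) -> int:
    """Number of sessions scheduled per participant over the whole study."""
    weekdays = measurement_weekdays(spec.sessions_per_week)
    return sum(
        2
        for day in range(spec.study_days)
        if day % 7 in weekdays
    )
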