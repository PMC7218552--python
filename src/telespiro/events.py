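"""Detection of periods with successive significant decreases in lung function.

The candidate exacerbation-alerting rule: within one AM or PM stream, a
significant step is a decrease of more than ``step_threshold`` (default
50 mL) between two consecutive measurements, and a *decrease period* is a
maximal run of at least two such steps. The period ends when the next value
rises by more than the step threshold (*rebound*); a smaller movement leaves
the marker *unchanged*; a period running into the end of the series is
*censored*.

Two rule variants are provided through ``mode``:

- ``per_step`` (default): every step must individually fall by more than the
  step threshold, so two steps imply a total fall of more than twice the
  threshold.
- ``total``: every step must fall (by any amount) and the cumulative fall
  over the run must exceed ``total_threshold``. This is the reading needed to
  count runs whose *total* decrease exceeds a bound without each step being
  individually significant.

Each period also records whether its onset value was above the participant's
overall stream mean and whether the cumulative fall exceeds
``total_threshold``.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import DecreasePeriod, Marker

STEP_THRESHOLD_ML = 50.0
TOTAL_THRESHOLD_ML = 100.0
MODES = ("per_step", "total")


def detect_decrease_periods(
    values: Sequence[float],
    mode: str = "per_step",
    step_threshold: float = STEP_THRESHOLD_ML,
    total_threshold: float = TOTAL_THRESHOLD_ML,
    reference_mean: Optional[float] = None,
    dates: Optional[Sequence[dt.date]] = None,
    participant_id: str = "",
    marker: Marker = Marker.FEV1,
    stream: str = "AM",
    extend_through_unchanged: bool = False,
) -> list[DecreasePeriod]:
    """Scan one chronological stream of session values (mL) for decrease periods.

    Periods are maximal and non-overlapping, scanned left to right; after a
    period terminates, scanning resumes at the terminating value (which may
    begin a new period). Fewer than three values cannot contain a period.

    With ``extend_through_unchanged`` a period is not closed by a small
    (within-threshold) movement when further qualifying decreases follow; the
    plateau steps are absorbed and only qualifying decreases are counted in
    ``n_steps``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        return []
    if dates is not None and len(dates) != n:
        raise ValueError("dates must align with values")

    diffs = np.diff(v)
    if mode == "per_step":
        qual = diffs < -step_threshold
    else:
        qual = diffs < 0
    if extend_through_unchanged:
        return _scan_extended(
            v, diffs, qual, mode, step_threshold, total_threshold, reference_mean,
            dates, participant_id, marker, stream,
        )

    periods: list[DecreasePeriod] = []
    i = 0
    while i < n - 1:
        if qual[i] and i + 1 < n - 1 and qual[i + 1]:
            j = i + 1
            while j < n - 1 and qual[j]:
                j += 1
            start, end = i, j  # steps start..j-1 qualify
            total = v[start] - v[end]
            keep = True if mode == "per_step" else total > total_threshold
            if keep:
                if end < n - 1:
                    nxt = v[end + 1] - v[end]
                    termination = "rebound" if nxt > step_threshold else "unchanged"
                else:
                    termination = "censored"
                periods.append(
                    _make_period(
                        v, start, end, end - start, total, termination, reference_mean,
                        total_threshold, dates, participant_id, marker, stream,
                    )
                )
            i = end + 1 if end < n - 1 else end
        else:
            i += 1
    return periods


def _make_period(
    v, start, end, n_steps, total, termination, reference_mean, total_threshold,
    dates, participant_id, marker, stream,
) -> DecreasePeriod:
    return DecreasePeriod(
        participant_id=participant_id,
        marker=marker,
        stream=stream,
        start_index=int(start),
        end_index=int(end),
        start_date=dates[start] if dates is not None else None,
        end_date=dates[end] if dates is not None else None,
        n_steps=int(n_steps),
        total_decrease=float(total),
        onset_above_mean=(bool(v[start] > reference_mean) if reference_mean is not None else None),
        termination=termination,
        exceeds_total=bool(total > total_threshold),
    )


def _scan_extended(
    v, diffs, qual, mode, step_threshold, total_threshold, reference_mean,
    dates, participant_id, marker, stream,
):
    """Variant allowing within-threshold plateau steps inside a period."""
    n = len(v)
    # a step may continue an open period if it is qualifying or a plateau
    plateau = np.abs(diffs) <= step_threshold
    periods: list[DecreasePeriod] = []
    i = 0
    while i < n - 1:
        if qual[i] and i + 1 < n - 1 and (qual[i + 1] or plateau[i + 1]):
            j = i + 1
            last_qual = i
            while j < n - 1 and (qual[j] or plateau[j]):
                if qual[j]:
                    last_qual = j
                j += 1
            start, end = i, last_qual + 1  # trim trailing plateau
            n_steps = int(qual[start:end].sum())
            total = v[start] - v[end]
            keep = n_steps >= 2 and (mode == "per_step" or total > total_threshold)
            if keep:
                if end < n - 1:
                    nxt = v[end + 1] - v[end]
                    termination = "rebound" if nxt > step_threshold else "unchanged"
                else:
                    termination = "censored"
                periods.append(
                    _make_period(
                        v, start, end, n_steps, total, termination, reference_mean,
                        total_threshold, dates, participant_id, marker, stream,
                    )
                )
                i = end + 1 if end < n - 1 else end
            else:
                i += 1
        else:
            i += 1
    return periods


def detect_cohort_periods(
    qc_table: pd.DataFrame,
    marker: Marker,
    mode: str = "per_step",
    step_threshold: float = STEP_THRESHOLD_ML,
    total_threshold: float = TOTAL_THRESHOLD_ML,
    learning_days: int = 14,
    extend_through_unchanged: bool = False,
) -> list[DecreasePeriod]:
    """Run the detector on every participant's AM and PM streams.

    Values are post-learning session-level marker values in mL; the reference
    mean used for the onset-above-mean flag is the participant's overall
    post-learning mean of the same stream.
    """
    col = "session_fev1_l" if marker is Marker.FEV1 else "session_ic_l"
    periods: list[DecreasePeriod] = []
    for pid, df in qc_table.groupby("participant_id", sort=True):
        df = df.sort_values("timestamp")
        dates = pd.to_datetime(df["timestamp"]).dt.date
        if df.empty:
            continue
        first_eligible = dates.min() + dt.timedelta(days=learning_days)
        post = df[np.array([d >= first_eligible for d in dates])]
        for stream in ("AM", "PM"):
            sub = post[post["half"] == stream].dropna(subset=[col])
            vals = sub[col].to_numpy(dtype=float) * 1000.0
            if len(vals) < 3:
                continue
            sdates = list(pd.to_datetime(sub["timestamp"]).dt.date)
            periods.extend(
                detect_decrease_periods(
                    vals,
                    mode=mode,
                    step_threshold=step_threshold,
                    total_threshold=total_threshold,
                    reference_mean=float(vals.mean()),
                    dates=sdates,
                    participant_id=pid,
                    marker=marker,
                    stream=stream,
                    extend_through_unchanged=extend_through_unchanged,
                )
            )
    return periods


def period_summary(periods: Sequence[DecreasePeriod]) -> dict:
    """Tabulate detected periods the way a monitoring report presents them.

    ``by_n_steps`` labels a period spanning ``n`` decrease steps as an
    "n-day period" (the run covers n+1 measurement days in its stream).
    """
    by_steps: dict[int, int] = {}
    by_term = {"rebound": 0, "unchanged": 0, "censored": 0}
    onset_above = 0
    exceeds = 0
    for p in periods:
        by_steps[p.n_steps] = by_steps.get(p.n_steps, 0) + 1
        by_term[p.termination] += 1
        if p.onset_above_mean:
            onset_above += 1
        if p.exceeds_total:
            exceeds += 1
    return {
        "n_periods": len(periods),
        "by_n_steps": dict(sorted(by_steps.items())),
        "by_termination": by_term,
        "onset_above_mean": onset_above,
        "exceeds_total_threshold": exceeds,
    }


def periods_table(periods: Sequence[DecreasePeriod]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": p.participant_id,
            "marker": p.marker.value,
            "stream": p.stream,
            "start_index": p.start_index,
            "end_index": p.end_index,
            "start_date": p.start_date,
            "end_date": p.end_date,
            "n_steps": p.n_steps,
            "total_decrease_ml": p.total_decrease,
            "onset_above_mean": p.onset_above_mean,
            "termination": p.termination,
            "exceeds_total": p.exceeds_total,
        }
        for p in periods
    ]
    return pd.DataFrame(rows)
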