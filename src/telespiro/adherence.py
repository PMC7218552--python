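"""Protocol adherence accounting.

Adherence is the ratio of executed protocol sessions to scheduled sessions
over the eligible study span: everything after the per-participant learning
phase (default: first 14 calendar days), minus any agreed exclusion windows
(breaks, system maintenance). The scheduled count is pro-rated at
``scheduled_per_week`` per 7-day block; partial weeks contribute
``round(scheduled_per_week * days / 7)``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .models import Session, StudyCalendar


@dataclass(frozen=True)
class AdherenceResult:
    participant_id: str
    ratio: Optional[float]
    executed: int
    scheduled: int
    capped: bool  # True when executed exceeded scheduled (ratio > 1)
    reason: Optional[str] = None  # set when ratio is undefined


def _prorated(scheduled_per_week: int, days: int) -> int:
    whole_weeks, rem = divmod(days, 7)
    return scheduled_per_week * whole_weeks + round(scheduled_per_week * rem / 7)


def _overlap_days(a_start: dt.date, a_end: dt.date, b_start: dt.date, b_end: dt.date) -> int:
    start = max(a_start, b_start)
    end = min(a_end, b_end)
    return max(0, (end - start).days + 1)


def adherence_ratio(sessions: Iterable[Session], calendar: StudyCalendar) -> AdherenceResult:
    """Executed / scheduled sessions over the post-learning, non-excluded span.

    Sessions must belong to the calendar's participant. The eligible span runs
    from ``first_session_date + learning_days`` to ``study_end_date`` (or the
    last observed session date). A ratio above 1 — possible when a participant
    measured more often than scheduled — is reported as-is with ``capped``
    set.
    """
    sessions = list(sessions)
    for s in sessions:
        if s.participant_id != calendar.participant_id:
            raise ValueError(
                f"session participant {s.participant_id!r} does not match calendar "
                f"{calendar.participant_id!r}"
            )

    start = calendar.first_session_date + dt.timedelta(days=calendar.learning_days)
    end = calendar.study_end_date
    if end is None:
        if not sessions:
            return AdherenceResult(calendar.participant_id, None, 0, 0, False, "no sessions")
        end = max(s.date for s in sessions)
    if end < start:
        return AdherenceResult(calendar.participant_id, None, 0, 0, False, "no eligible span")

    span_days = (end - start).days + 1
    scheduled = _prorated(calendar.scheduled_per_week, span_days)
    for w_start, w_end in calendar.exclusion_windows:
        scheduled -= _prorated(
            calendar.scheduled_per_week, _overlap_days(start, end, w_start, w_end)
        )
    if scheduled <= 0:
        return AdherenceResult(calendar.participant_id, None, 0, 0, False, "no eligible span")

    def excluded(d: dt.date) -> bool:
        return any(ws <= d <= we for ws, we in calendar.exclusion_windows)

    executed = sum(1 for s in sessions if start <= s.date <= end and not excluded(s.date))
    ratio = executed / scheduled
    return AdherenceResult(calendar.participant_id, ratio, executed, scheduled, ratio > 1)


def cohort_adherence(
    sessions: Iterable[Session], calendars: Iterable[StudyCalendar]
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-participant adherence table and the pooled cohort ratio.

    The pooled ratio divides total executed by total scheduled over
    participants with a defined ratio; the per-participant mean is also in the
    table metadata users may prefer for unbalanced cohorts.
    """
    sessions = list(sessions)
    rows = []
    tot_exec = tot_sched = 0
    for cal in calendars:
        own = [s for s in sessions if s.participant_id == cal.participant_id]
        res = adherence_ratio(own, cal)
        rows.append(
            {
                "participant_id": res.participant_id,
                "adherence": res.ratio,
                "executed": res.executed,
                "scheduled": res.scheduled,
                "capped": res.capped,
                "reason": res.reason,
            }
        )
        if res.ratio is not None:
            tot_exec += res.executed
            tot_sched += res.scheduled
    pooled = tot_exec / tot_sched if tot_sched else None
    return pd.DataFrame(rows), pooled
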