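"""Session-level spirometry quality control.

Implements the ATS/ERS-style rules a home-monitoring pipeline applies to each
protocol execution: select the best (largest) valid manoeuvres, judge FEV1
repeatability from the gap between the two largest efforts, judge IC quality
from the coefficient of variation of the selected efforts, and derive the
session values used downstream — the largest valid FEV1 and the mean of the
selected IC efforts.

Two comparison conventions coexist in practice for the 150 mL rule: strict
``< 0.150 L`` as an acceptability criterion and ``<= 150 mL`` as a reporting
bucket. Both are computed and carried through; ``qc_report`` records which
convention each fraction uses.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import Effort, Half, Marker, Session, SessionQC

REPEATABILITY_L = 0.150  # ATS/ERS FEV1 repeatability threshold, litres
REPEATABILITY_STRICT_L = 0.100  # threshold applicable when FVC < 1 L
CV_THRESHOLDS = (0.05, 0.08, 0.10)
N_BEST = 3


def select_best_efforts(efforts: Sequence[Effort], k: int = N_BEST) -> list[Effort]:
    """Up to ``k`` valid efforts with the largest volumes.

    Order is by value descending, ties broken by manoeuvre order; fewer than
    ``k`` are returned when fewer are valid. All efforts must share a test
    type.
    """
    types = {e.test_type for e in efforts}
    if len(types) > 1:
        raise ValueError(f"mixed test types in effort list: {sorted(t.value for t in types)}")
    valid = [e for e in efforts if e.valid]
    return sorted(valid, key=lambda e: (-e.value, e.order))[:k]


def fev1_repeatability(
    selected: Sequence[Effort],
) -> tuple[Optional[float], Optional[bool], Optional[bool], Optional[bool]]:
    """Gap between the two largest selected FEV1 efforts and its verdicts.

    Returns ``(diff_top2_l, acceptable, within_150, within_100)`` where
    ``acceptable`` uses the strict ``< 0.150 L`` criterion and the two bucket
    flags use ``<=`` at 150 and 100 mL. With fewer than two efforts all
    results are None.
    """
    if len(selected) < 2:
        return None, None, None, None
    vals = sorted((e.value for e in selected), reverse=True)
    # volumes are recorded at mL resolution; compare at micro-litre rounding
    # so boundary values are not misclassified by float artifacts
    diff = round(vals[0] - vals[1], 6)
    return diff, diff < REPEATABILITY_L, diff <= REPEATABILITY_L, diff <= REPEATABILITY_STRICT_L


def ic_cv(
    selected: Sequence[Effort],
) -> tuple[Optional[float], Optional[bool], Optional[bool], Optional[bool]]:
    """Coefficient of variation (sample SD / mean) of the selected IC efforts.

    Returns ``(cv, cv <= 5%, cv <= 8%, cv <= 10%)``; None everywhere with
    fewer than two efforts or a non-positive mean.
    """
    if len(selected) < 2:
        return None, None, None, None
    vals = np.array([e.value for e in selected])
    mean = vals.mean()
    if mean <= 0:
        return None, None, None, None
    cv = float(round(vals.std(ddof=1) / mean, 6))  # see repeatability rounding note
    t5, t8, t10 = CV_THRESHOLDS
    return cv, cv <= t5, cv <= t8, cv <= t10


def summarize_session(session: Session) -> SessionQC:
    """QC verdicts and derived FEV1/IC values for one session."""
    sel_fev1 = select_best_efforts(session.efforts_of(Marker.FEV1))
    sel_ic = select_best_efforts(session.efforts_of(Marker.IC))

    diff, acceptable, w150, w100 = fev1_repeatability(sel_fev1)
    cv, le5, le8, le10 = ic_cv(sel_ic)

    return SessionQC(
        participant_id=session.participant_id,
        timestamp=session.timestamp,
        half=session.half,
        n_valid_fev1=len(sel_fev1),
        n_valid_ic=len(sel_ic),
        fev1_diff_top2=diff,
        fev1_acceptable=acceptable,
        fev1_within_150=w150,
        fev1_within_100=w100,
        ic_cv=cv,
        ic_cv_le_5=le5,
        ic_cv_le_8=le8,
        ic_cv_le_10=le10,
        session_fev1=max((e.value for e in sel_fev1), default=None),
        session_ic=float(np.mean([e.value for e in sel_ic])) if sel_ic else None,
        complete_fev1=len(sel_fev1) >= N_BEST,
        complete_ic=len(sel_ic) >= N_BEST,
        cat=session.cat,
        spo2=session.spo2,
        heart_rate=session.heart_rate,
    )


def summarize_sessions(sessions: Iterable[Session]) -> pd.DataFrame:
    """Per-session QC table (one row per session, chronological per participant)."""
    rows = []
    for s in sessions:
        qc = summarize_session(s)
        rows.append(
            {
                "participant_id": qc.participant_id,
                "timestamp": qc.timestamp,
                "date": qc.timestamp.date(),
                "half": qc.half.value,
                "n_valid_fev1": qc.n_valid_fev1,
                "n_valid_ic": qc.n_valid_ic,
                "fev1_diff_top2_l": qc.fev1_diff_top2,
                "fev1_acceptable": qc.fev1_acceptable,
                "fev1_within_150": qc.fev1_within_150,
                "fev1_within_100": qc.fev1_within_100,
                "ic_cv": qc.ic_cv,
                "ic_cv_le_5": qc.ic_cv_le_5,
                "ic_cv_le_8": qc.ic_cv_le_8,
                "ic_cv_le_10": qc.ic_cv_le_10,
                "session_fev1_l": qc.session_fev1,
                "session_ic_l": qc.session_ic,
                "complete_fev1": qc.complete_fev1,
                "complete_ic": qc.complete_ic,
                "cat": qc.cat,
                "spo2": qc.spo2,
                "heart_rate": qc.heart_rate,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)
    return df


def qc_report(qc_table: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level completeness and threshold-bucket fractions.

    Completeness fractions (3 / 2 / 1 / 0 valid manoeuvres) are over all
    sessions; repeatability and CV bucket fractions are over sessions with at
    least two valid efforts of the marker. The denominator policy and the
    comparison convention are recorded in the ``convention`` column.
    """
    if qc_table.empty:
        raise ValueError("qc_report requires at least one session")
    n = len(qc_table)
    rows = []

    def add(metric, value, denominator, convention):
        rows.append(
            {"metric": metric, "value": value, "denominator": denominator, "convention": convention}
        )

    for marker, col in (("fev1", "n_valid_fev1"), ("ic", "n_valid_ic")):
        counts = qc_table[col].clip(upper=3).value_counts()
        for k in (3, 2, 1, 0):
            add(
                f"{marker}_complete_{k}",
                counts.get(k, 0) / n,
                n,
                "fraction of all sessions with exactly this many valid efforts (3 = complete)",
            )

    rep = qc_table[qc_table["n_valid_fev1"] >= 2]
    if len(rep):
        add("fev1_acceptable_strict", rep["fev1_acceptable"].mean(), len(rep), "diff < 0.150 L; sessions with >=2 valid FEV1 efforts")
        add("fev1_within_150", rep["fev1_within_150"].mean(), len(rep), "diff <= 150 mL; sessions with >=2 valid FEV1 efforts")
        add("fev1_within_100", rep["fev1_within_100"].mean(), len(rep), "diff <= 100 mL; sessions with >=2 valid FEV1 efforts")
    cvr = qc_table[qc_table["n_valid_ic"] >= 2]
    if len(cvr):
        for t, col in ((5, "ic_cv_le_5"), (8, "ic_cv_le_8"), (10, "ic_cv_le_10")):
            add(f"ic_cv_le_{t}", cvr[col].mean(), len(cvr), f"CV <= {t}%; sessions with >=2 valid IC efforts")
    return pd.DataFrame(rows)
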