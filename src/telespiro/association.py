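"""Cross-marker association analysis.

Per participant, Pearson correlations between session-level markers (FEV1, IC,
CAT, SpO2) over pairwise-complete sessions (AM and PM both included), then
cross-participant medians and IQR widths, and the count of participants whose
correlation reaches a "moderate" strength threshold. Also descriptive group
contrasts: paired same-day PM-minus-AM differences and beginning/mid/late
period means — the descriptive analogue of a mixed-model analysis, which this
package deliberately leaves to off-the-shelf fitters.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .models import Participant

MARKER_PAIRS = (
    ("fev1", "ic"),
    ("ic", "cat"),
    ("fev1", "cat"),
    ("ic", "spo2"),
    ("fev1", "spo2"),
)
_COLS = {"fev1": "session_fev1_l", "ic": "session_ic_l", "cat": "cat", "spo2": "spo2"}
MIN_PAIRS = 3
MODERATE_R = 0.40


def _pair_label(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def marker_correlations(qc_table: pd.DataFrame, participant_id: str) -> dict[str, object]:
    """One participant's row of the correlation table.

    For each marker pair, Pearson r over sessions where both markers are
    recorded; cells with fewer than three pairs or a zero-variance marker are
    NaN with the reason recorded in ``<pair>_reason``.
    """
    df = qc_table[qc_table["participant_id"] == participant_id]
    row: dict[str, object] = {"participant_id": participant_id}
    for a, b in MARKER_PAIRS:
        label = _pair_label(a, b)
        sub = df[[_COLS[a], _COLS[b]]].dropna()
        x = sub[_COLS[a]].to_numpy(dtype=float)
        y = sub[_COLS[b]].to_numpy(dtype=float)
        if len(sub) < MIN_PAIRS:
            row[label], row[f"{label}_n"], row[f"{label}_reason"] = float("nan"), len(sub), "too few pairs"
        elif np.ptp(x) == 0 or np.ptp(y) == 0:
            row[label], row[f"{label}_n"], row[f"{label}_reason"] = float("nan"), len(sub), "zero variance"
        else:
            row[label] = float(pearsonr(x, y).statistic)
            row[f"{label}_n"] = len(sub)
            row[f"{label}_reason"] = None
    return row


def correlation_table(qc_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant Pearson correlations for all marker pairs."""
    pids = sorted(qc_table["participant_id"].unique())
    return pd.DataFrame([marker_correlations(qc_table, pid) for pid in pids])


def correlation_summary(
    table: pd.DataFrame, strength_threshold: float = MODERATE_R
) -> pd.DataFrame:
    """Cross-participant median, IQR width and strength counts per marker pair.

    The median is the middle order statistic (mean of the middle two for even
    n); the IQR is reported as a single width Q3 - Q1 using linear
    interpolation (the quantile convention is recorded in the output).
    ``n_ge_threshold`` counts participants with r at or above
    ``strength_threshold`` ("moderate or stronger positive").
    """
    if table.empty:
        raise ValueError("correlation summary requires at least one participant row")
    rows = []
    for a, b in MARKER_PAIRS:
        label = _pair_label(a, b)
        r = table[label].dropna().to_numpy(dtype=float)
        if len(r) == 0:
            rows.append({"pair": label, "median": float("nan"), "iqr": float("nan"),
                         "n": 0, "n_ge_threshold": 0,
                         "quantile_convention": "linear interpolation"})
            continue
        q1, q3 = np.percentile(r, [25, 75])
        rows.append(
            {
                "pair": label,
                "median": float(np.median(r)),
                "iqr": float(q3 - q1),
                "n": len(r),
                "n_ge_threshold": int((r >= strength_threshold).sum()),
                "quantile_convention": "linear interpolation",
            }
        )
    return pd.DataFrame(rows)


def group_contrasts(
    qc_table: pd.DataFrame,
    learning_days: int = 14,
) -> dict[str, pd.DataFrame]:
    """Descriptive AM-vs-PM and beginning/mid/late contrasts per marker.

    ``diurnal``: paired same-day PM - AM differences (sessions from the same
    calendar day), summarised as cohort mean, SD, SE and pair count per
    marker. ``period``: each participant's post-learning span is split into
    three equal time intervals (beginning/mid/late); per-participant period
    means are averaged across the cohort.
    """
    markers = ("fev1", "ic", "spo2", "cat")

    # --- paired same-day PM - AM differences -------------------------------
    diffs: dict[str, list[float]] = {m: [] for m in markers}
    for pid, df in qc_table.groupby("participant_id", sort=True):
        df = df.assign(_date=pd.to_datetime(df["timestamp"]).dt.date)
        for _, day in df.groupby("_date"):
            am = day[day["half"] == "AM"]
            pm = day[day["half"] == "PM"]
            if len(am) != 1 or len(pm) != 1:
                continue
            for m in markers:
                a, p = am[_COLS[m]].iloc[0], pm[_COLS[m]].iloc[0]
                if pd.notna(a) and pd.notna(p):
                    diffs[m].append(float(p) - float(a))
    diurnal_rows = []
    for m in markers:
        d = np.asarray(diffs[m], dtype=float)
        n = len(d)
        diurnal_rows.append(
            {
                "marker": m,
                "mean_pm_minus_am": float(d.mean()) if n else float("nan"),
                "sd": float(d.std(ddof=1)) if n >= 2 else float("nan"),
                "se": float(d.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan"),
                "n_pairs": n,
            }
        )

    # --- beginning / mid / late tertile means ------------------------------
    period_accum: dict[tuple[str, str], list[float]] = {
        (m, p): [] for m in markers for p in ("beginning", "mid", "late")
    }
    labels = ("beginning", "mid", "late")
    for pid, df in qc_table.groupby("participant_id", sort=True):
        df = df.sort_values("timestamp")
        dates = pd.to_datetime(df["timestamp"]).dt.date
        first = dates.min() + dt.timedelta(days=learning_days)
        post = df[np.array([d >= first for d in dates])]
        if post.empty:
            continue
        pdates = np.array(pd.to_datetime(post["timestamp"]).dt.date)
        t0, t1 = pdates.min(), pdates.max()
        span = max((t1 - t0).days + 1, 1)
        tert = np.minimum(np.array([(d - t0).days for d in pdates]) * 3 // span, 2)
        for k, lab in enumerate(labels):
            block = post[tert == k]
            if block.empty:
                continue
            for m in markers:
                v = block[_COLS[m]].dropna()
                if len(v):
                    period_accum[(m, lab)].append(float(v.mean()))
    period_rows = []
    for m in markers:
        rec: dict[str, object] = {"marker": m}
        for lab in labels:
            vals = period_accum[(m, lab)]
            rec[f"{lab}_mean"] = float(np.mean(vals)) if vals else float("nan")
            rec[f"{lab}_n"] = len(vals)
        period_rows.append(rec)

    return {"diurnal": pd.DataFrame(diurnal_rows), "period": pd.DataFrame(period_rows)}
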