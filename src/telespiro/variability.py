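"""Short-term and long-term variability of session-level lung function.

Short-term variability is summarised by the changes (deltas) between
consecutive recorded sessions — either all sessions (ALL stream) or restricted
to morning-to-morning (AM) / evening-to-evening (PM) pairs — expressed in mL
and in percent of the participant's predicted value. The habitual-variability
envelope is the 2-SD range (mean ± 2·sample SD of deltas) and the full shape
is shown as per-participant Gaussian-kernel densities with a cross-participant
average curve. Long-term variability is tracked as weekly means, and home vs
lab agreement as monthly home/baseline ratios stratified by AM/PM.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .models import DeltaSeries, Marker, Participant, WeeklySummary

STREAMS = ("ALL", "AM", "PM")
_MARKER_COL = {Marker.FEV1: "session_fev1_l", Marker.IC: "session_ic_l"}


def _predicted_map(participants: Iterable[Participant], marker: Marker) -> dict[str, float]:
    attr = "predicted_fev1" if marker is Marker.FEV1 else "predicted_ic"
    return {p.participant_id: getattr(p, attr) for p in participants}


def _baseline_map(participants: Iterable[Participant], marker: Marker) -> dict[str, float]:
    attr = "baseline_fev1" if marker is Marker.FEV1 else "baseline_ic"
    return {p.participant_id: getattr(p, attr) for p in participants}


def compute_deltas(
    qc_table: pd.DataFrame,
    participant_id: str,
    marker: Marker,
    stream: str = "ALL",
    predicted: Optional[float] = None,
    max_gap_days: Optional[int] = None,
) -> DeltaSeries:
    """Changes between consecutive recorded sessions of one participant/stream.

    Sessions with a missing marker value are skipped, so the nearest recorded
    neighbours are paired. ``max_gap_days`` optionally drops pairs spanning a
    longer calendar gap (breaks, maintenance). ``predicted`` (L) converts
    deltas to percent-of-predicted; when omitted the percent series is NaN.
    """
    if stream not in STREAMS:
        raise ValueError(f"stream must be one of {STREAMS}")
    col = _MARKER_COL[marker]
    df = qc_table[qc_table["participant_id"] == participant_id]
    if stream != "ALL":
        df = df[df["half"] == stream]
    df = df.dropna(subset=[col]).sort_values("timestamp")

    values = df[col].to_numpy(dtype=float)
    dates = [pd.Timestamp(t).date() for t in df["timestamp"]]
    deltas_ml, deltas_pct, pairs = [], [], []
    for i in range(1, len(values)):
        gap = (dates[i] - dates[i - 1]).days
        if max_gap_days is not None and gap > max_gap_days:
            continue
        d_l = values[i] - values[i - 1]
        deltas_ml.append(d_l * 1000.0)
        deltas_pct.append(d_l / predicted * 100.0 if predicted else float("nan"))
        pairs.append((dates[i - 1], dates[i]))
    return DeltaSeries(
        participant_id=participant_id,
        marker=marker,
        stream=stream,
        deltas_ml=tuple(deltas_ml),
        deltas_pctpred=tuple(deltas_pct),
        paired_dates=tuple(pairs),
    )


def cohort_delta_series(
    qc_table: pd.DataFrame,
    participants: Sequence[Participant],
    marker: Marker,
    stream: str,
    max_gap_days: Optional[int] = None,
) -> list[DeltaSeries]:
    pred = _predicted_map(participants, marker)
    return [
        compute_deltas(qc_table, p.participant_id, marker, stream, pred[p.participant_id], max_gap_days)
        for p in participants
    ]


def two_sd_range(
    series: DeltaSeries | Sequence[DeltaSeries],
    pooled: bool = True,
    units: str = "ml",
) -> Optional[tuple[float, float]]:
    """Mean ± 2·sample SD of the deltas — the habitual-variability envelope.

    With a list of per-participant series and ``pooled=True`` the raw deltas
    are pooled before taking mean and SD; with ``pooled=False`` the
    per-participant SDs are averaged around the pooled mean. Returns None with
    fewer than two deltas.
    """
    if isinstance(series, DeltaSeries):
        series = [series]
    key = "deltas_ml" if units == "ml" else "deltas_pctpred"
    arrays = [np.asarray(getattr(s, key), dtype=float) for s in series]
    arrays = [a[~np.isnan(a)] for a in arrays]
    allv = np.concatenate(arrays) if arrays else np.array([])
    if len(allv) < 2:
        return None
    mean = allv.mean()
    if pooled:
        sd = allv.std(ddof=1)
    else:
        sds = [a.std(ddof=1) for a in arrays if len(a) >= 2]
        if not sds:
            return None
        sd = float(np.mean(sds))
    return float(mean - 2 * sd), float(mean + 2 * sd)


@dataclass(frozen=True)
class DensityCurve:
    """A kernel-density estimate of the delta distribution on a fixed grid."""

    participant_id: str  # "" for the cross-participant average curve
    grid: np.ndarray
    heights: np.ndarray
    degenerate: bool = False  # all deltas identical: a point mass, not a KDE

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.heights, self.grid))


def delta_density(
    series_list: Sequence[DeltaSeries],
    units: str = "ml",
    grid: Optional[np.ndarray] = None,
    n_grid: int = 512,
    min_deltas: int = 5,
) -> tuple[list[DensityCurve], Optional[DensityCurve]]:
    """Per-participant relative-density curves plus their average.

    Each participant's deltas are smoothed with a Gaussian kernel (Silverman's
    bandwidth rule) and normalized on a shared grid before averaging, so every
    participant contributes equally to the mean curve regardless of session
    count. Participants with fewer than ``min_deltas`` deltas are skipped; a
    zero-variance series yields a flagged point-mass spike instead of a KDE.
    """
    key = "deltas_ml" if units == "ml" else "deltas_pctpred"
    data = []
    for s in series_list:
        a = np.asarray(getattr(s, key), dtype=float)
        a = a[~np.isnan(a)]
        if len(a) >= min_deltas:
            data.append((s.participant_id, a))
    if not data:
        return [], None

    if grid is None:
        allv = np.concatenate([a for _, a in data])
        lo, hi = allv.min(), allv.max()
        pad = 0.25 * max(hi - lo, 1.0)
        grid = np.linspace(lo - pad, hi + pad, n_grid)

    curves: list[DensityCurve] = []
    for pid, a in data:
        if np.ptp(a) == 0:
            heights = np.zeros_like(grid)
            idx = int(np.argmin(np.abs(grid - a[0])))
            # unit-integral triangular spike at the point mass
            step = grid[1] - grid[0] if len(grid) > 1 else 1.0
            heights[idx] = 1.0 / step
            curves.append(DensityCurve(pid, grid, heights, degenerate=True))
            continue
        kde = gaussian_kde(a, bw_method="silverman")
        heights = kde(grid)
        integral = np.trapezoid(heights, grid)
        curves.append(DensityCurve(pid, grid, heights / integral))

    mean_heights = np.mean([c.heights for c in curves], axis=0)
    mean_curve = DensityCurve("", grid, mean_heights, degenerate=any(c.degenerate for c in curves))
    return curves, mean_curve


def weekly_means(
    qc_table: pd.DataFrame,
    participants: Sequence[Participant],
    learning_days: int = 14,
) -> list[WeeklySummary]:
    """Weekly means of FEV1 %pred, IC %pred, SpO2 and CAT per participant.

    Weeks are consecutive 7-day blocks starting at the participant's first
    post-learning session; empty weeks inside the span are emitted with
    ``n_sessions = 0`` and missing means.
    """
    pred_fev1 = _predicted_map(participants, Marker.FEV1)
    pred_ic = _predicted_map(participants, Marker.IC)
    out: list[WeeklySummary] = []
    for pid, df in qc_table.groupby("participant_id", sort=True):
        df = df.sort_values("timestamp")
        dates = pd.to_datetime(df["timestamp"]).dt.date
        first = dates.min() + dt.timedelta(days=learning_days)
        post = df[np.array([d >= first for d in dates])]
        if post.empty:
            continue
        pdates = pd.to_datetime(post["timestamp"]).dt.date
        anchor = pdates.min()
        widx = np.array([(d - anchor).days // 7 + 1 for d in pdates])
        for w in range(1, widx.max() + 1):
            block = post[widx == w]
            if block.empty:
                out.append(WeeklySummary(pid, w, None, None, None, None, 0))
                continue

            def _mean(col, scale=1.0):
                v = block[col].dropna()
                return float(v.mean() * scale) if len(v) else None

            fev1 = block["session_fev1_l"].dropna()
            ic = block["session_ic_l"].dropna()
            out.append(
                WeeklySummary(
                    participant_id=pid,
                    week_index=w,
                    mean_fev1_pctpred=float(fev1.mean() / pred_fev1[pid] * 100) if len(fev1) else None,
                    mean_ic_pctpred=float(ic.mean() / pred_ic[pid] * 100) if len(ic) else None,
                    mean_spo2=_mean("spo2"),
                    mean_cat=_mean("cat"),
                    n_sessions=len(block),
                )
            )
    return out


def weekly_means_table(
    qc_table: pd.DataFrame, participants: Sequence[Participant], learning_days: int = 14
) -> pd.DataFrame:
    rows = [
        {
            "participant_id": w.participant_id,
            "week_index": w.week_index,
            "mean_fev1_pctpred": w.mean_fev1_pctpred,
            "mean_ic_pctpred": w.mean_ic_pctpred,
            "mean_spo2": w.mean_spo2,
            "mean_cat": w.mean_cat,
            "n_sessions": w.n_sessions,
        }
        for w in weekly_means(qc_table, participants, learning_days)
    ]
    return pd.DataFrame(rows)


MONTH_DAYS = 28  # analysis month: four scheduled weeks


def monthly_home_vs_baseline(
    qc_table: pd.DataFrame,
    participants: Sequence[Participant],
    learning_days: int = 14,
) -> pd.DataFrame:
    """Home/baseline ratios for the first and last month, AM and PM separately.

    A month is a 28-day block counted from the first post-learning session;
    ``first`` is block 1 and ``last`` the final complete block. The ratio is
    the mean of the block's session values divided by the supervised baseline
    value. Rows with no complete block are NaN.
    """
    rows = []
    base = {m: _baseline_map(participants, m) for m in Marker}
    for p in participants:
        pid = p.participant_id
        df = qc_table[qc_table["participant_id"] == pid].sort_values("timestamp")
        rec: dict[str, object] = {"participant_id": pid}
        if df.empty:
            rows.append(rec)
            continue
        dates = pd.to_datetime(df["timestamp"]).dt.date
        first_date = dates.min() + dt.timedelta(days=learning_days)
        post = df[np.array([d >= first_date for d in dates])]
        if post.empty:
            rows.append(rec)
            continue
        pdates = np.array(pd.to_datetime(post["timestamp"]).dt.date)
        anchor = pdates.min()
        offs = np.array([(d - anchor).days for d in pdates])
        span = offs.max() + 1
        n_complete = span // MONTH_DAYS
        block_idx = offs // MONTH_DAYS + 1
        for which, blk in (("first", 1 if n_complete else 0), ("last", n_complete)):
            sel = post[block_idx == blk] if blk >= 1 else post.iloc[0:0]
            for marker, col in _MARKER_COL.items():
                for half in ("AM", "PM"):
                    vals = sel[sel["half"] == half][col].dropna()
                    key = f"{marker.value.lower()}_{which}_{half.lower()}"
                    if blk >= 1 and len(vals):
                        rec[key] = float(vals.mean() / base[marker][pid])
                    else:
                        rec[key] = float("nan")
        rows.append(rec)
    return pd.DataFrame(rows)
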