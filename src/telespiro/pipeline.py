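"""End-to-end analysis pipeline.

Runs the stages in protocol order — QC, adherence, variability, event
detection, association — over either a session CSV or a freshly simulated
cohort, writing every stage's table as CSV, a JSON metrics summary, plots,
and a log of the seeds, thresholds and conventions used.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import adherence as adherence_mod
from . import association, events, io, qc, variability
from .models import CohortSpec, Marker, Participant, Session, StudyCalendar

log = logging.getLogger("telespiro")


def build_calendars(
    participants: list[Participant],
    sessions: list[Session],
    learning_days: int,
    scheduled_per_week: int = 6,
    exclusion_windows: Optional[list[tuple[dt.date, dt.date]]] = None,
    study_end: Optional[dt.date] = None,
) -> list[StudyCalendar]:
    """One calendar per participant, anchored at their first recorded session."""
    cals = []
    for p in participants:
        own = [s for s in sessions if s.participant_id == p.participant_id]
        if not own:
            continue
        first = min(s.date for s in own)
        cals.append(
            StudyCalendar(
                participant_id=p.participant_id,
                first_session_date=first,
                learning_days=learning_days,
                exclusion_windows=list(exclusion_windows or []),
                scheduled_per_week=scheduled_per_week,
                study_end_date=study_end,
            )
        )
    return cals


def run_pipeline(
    config: dict,
    outdir: Union[str, Path],
    participants: Optional[list[Participant]] = None,
    sessions: Optional[list[Session]] = None,
    make_plots: bool = True,
) -> dict:
    """Execute qc -> adherence -> variability -> events -> association.

    Inputs come from ``participants``/``sessions`` if given, else from the
    config's CSV paths, else (with ``simulate = true``) from the synthetic
    generator. Returns the JSON-ready metrics summary that is also written to
    ``metrics.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir, participants, sessions, make_plots)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config, outdir, participants, sessions, make_plots) -> dict:
    from .synthetic import generate_cohort

    if sessions is None or participants is None:
        if config.get("simulate"):
            spec = CohortSpec(
                n_participants=config["n_participants"],
                study_days=config["study_days"],
                adherence_prob=config["adherence_prob"],
                seed=config["seed"],
            )
            participants, sessions = generate_cohort(spec)
            io.write_sessions(sessions, outdir / "sessions.csv")
            io.write_participants(participants, outdir / "participants.csv")
            log.info("simulated cohort: %d participants, seed=%d", len(participants), spec.seed)
        else:
            if not config.get("sessions_csv") or not config.get("participants_csv"):
                raise ValueError("config must name sessions_csv and participants_csv, or set simulate = true")
            sessions = io.read_sessions(config["sessions_csv"], ampm_cutoff_hour=config["ampm_cutoff_hour"])
            participants = io.read_participants(config["participants_csv"])

    learning_days = config["learning_days"]
    step_thr = config["step_threshold_ml"]
    total_thr = config["total_threshold_ml"]
    max_gap = config["max_gap_days"] or None
    metrics: dict[str, object] = {
        "conventions": {
            "sd": "sample (n-1)",
            "quantiles": "linear interpolation",
            "repeatability": "strict < for acceptability, <= for buckets",
            "learning_days": learning_days,
            "step_threshold_ml": step_thr,
            "total_threshold_ml": total_thr,
            "event_mode": config["event_mode"],
            "seed": config.get("seed"),
        }
    }

    # --- stage 1: QC --------------------------------------------------------
    try:
        qc_table = qc.summarize_sessions(sessions)
        if qc_table.empty:
            raise ValueError("no sessions to analyse")
        qc_table.to_csv(outdir / "session_qc.csv", index=False)
        report = qc.qc_report(qc_table)
        report.to_csv(outdir / "qc_report.csv", index=False)
        metrics["qc"] = {r["metric"]: r["value"] for _, r in report.iterrows()}
    except Exception as exc:
        raise RuntimeError(f"stage qc failed: {exc}") from exc

    # --- stage 2: adherence -------------------------------------------------
    try:
        windows = io.parse_exclusion_windows(config.get("exclusion_windows", ""))
        end = None
        if config.get("simulate"):
            end = min(s.date for s in sessions) + dt.timedelta(days=config["study_days"] - 1)
        calendars = build_calendars(participants, sessions, learning_days, 6, windows, end)
        adh_table, pooled = adherence_mod.cohort_adherence(sessions, calendars)
        adh_table.to_csv(outdir / "adherence.csv", index=False)
        metrics["adherence"] = {
            "pooled": pooled,
            "per_participant_mean": float(adh_table["adherence"].dropna().mean())
            if adh_table["adherence"].notna().any()
            else None,
        }
    except Exception as exc:
        raise RuntimeError(f"stage adherence failed: {exc}") from exc

    # --- stage 3: variability ----------------------------------------------
    try:
        delta_rows = []
        ranges = {}
        for marker in Marker:
            for stream in variability.STREAMS:
                series = variability.cohort_delta_series(qc_table, participants, marker, stream, max_gap)
                for s in series:
                    for d_ml, d_pct, (d0, d1) in zip(s.deltas_ml, s.deltas_pctpred, s.paired_dates):
                        delta_rows.append(
                            {
                                "participant_id": s.participant_id,
                                "marker": marker.value,
                                "stream": stream,
                                "delta_ml": d_ml,
                                "delta_pctpred": d_pct,
                                "from_date": d0,
                                "to_date": d1,
                            }
                        )
                rng2 = variability.two_sd_range(series, pooled=True)
                ranges[f"{marker.value.lower()}_{stream.lower()}"] = rng2
                if stream in ("AM", "PM"):
                    curves, mean_curve = variability.delta_density(series)
                    if mean_curve is not None:
                        dens = pd.DataFrame(
                            {"grid_ml": mean_curve.grid, "mean_density": mean_curve.heights}
                        )
                        for c in curves:
                            dens[c.participant_id] = c.heights
                        dens.to_csv(outdir / f"density_{marker.value.lower()}_{stream.lower()}.csv", index=False)
        pd.DataFrame(delta_rows).to_csv(outdir / "deltas.csv", index=False)
        metrics["two_sd_ranges_ml"] = {
            k: (None if v is None else {"low": v[0], "high": v[1]}) for k, v in ranges.items()
        }
        weekly = variability.weekly_means_table(qc_table, participants, learning_days)
        weekly.to_csv(outdir / "weekly_means.csv", index=False)
        monthly = variability.monthly_home_vs_baseline(qc_table, participants, learning_days)
        monthly.to_csv(outdir / "monthly_ratios.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage variability failed: {exc}") from exc

    # --- stage 4: events ----------------------------------------------------
    try:
        all_periods = []
        metrics["events"] = {}
        for marker in Marker:
            periods = events.detect_cohort_periods(
                qc_table,
                marker,
                mode=config["event_mode"],
                step_threshold=step_thr,
                total_threshold=total_thr,
                learning_days=learning_days,
                extend_through_unchanged=config["extend_through_unchanged"],
            )
            all_periods.extend(periods)
            metrics["events"][marker.value.lower()] = events.period_summary(periods)
        events.periods_table(all_periods).to_csv(outdir / "decrease_periods.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage events failed: {exc}") from exc

    # --- stage 5: association ----------------------------------------------
    try:
        corr = association.correlation_table(qc_table)
        corr.to_csv(outdir / "correlations.csv", index=False)
        summary = association.correlation_summary(corr, config["strength_threshold"])
        summary.to_csv(outdir / "correlation_summary.csv", index=False)
        metrics["correlations"] = {
            r["pair"]: {"median": r["median"], "iqr": r["iqr"], "n_ge_threshold": int(r["n_ge_threshold"])}
            for _, r in summary.iterrows()
        }
        contrasts = association.group_contrasts(qc_table, learning_days)
        contrasts["diurnal"].to_csv(outdir / "diurnal_contrasts.csv", index=False)
        contrasts["period"].to_csv(outdir / "period_contrasts.csv", index=False)
        metrics["diurnal_pm_minus_am"] = {
            r["marker"]: r["mean_pm_minus_am"] for _, r in contrasts["diurnal"].iterrows()
        }
    except Exception as exc:
        raise RuntimeError(f"stage association failed: {exc}") from exc

    if make_plots:
        try:
            _plots(outdir, weekly, qc_table, participants)
        except Exception as exc:  # plotting must never sink the analysis
            log.warning("plotting failed: %s", exc)

    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, default=_jsonable)
    log.info("pipeline complete; outputs in %s", outdir)
    return metrics


def _jsonable(obj):
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _plots(outdir: Path, weekly: pd.DataFrame, qc_table: pd.DataFrame, participants) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .models import Marker
    from .variability import cohort_delta_series, delta_density

    # weekly means distribution per week
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    panels = [
        ("mean_fev1_pctpred", "FEV1 (% predicted)"),
        ("mean_ic_pctpred", "IC (% predicted)"),
        ("mean_spo2", "SpO2 (%)"),
        ("mean_cat", "CAT"),
    ]
    for ax, (col, label) in zip(axes.ravel(), panels):
        data = [
            g[col].dropna().to_numpy()
            for _, g in weekly.groupby("week_index")
        ]
        weeks = sorted(weekly["week_index"].unique())
        data = [d for d in data if True]
        ax.boxplot(data, positions=weeks, widths=0.6)
        ax.set_title(label)
        ax.set_xlabel("week")
    fig.tight_layout()
    fig.savefig(outdir / "weekly_means.png", dpi=120)
    plt.close(fig)

    # density curves per marker/stream
    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    for row, marker in enumerate(Marker):
        for colidx, stream in enumerate(("AM", "PM")):
            ax = axes[row][colidx]
            series = cohort_delta_series(qc_table, participants, marker, stream)
            curves, mean_curve = delta_density(series)
            for c in curves:
                ax.plot(c.grid, c.heights, color="grey", lw=0.7, alpha=0.7)
            if mean_curve is not None:
                ax.plot(mean_curve.grid, mean_curve.heights, color="red", lw=2)
            ax.set_title(f"Δ{marker.value} ({stream})")
            ax.set_xlabel("change between measurements (mL)")
    fig.tight_layout()
    fig.savefig(outdir / "delta_density.png", dpi=120)
    plt.close(fig)
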