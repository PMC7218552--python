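"""Delta series, 2-SD ranges, relative-density curves, weekly/monthly means."""

import datetime as dt

import numpy as np
import pytest
from scipy.signal import argrelmax

from telespiro.models import DeltaSeries, Half, Marker
from telespiro.qc import summarize_sessions
from telespiro.synthetic import generate_cohort
from telespiro.variability import (
    cohort_delta_series,
    compute_deltas,
    delta_density,
    monthly_home_vs_baseline,
    two_sd_range,
    weekly_means,
)

from conftest import make_session, zero_noise_spec


def sessions_with_fev1(values, half=Half.AM, pid="P01", step_days=2):
    """One session per value, every other day, all efforts identical."""
    out = []
    for i, v in enumerate(values):
        if v is None:
            continue
        out.append(make_session(pid=pid, day=i * step_days, half=half, fev1=(v, v, v)))
    return out


def series_of(deltas_ml, pid="P01", stream="AM"):
    d0 = dt.date(2014, 1, 6)
    dates = tuple((d0 + dt.timedelta(days=2 * i), d0 + dt.timedelta(days=2 * i + 2)) for i in range(len(deltas_ml)))
    return DeltaSeries(pid, Marker.FEV1, stream, tuple(deltas_ml), tuple(float("nan") for _ in deltas_ml), dates)


class TestComputeDeltas:
    def test_arithmetic_in_ml_and_pctpred(self):
        qt = summarize_sessions(sessions_with_fev1([1.50, 1.44, 1.50]))
        s = compute_deltas(qt, "P01", Marker.FEV1, "AM", predicted=3.0)
        assert list(s.deltas_ml) == pytest.approx([-60.0, 60.0], abs=1e-9)
        assert list(s.deltas_pctpred) == pytest.approx([-2.0, 2.0], abs=1e-9)

    def test_zero_noise_cohort_all_zero(self, zero_noise_cohort):
        participants, sessions = zero_noise_cohort
        qt = summarize_sessions(sessions)
        for stream in ("ALL", "AM", "PM"):
            for s in cohort_delta_series(qt, participants, Marker.FEV1, stream):
                assert all(d == pytest.approx(0.0, abs=1e-9) for d in s.deltas_ml)

    def test_missing_middle_session_pairs_neighbours(self):
        qt = summarize_sessions(sessions_with_fev1([1.5, None, 1.4]))
        s = compute_deltas(qt, "P01", Marker.FEV1, "AM")
        assert list(s.deltas_ml) == pytest.approx([-100.0], abs=1e-9)

    def test_max_gap_excludes_pairs_across_breaks(self):
        qt = summarize_sessions(sessions_with_fev1([1.5, None, 1.4]))
        s = compute_deltas(qt, "P01", Marker.FEV1, "AM", max_gap_days=3)
        assert len(s) == 0

    def test_too_few_sessions_empty(self):
        qt = summarize_sessions(sessions_with_fev1([1.5]))
        assert len(compute_deltas(qt, "P01", Marker.FEV1, "AM")) == 0

    def test_stream_accounting_identity(self, default_qc_table, default_cohort):
        # AM + PM delta counts never exceed the ALL count plus the number of
        # half alternations that break consecutive same-stream pairs
        _, participants, _ = default_cohort
        for p in participants[:4]:
            n = {
                s: len(compute_deltas(default_qc_table, p.participant_id, Marker.FEV1, s))
                for s in ("ALL", "AM", "PM")
            }
            halves = default_qc_table[
                default_qc_table["participant_id"] == p.participant_id
            ].sort_values("timestamp")["half"]
            alternations = int((halves != halves.shift()).iloc[1:].sum())
            assert n["AM"] + n["PM"] <= n["ALL"] + alternations


class TestTwoSdRange:
    def test_symmetric_case(self):
        assert two_sd_range(series_of([-100.0, 0.0, 100.0])) == pytest.approx((-200.0, 200.0))

    def test_zero_variance_collapses_to_point(self):
        assert two_sd_range(series_of([25.0, 25.0, 25.0])) == pytest.approx((25.0, 25.0))

    def test_insufficient_data_missing(self):
        assert two_sd_range(series_of([10.0])) is None

    def test_translation_equivariance(self):
        base = sessions_with_fev1([1.5, 1.4, 1.55, 1.45])
        shifted = sessions_with_fev1([1.8, 1.7, 1.85, 1.75])
        r1 = two_sd_range(compute_deltas(summarize_sessions(base), "P01", Marker.FEV1, "AM"))
        r2 = two_sd_range(compute_deltas(summarize_sessions(shifted), "P01", Marker.FEV1, "AM"))
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_per_participant_sd_averaging_mode(self):
        series = [series_of([-100.0, 0.0, 100.0], pid="P01"), series_of([-10.0, 0.0, 10.0], pid="P02")]
        lo_pooled, hi_pooled = two_sd_range(series, pooled=True)
        lo_avg, hi_avg = two_sd_range(series, pooled=False)
        assert hi_avg < hi_pooled  # averaging per-participant SDs shrinks the envelope


class TestDeltaDensity:
    def test_standard_normal_mode_height(self):
        rng = np.random.default_rng(4)
        series = [series_of(rng.standard_normal(2000), pid=f"P{i}") for i in range(3)]
        curves, mean_curve = delta_density(series)
        at_zero = np.interp(0.0, mean_curve.grid, mean_curve.heights)
        assert abs(at_zero - 0.3989) <= 0.04
        for c in curves:
            assert c.integral == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_series_flagged_spike(self):
        curves, mean_curve = delta_density([series_of([5.0] * 6)])
        assert curves[0].degenerate
        assert mean_curve.degenerate
        assert curves[0].integral == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_mixture_shows_two_peaks(self):
        rng = np.random.default_rng(8)
        deltas = np.concatenate([rng.normal(-200, 30, 400), rng.normal(200, 30, 400)])
        _, mean_curve = delta_density([series_of(deltas)])
        peaks = argrelmax(mean_curve.heights, order=5)[0]
        tall = [p for p in peaks if mean_curve.heights[p] > 0.3 * mean_curve.heights.max()]
        assert len(tall) == 2

    def test_too_few_deltas_skipped(self):
        curves, mean_curve = delta_density([series_of([1.0, 2.0])])
        assert curves == [] and mean_curve is None

    def test_every_emitted_curve_integrates_to_one(self, default_qc_table, default_cohort):
        _, participants, _ = default_cohort
        series = cohort_delta_series(default_qc_table, participants, Marker.IC, "PM")
        curves, mean_curve = delta_density(series)
        for c in curves + [mean_curve]:
            assert c.integral == pytest.approx(1.0, abs=1e-3)


class TestWeeklyMeans:
    def test_constant_cohort_constant_weeks(self, zero_noise_cohort):
        participants, sessions = zero_noise_cohort
        qt = summarize_sessions(sessions)
        pct = {p.participant_id: p.baseline_fev1 / p.predicted_fev1 * 100 for p in participants}
        for w in weekly_means(qt, participants):
            if w.n_sessions:
                assert w.mean_fev1_pctpred == pytest.approx(pct[w.participant_id])

    def test_six_sessions_at_half_predicted(self):
        sessions = [
            make_session(day=14 + d, half=h, fev1=(1.5, 1.5, 1.5))
            for d in (0, 2, 4)
            for h in (Half.AM, Half.PM)
        ]
        # learning anchor: include an early session so week 1 starts at day 14
        sessions = [make_session(day=0)] + sessions
        qt = summarize_sessions(sessions)
        from telespiro.models import Participant

        p = Participant("P01", "f", 1.0, 2.0, 3.0, 2.5, dt.date(2014, 1, 6))
        weeks = [w for w in weekly_means(qt, [p]) if w.week_index == 1]
        assert weeks[0].n_sessions == 6
        assert weeks[0].mean_fev1_pctpred == pytest.approx(50.0)

    def test_empty_weeks_emitted_with_zero_sessions(self):
        sessions = sessions_with_fev1([1.5, 1.5], step_days=15)
        from telespiro.models import Participant

        p = Participant("P01", "f", 1.0, 2.0, 3.0, 2.5, dt.date(2014, 1, 6))
        weeks = weekly_means(summarize_sessions(sessions), [p], learning_days=0)
        assert [w.n_sessions for w in weeks] == [1, 0, 1]
        assert weeks[1].mean_fev1_pctpred is None

    def test_injected_drop_moves_nadir_week(self):
        from telespiro.models import ExacerbationEvent

        spec = zero_noise_spec(
            n_participants=1,
            study_days=84,
            baseline_fev1=[1.2],
            exacerbations=[
                ExacerbationEvent(
                    participant_id="P01", onset_day=42, duration_days=14,
                    fev1_drop_frac=0.3, ic_drop_frac=0.0, cat_rise=0, ramp_days=0,
                )
            ],
        )
        participants, sessions = generate_cohort(spec)
        weeks = weekly_means(summarize_sessions(sessions), participants)
        by_idx = {w.week_index: w for w in weeks}
        pre = by_idx[2].mean_fev1_pctpred
        nadir = min(w.mean_fev1_pctpred for w in weeks if w.n_sessions)
        assert nadir == pytest.approx(0.7 * pre, rel=1e-6)


class TestMonthlyRatios:
    def test_constant_home_equals_baseline(self, zero_noise_cohort):
        participants, sessions = zero_noise_cohort
        qt = summarize_sessions(sessions)
        table = monthly_home_vs_baseline(qt, participants)
        for col in ("fev1_first_am", "fev1_first_pm", "ic_first_am", "ic_first_pm"):
            assert table[col].dropna().to_numpy() == pytest.approx(1.0)

    def test_uniform_deficit_recovered(self):
        from telespiro.models import Participant

        sessions = [
            make_session(day=d, half=h, fev1=(0.84, 0.84, 0.84))
            for d in range(0, 56, 2)
            for h in (Half.AM, Half.PM)
        ]
        p = Participant("P01", "f", 1.0, 2.0, 3.0, 2.5, dt.date(2014, 1, 6))
        table = monthly_home_vs_baseline(summarize_sessions(sessions), [p], learning_days=0)
        assert table["fev1_first_am"].iloc[0] == pytest.approx(0.84)
        assert table["fev1_last_pm"].iloc[0] == pytest.approx(0.84)

    def test_no_complete_block_missing(self):
        from telespiro.models import Participant

        sessions = sessions_with_fev1([1.5, 1.4])
        p = Participant("P01", "f", 1.0, 2.0, 3.0, 2.5, dt.date(2014, 1, 6))
        table = monthly_home_vs_baseline(summarize_sessions(sessions), [p], learning_days=0)
        assert np.isnan(table["fev1_last_am"].iloc[0])
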