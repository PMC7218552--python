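"""Generator contracts: schedule, determinism, noise calibration, injection."""

import datetime as dt

import numpy as np
import pydantic
import pytest

from telespiro.io import write_sessions
from telespiro.models import CohortSpec, ExacerbationEvent, Half, Marker
from telespiro.qc import summarize_sessions
from telespiro.synthetic import generate_cohort, inject_exacerbation, scheduled_sessions

from conftest import zero_noise_spec


def test_full_adherence_yields_exact_schedule():
    spec = zero_noise_spec(n_participants=2, study_days=28)
    _, sessions = generate_cohort(spec)
    per = {}
    for s in sessions:
        per[s.participant_id] = per.get(s.participant_id, 0) + 1
    assert per == {"P01": 24, "P02": 24}
    assert scheduled_sessions(spec) == 24


def test_sessions_time_ordered_with_bounded_efforts(default_cohort):
    _, _, sessions = default_cohort
    last = {}
    for s in sessions:
        if s.participant_id in last:
            assert s.timestamp > last[s.participant_id]
        last[s.participant_id] = s.timestamp
        for marker in Marker:
            n = len(s.efforts_of(marker))
            assert 1 <= n <= 5


def test_zero_noise_efforts_equal_baseline(zero_noise_cohort):
    participants, sessions = zero_noise_cohort
    baseline = {p.participant_id: p.baseline_fev1 for p in participants}
    for s in sessions:
        for e in s.efforts_of(Marker.FEV1):
            assert e.value == pytest.approx(baseline[s.participant_id], abs=1e-12)


def test_reproducible_given_seed(tmp_path):
    spec = CohortSpec(seed=42, n_participants=3, study_days=28)
    _, s1 = generate_cohort(spec)
    _, s2 = generate_cohort(spec)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_sessions(s1, p1)
    write_sessions(s2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    _, s3 = generate_cohort(CohortSpec(seed=43, n_participants=3, study_days=28))
    p3 = tmp_path / "c.csv"
    write_sessions(s3, p3)
    assert p1.read_bytes() != p3.read_bytes()


def test_adherence_probability_recovered_within_2pct():
    # ~10,000 scheduled sessions: 64 participants x 26 weeks x 6/week
    spec = zero_noise_spec(
        n_participants=64,
        study_days=182,
        adherence_prob=0.9,
        baseline_fev1=None,
        baseline_ic=None,
        predicted_fev1=None,
        predicted_ic=None,
        seed=11,
    )
    _, sessions = generate_cohort(spec)
    scheduled = scheduled_sessions(spec) * spec.n_participants
    assert scheduled >= 9000
    assert abs(len(sessions) / scheduled - 0.9) < 0.02


def test_am_am_delta_sd_matches_day_noise():
    # day-to-day SD 0.105 L -> AM-to-AM delta SD ~ 0.105*sqrt(2) = 0.148 L
    spec = zero_noise_spec(
        n_participants=10,
        study_days=182,
        day_sd_fev1=0.105,
        effort_sd_fev1=0.0,
        baseline_fev1=[1.5] * 10,
        baseline_ic=[2.0] * 10,
        predicted_fev1=[3.0] * 10,
        predicted_ic=[2.5] * 10,
        seed=5,
    )
    _, sessions = generate_cohort(spec)
    deltas = []
    for pid in {s.participant_id for s in sessions}:
        am = [s for s in sessions if s.participant_id == pid and s.half is Half.AM]
        vals = [s.efforts_of(Marker.FEV1)[0].value for s in am]
        deltas.extend(np.diff(vals))
    assert 0.135 <= np.std(deltas, ddof=1) <= 0.165


def test_two_sd_width_recovers_calibrated_day_noise():
    # calibrated so SD(delta) = day_sd*sqrt(2) = 105 mL -> 2-SD width ~ 420 mL
    from telespiro.variability import cohort_delta_series, two_sd_range

    day_sd = 0.105 / np.sqrt(2)
    spec = zero_noise_spec(
        n_participants=11,
        study_days=182,
        day_sd_fev1=day_sd,
        seed=3,
        baseline_fev1=[1.5] * 11,
        baseline_ic=[2.0] * 11,
        predicted_fev1=[3.0] * 11,
        predicted_ic=[2.5] * 11,
    )
    participants, sessions = generate_cohort(spec)
    qt = summarize_sessions(sessions)
    lo, hi = two_sd_range(cohort_delta_series(qt, participants, Marker.FEV1, "AM"), pooled=True)
    assert abs((hi - lo) - 420.0) <= 42.0


def test_cat_coupling_sign_recovered_per_participant():
    spec = zero_noise_spec(
        n_participants=10,
        study_days=182,
        day_sd_ic=0.1,
        cat_sd=2.0,
        ic_cat_coupling=-0.5,
        baseline_fev1=[1.5] * 10,
        baseline_ic=[2.0] * 10,
        predicted_fev1=[3.0] * 10,
        predicted_ic=[2.5] * 10,
        seed=9,
    )
    participants, sessions = generate_cohort(spec)
    qt = summarize_sessions(sessions)
    from telespiro.association import correlation_table

    table = correlation_table(qt)
    signs = np.sign(table["ic_vs_cat"].dropna())
    assert (signs < 0).sum() >= 9


def test_invalid_spec_names_field():
    with pytest.raises(pydantic.ValidationError, match="adherence_prob"):
        CohortSpec(adherence_prob=1.5)
    with pytest.raises(pydantic.ValidationError, match="baseline_fev1"):
        CohortSpec(n_participants=2, baseline_fev1=[1.0])
    with pytest.raises(pydantic.ValidationError, match="study_days"):
        CohortSpec(
            study_days=30,
            exacerbations=[
                ExacerbationEvent(
                    participant_id="P01", onset_day=20, duration_days=20,
                    fev1_drop_frac=0.2, ic_drop_frac=0.2, cat_rise=2, ramp_days=2,
                )
            ],
        )


class TestInjectExacerbation:
    def test_null_event_is_identity(self, zero_noise_cohort):
        _, sessions = zero_noise_cohort
        event = ExacerbationEvent(
            participant_id="P01", onset_day=14, duration_days=14,
            fev1_drop_frac=0.0, ic_drop_frac=0.0, cat_rise=0.0, ramp_days=0,
        )
        out = inject_exacerbation(sessions, event)
        for a, b in zip(sessions, out):
            assert [e.value for e in a.efforts] == [e.value for e in b.efforts]
            assert a.cat == b.cat

    def test_unramped_drop_is_exact(self):
        spec = zero_noise_spec(n_participants=1, study_days=42,
                               baseline_fev1=[1.2], baseline_ic=[2.0],
                               predicted_fev1=[2.4], predicted_ic=[2.5])
        _, sessions = generate_cohort(spec)
        event = ExacerbationEvent(
            participant_id="P01", onset_day=14, duration_days=14,
            fev1_drop_frac=0.3, ic_drop_frac=0.0, cat_rise=0.0, ramp_days=0,
        )
        out = inject_exacerbation(sessions, event, study_start=spec.start_date)
        for s in out:
            day = (s.date - spec.start_date).days
            expected = 1.2 * 0.7 if 14 <= day < 28 else 1.2
            for e in s.efforts_of(Marker.FEV1):
                assert e.value == pytest.approx(expected, abs=1e-12)

    def test_other_sessions_untouched(self, zero_noise_cohort):
        _, sessions = zero_noise_cohort
        event = ExacerbationEvent(
            participant_id="P02", onset_day=14, duration_days=14,
            fev1_drop_frac=0.3, ic_drop_frac=0.3, cat_rise=5, ramp_days=2,
        )
        out = inject_exacerbation(sessions, event)
        for a, b in zip(sessions, out):
            if a.participant_id != "P02":
                assert a is b

    def test_unknown_participant_rejected(self, zero_noise_cohort):
        _, sessions = zero_noise_cohort
        event = ExacerbationEvent(
            participant_id="P99", onset_day=0, duration_days=7,
            fev1_drop_frac=0.1, ic_drop_frac=0.1, cat_rise=1, ramp_days=0,
        )
        with pytest.raises(ValueError, match="P99"):
            inject_exacerbation(sessions, event)

    def test_ramped_drop_triggers_detector(self):
        from telespiro.events import detect_cohort_periods

        spec = zero_noise_spec(
            n_participants=1, study_days=84,
            baseline_fev1=[1.2], baseline_ic=[2.0],
            predicted_fev1=[2.4], predicted_ic=[2.5],
            exacerbations=[
                ExacerbationEvent(
                    participant_id="P01", onset_day=42, duration_days=21,
                    fev1_drop_frac=0.3, ic_drop_frac=0.3, cat_rise=5, ramp_days=6,
                )
            ],
        )
        _, sessions = generate_cohort(spec)
        qt = summarize_sessions(sessions)
        periods = detect_cohort_periods(qt, Marker.FEV1)
        onset = spec.start_date + dt.timedelta(days=42)
        end = spec.start_date + dt.timedelta(days=63)
        assert any(p.start_date <= end and p.end_date >= onset for p in periods)
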