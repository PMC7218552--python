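import datetime as dt

import pytest

from telespiro.models import CohortSpec, Effort, Half, Marker, Session
from telespiro.qc import summarize_sessions
from telespiro.synthetic import generate_cohort


def make_efforts(marker: Marker, values, valid=None) -> list[Effort]:
    valid = valid or [True] * len(values)
    return [
        Effort(test_type=marker, value=v, valid=ok, order=i)
        for i, (v, ok) in enumerate(zip(values, valid))
    ]


def make_session(
    pid="P01",
    day=0,
    half=Half.AM,
    fev1=(1.0, 1.0, 1.0),
    ic=(2.0, 2.0, 2.0),
    cat=None,
    spo2=None,
    hr=None,
    start=dt.date(2014, 1, 6),
) -> Session:
    ts = dt.datetime.combine(start + dt.timedelta(days=day), dt.time(8 if half is Half.AM else 19, 0))
    efforts = make_efforts(Marker.FEV1, fev1) + make_efforts(Marker.IC, ic)
    return Session(
        participant_id=pid, timestamp=ts, half=half, efforts=efforts, cat=cat, spo2=spo2, heart_rate=hr
    )


def zero_noise_spec(**overrides) -> CohortSpec:
    """A fully deterministic cohort: every effort equals the baseline."""
    base = dict(
        n_participants=3,
        study_days=56,
        adherence_prob=1.0,
        effort_sd_fev1=0.0,
        effort_sd_ic=0.0,
        day_sd_fev1=0.0,
        day_sd_ic=0.0,
        diurnal_offset_fev1=0.0,
        diurnal_offset_ic=0.0,
        drift_sd=0.0,
        p_invalid_effort=0.0,
        cat_sd=0.0,
        ic_cat_coupling=0.0,
        spo2_sd=0.0,
        heart_rate_sd=0.0,
        baseline_fev1=[1.2, 1.0, 1.5],
        baseline_ic=[2.0, 1.8, 2.4],
        predicted_fev1=[2.4, 2.5, 3.0],
        predicted_ic=[2.5, 2.4, 3.0],
        seed=0,
    )
    base.update(overrides)
    n = base["n_participants"]
    for key in ("baseline_fev1", "baseline_ic", "predicted_fev1", "predicted_ic"):
        vals = base[key]
        if vals is not None and len(vals) != n:
            base[key] = [vals[i % len(vals)] for i in range(n)]
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return generate_cohort(zero_noise_spec())


@pytest.fixture(scope="session")
def default_cohort():
    """The study-condition cohort: 11 participants, 26 weeks, ~90% adherence."""
    spec = CohortSpec(seed=7)
    participants, sessions = generate_cohort(spec)
    return spec, participants, sessions


@pytest.fixture(scope="session")
def default_qc_table(default_cohort):
    _, _, sessions = default_cohort
    return summarize_sessions(sessions)
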