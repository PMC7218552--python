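"""Canonical file formats and configuration.

Sessions are exchanged as a long-format CSV with one row per spirometry
effort; session-level fields (half, CAT, SpO2, heart rate) are repeated on
every row of the session. Participant metadata travels in a separate CSV.
Configuration is a flat ``key = value`` text file validated against a schema
whose defaults are the analysis conventions (50 mL step threshold, 100 mL
total threshold, 150/100 mL repeatability, 5/8/10% CV, 14-day learning phase,
12:00 AM/PM cutoff).
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .models import Effort, Half, Marker, Participant, Session

log = logging.getLogger("telespiro")

SESSION_COLUMNS = [
    "participant_id",
    "timestamp",
    "half",
    "test_type",
    "effort_index",
    "volume_l",
    "valid",
    "cat",
    "spo2",
    "heart_rate",
]

AMPM_CUTOFF_HOUR = 12


class SchemaError(ValueError):
    """Input rows violate the session-record schema."""


def write_sessions(sessions: Iterable[Session], path: Union[str, Path]) -> None:
    """Write sessions as the canonical long-format effort-level CSV."""
    rows = []
    for s in sessions:
        for e in sorted(s.efforts, key=lambda e: (e.test_type.value, e.order)):
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "timestamp": s.timestamp.isoformat(),
                    "half": s.half.value,
                    "test_type": e.test_type.value,
                    "effort_index": e.order,
                    "volume_l": f"{e.value:.4f}",
                    "valid": int(e.valid),
                    "cat": "" if s.cat is None else s.cat,
                    "spo2": "" if s.spo2 is None else s.spo2,
                    "heart_rate": "" if s.heart_rate is None else s.heart_rate,
                }
            )
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def read_sessions(
    path: Union[str, Path],
    strict: bool = True,
    ampm_cutoff_hour: int = AMPM_CUTOFF_HOUR,
) -> list[Session]:
    """Read the canonical session CSV back into Session objects.

    In strict mode any malformed row (schema violation, out-of-range CAT or
    SpO2, half inconsistent with the timestamp under the AM/PM cutoff) raises
    :class:`SchemaError` naming the offending line numbers and columns; in
    lenient mode offending sessions are dropped with a warning. An empty file
    yields an empty cohort with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty session file, returning empty cohort")
        return []
    if df.empty:
        warnings.warn(f"{path}: no session rows, returning empty cohort")
        return []

    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    problems: list[str] = []  # "line N: message"
    bad_sessions: set[tuple[str, str]] = set()

    def flag(idx: int, key: tuple[str, str], msg: str) -> None:
        problems.append(f"line {idx + 2}: {msg}")  # +2: header + 0-base
        bad_sessions.add(key)

    sessions: dict[tuple[str, str], Session] = {}
    for idx, row in df.iterrows():
        key = (str(row["participant_id"]), str(row["timestamp"]))
        try:
            ts = dt.datetime.fromisoformat(str(row["timestamp"]))
        except ValueError:
            flag(idx, key, f"unparseable timestamp {row['timestamp']!r} [timestamp]")
            continue
        half_str = str(row["half"])
        if half_str not in ("AM", "PM"):
            flag(idx, key, f"half must be AM or PM, got {half_str!r} [half]")
            continue
        expected = "AM" if ts.hour < ampm_cutoff_hour else "PM"
        if half_str != expected:
            flag(idx, key, f"half {half_str} inconsistent with timestamp hour {ts.hour} [half]")
            continue
        try:
            marker = Marker(str(row["test_type"]))
        except ValueError:
            flag(idx, key, f"unknown test_type {row['test_type']!r} [test_type]")
            continue

        cat = None if pd.isna(row["cat"]) else int(row["cat"])
        spo2 = None if pd.isna(row["spo2"]) else float(row["spo2"])
        hr = None if pd.isna(row["heart_rate"]) else float(row["heart_rate"])
        if cat is not None and not (0 <= cat <= 40):
            flag(idx, key, f"cat out of range [0, 40]: {cat} [cat]")
            continue
        if spo2 is not None and not (50 <= spo2 <= 100):
            flag(idx, key, f"spo2 out of range [50, 100]: {spo2} [spo2]")
            continue

        try:
            effort = Effort(
                test_type=marker,
                value=float(row["volume_l"]),
                valid=bool(int(row["valid"])),
                order=int(row["effort_index"]),
            )
        except (TypeError, ValueError) as exc:
            flag(idx, key, f"bad effort fields: {exc} [volume_l/valid/effort_index]")
            continue

        if key not in sessions:
            sessions[key] = Session(
                participant_id=key[0],
                timestamp=ts,
                half=Half(half_str),
                efforts=[],
                cat=cat,
                spo2=spo2,
                heart_rate=hr,
            )
        sessions[key].efforts.append(effort)

    if problems:
        if strict:
            raise SchemaError(f"{path}: {len(problems)} malformed rows:\n" + "\n".join(problems))
        warnings.warn(f"{path}: dropped {len(bad_sessions)} sessions with malformed rows")
        for key in bad_sessions:
            sessions.pop(key, None)

    out = sorted(sessions.values(), key=lambda s: (s.participant_id, s.timestamp))
    log.info("read %d sessions from %s", len(out), path)
    return out


def write_participants(participants: Iterable[Participant], path: Union[str, Path]) -> None:
    rows = [
        {
            "participant_id": p.participant_id,
            "sex": p.sex,
            "baseline_fev1": p.baseline_fev1,
            "baseline_ic": p.baseline_ic,
            "predicted_fev1": p.predicted_fev1,
            "predicted_ic": p.predicted_ic,
            "enrolment_date": p.enrolment_date.isoformat(),
        }
        for p in participants
    ]
    # %.17g guarantees doubles survive the text round-trip exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_participants(path: Union[str, Path]) -> list[Participant]:
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    return [
        Participant(
            participant_id=str(r["participant_id"]),
            sex=str(r["sex"]),
            baseline_fev1=float(r["baseline_fev1"]),
            baseline_ic=float(r["baseline_ic"]),
            predicted_fev1=float(r["predicted_fev1"]),
            predicted_ic=float(r["predicted_ic"]),
            enrolment_date=dt.date.fromisoformat(str(r["enrolment_date"])),
        )
        for _, r in df.iterrows()
    ]


# --- configuration -----------------------------------------------------------

CONFIG_SCHEMA: dict[str, tuple[type, object]] = {
    # analysis conventions
    "step_threshold_ml": (float, 50.0),
    "total_threshold_ml": (float, 100.0),
    "event_mode": (str, "per_step"),
    "extend_through_unchanged": (bool, False),
    "repeatability_l": (float, 0.150),
    "repeatability_strict_l": (float, 0.100),
    "learning_days": (int, 14),
    "ampm_cutoff_hour": (int, 12),
    "max_gap_days": (int, 0),  # 0 = no limit
    "strength_threshold": (float, 0.40),
    # inputs: either paths ...
    "sessions_csv": (str, ""),
    "participants_csv": (str, ""),
    # ... or a simulation
    "simulate": (bool, False),
    "seed": (int, 0),
    "n_participants": (int, 11),
    "study_days": (int, 182),
    "adherence_prob": (float, 0.906),
    # adherence exclusions: "YYYY-MM-DD:YYYY-MM-DD,..." applied to everyone
    "exclusion_windows": (str, ""),
}


def parse_config(path: Union[str, Path, None] = None, overrides: Optional[dict] = None) -> dict:
    """Parse a flat ``key = value`` config file against the schema.

    Unknown keys and unparsable values are errors. ``overrides`` (already
    typed) win over file values; omitted keys take their defaults.
    """
    values: dict[str, object] = {k: d for k, (_, d) in CONFIG_SCHEMA.items()}
    if path is not None:
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in CONFIG_SCHEMA:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = CONFIG_SCHEMA[key][0]
            try:
                if typ is bool:
                    if val.lower() not in ("true", "false", "1", "0", "yes", "no"):
                        raise ValueError(val)
                    values[key] = val.lower() in ("true", "1", "yes")
                else:
                    values[key] = typ(val)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse {val!r} as {typ.__name__} for {key!r}"
                ) from None
    if overrides:
        unknown = set(overrides) - set(CONFIG_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        values.update(overrides)
    return values


def parse_exclusion_windows(text: str) -> list[tuple[dt.date, dt.date]]:
    """Parse ``start:end,start:end`` (ISO dates, inclusive) into date pairs."""
    windows = []
    for chunk in filter(None, (c.strip() for c in text.split(","))):
        try:
            a, b = chunk.split(":")
            windows.append((dt.date.fromisoformat(a), dt.date.fromisoformat(b)))
        except ValueError:
            raise ValueError(f"bad exclusion window {chunk!r}; expected YYYY-MM-DD:YYYY-MM-DD") from None
    return windows
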