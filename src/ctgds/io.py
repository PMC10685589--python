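"""Cohort file formats, validation and run manifests.

A cohort on disk is two UTF-8 CSVs with header rows and dot decimals:

* ``births.csv`` — id, group, parity, caesarean, duration_min;
* ``events.csv`` — id, channel, state, start_s, dwell_s (run-length-encoded
  event streams, one row per run).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    FHR_STATES,
    GROUPS,
    PARITIES,
    TICKS_PER_S,
    UP_STATES,
    BirthRecord,
    EventStream,
)

BIRTH_COLUMNS = ["id", "group", "parity", "caesarean", "duration_min"]
EVENT_COLUMNS = ["id", "channel", "state", "start_s", "dwell_s"]


def births_frame(records: list[BirthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id, "group": r.group, "parity": r.parity,
                "caesarean": r.caesarean, "duration_min": r.duration_min,
            }
            for r in records
        ],
        columns=BIRTH_COLUMNS,
    )


def events_frame(records: list[BirthRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for channel, stream in (("fhr", r.fhr_stream), ("up", r.up_stream)):
            if stream is None:
                continue
            for state, start_s, dwell_s in stream.runs():
                rows.append(
                    {"id": r.id, "channel": channel, "state": state,
                     "start_s": start_s, "dwell_s": dwell_s}
                )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_cohort(records: list[BirthRecord], out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "births": out_dir / "births.csv",
        "events": out_dir / "events.csv",
    }
    births_frame(records).to_csv(paths["births"], index=False)
    events_frame(records).to_csv(paths["events"], index=False)
    return paths


def _stream_from_runs(channel: str, sub: pd.DataFrame) -> EventStream:
    labels = FHR_STATES if channel == "fhr" else UP_STATES
    code = {s: i for i, s in enumerate(labels)}
    sub = sub.sort_values("start_s")
    states = np.array([code[s] for s in sub["state"]], dtype=np.int8)
    dwells = np.round(sub["dwell_s"].to_numpy(dtype=float) * TICKS_PER_S).astype(np.int64)
    return EventStream(channel, states, dwells)


def read_cohort(cohort_dir: str | Path) -> list[BirthRecord]:
    cohort_dir = Path(cohort_dir)
    births = pd.read_csv(cohort_dir / "births.csv")
    missing = set(BIRTH_COLUMNS) - set(births.columns)
    if missing:
        raise ValueError(f"births.csv missing columns: {sorted(missing)}")
    events = pd.read_csv(cohort_dir / "events.csv")
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"events.csv missing columns: {sorted(missing)}")
    by_birth = dict(iter(events.groupby("id", sort=False)))
    records = []
    for _, row in births.iterrows():
        # durations live on a whole-second grid; snap to undo CSV parser ulps
        duration = round(float(row["duration_min"]) * 60) / 60.0
        rec = BirthRecord(
            id=row["id"], group=row["group"], parity=row["parity"],
            caesarean=bool(row["caesarean"]), duration_min=duration,
        )
        ev = by_birth.get(row["id"])
        if ev is not None:
            for channel in ("fhr", "up"):
                sub = ev[ev["channel"] == channel]
                if len(sub):
                    stream = _stream_from_runs(channel, sub)
                    if channel == "fhr":
                        rec.fhr_stream = stream
                    else:
                        rec.up_stream = stream
        records.append(rec)
    return records


def validate_cohort(records: list[BirthRecord]) -> list[str]:
    """Check event-stream and label invariants; returns issue strings."""
    issues = []
    for rec in records:
        if rec.group not in GROUPS:
            issues.append(f"{rec.id}: unknown group {rec.group!r}")
        if rec.parity not in PARITIES:
            issues.append(f"{rec.id}: unknown parity {rec.parity!r}")
        if rec.duration_min <= 0:
            issues.append(f"{rec.id}: non-positive duration")
        expected_ticks = int(round(rec.duration_min * 60 * TICKS_PER_S))
        for name, stream in (("fhr", rec.fhr_stream), ("up", rec.up_stream)):
            if stream is None:
                continue
            if np.any(stream.dwells <= 0):
                issues.append(f"{rec.id}/{name}: non-positive dwell")
            if np.any(stream.states[1:] == stream.states[:-1]):
                issues.append(f"{rec.id}/{name}: consecutive runs share a state")
            n_states = len(FHR_STATES) if name == "fhr" else len(UP_STATES)
            if len(stream.states) and (
                stream.states.min() < 0 or stream.states.max() >= n_states
            ):
                issues.append(f"{rec.id}/{name}: state code out of range")
            if stream.total_ticks != expected_ticks:
                issues.append(
                    f"{rec.id}/{name}: stream covers {stream.total_ticks} ticks, "
                    f"expected {expected_ticks}"
                )
    return issues


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, config_snapshot: dict, seeds: dict, outputs: list[Path]
) -> Path:
    """Record config, seeds and output digests for reproducibility."""
    manifest = {
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config": config_snapshot,
        "seeds": seeds,
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
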