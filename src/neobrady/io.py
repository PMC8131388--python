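"""Readers and writers for the package's CSV/JSON artifacts.

Conventions: comma-separated CSV with a mandatory header row, '.'
decimal separator, UTF-8, LF line endings.  JSON documents carry a
``schema_version`` field.  Every writer's output round-trips through
its reader.

Artifacts:

* RR series CSV — columns ``time_s,rr_ms``;
* beat-times CSV — single column ``time_s``;
* SpO2 CSV — columns ``time_s,spo2_pct``;
* alarm trace — CSV ``time_s,level`` plus a JSON detection list;
* event annotations — JSON list of ``{onset_s, offset_s, labels, ...}``;
* cohort — per record ``recNNN_rr.csv``, ``recNNN_spo2.csv``,
  ``recNNN_truth.json`` and a manifest JSON with config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortConfig, SyntheticRecord
from .detectors import AlarmTrace
from .events import BradycardiaEvent, ClinicalContext
from .series import BeatSeries, RRSeries

__all__ = [
    "read_rr_csv",
    "write_rr_csv",
    "read_beats_csv",
    "write_beats_csv",
    "write_spo2_csv",
    "read_spo2_csv",
    "write_alarm_trace",
    "read_detections_json",
    "write_detections_json",
    "events_to_json",
    "events_from_json",
    "write_events_json",
    "read_events_json",
    "write_cohort",
]

SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Malformed input file."""


def _read_csv(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    for c in columns:
        if len(df) and not np.issubdtype(df[c].dtype, np.number):
            bad = df[~pd.to_numeric(df[c], errors="coerce").notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{path}: non-numeric value in column {c!r} at line {line}")
    return df


def read_rr_csv(path) -> RRSeries:
    df = _read_csv(path, ["time_s", "rr_ms"])
    return RRSeries(beat_time=df["time_s"].to_numpy(float), rr=df["rr_ms"].to_numpy(float))


def write_rr_csv(series: RRSeries, path) -> None:
    pd.DataFrame({"time_s": series.beat_time, "rr_ms": series.rr}).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_beats_csv(path) -> BeatSeries:
    df = _read_csv(path, ["time_s"])
    return BeatSeries(times=df["time_s"].to_numpy(float))


def write_beats_csv(beats: BeatSeries, path) -> None:
    pd.DataFrame({"time_s": beats.times}).to_csv(path, index=False, lineterminator="\n")


def write_spo2_csv(time_s: np.ndarray, spo2: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": time_s, "spo2_pct": spo2}).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_spo2_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = _read_csv(path, ["time_s", "spo2_pct"])
    return df["time_s"].to_numpy(float), df["spo2_pct"].to_numpy(float)


def write_alarm_trace(trace: AlarmTrace, csv_path, json_path=None) -> None:
    pd.DataFrame({"time_s": trace.beat_time, "level": trace.level}).to_csv(
        csv_path, index=False, lineterminator="\n"
    )
    if json_path is not None:
        write_detections_json(list(trace.detections), json_path)


def write_detections_json(detections: list[float], path, meta: dict | None = None) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "detections_s": [float(d) for d in detections],
    }
    if meta:
        doc["meta"] = meta
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def read_detections_json(path) -> list[float]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if "detections_s" not in doc:
        raise ParseError(f"{path}: missing 'detections_s' field")
    return [float(d) for d in doc["detections_s"]]


def _event_to_dict(ev: BradycardiaEvent) -> dict:
    d = {
        "onset_s": ev.onset_raw,
        "offset_s": ev.offset_raw,
        "labels": sorted(ev.labels),
        "n_phases": ev.n_phases,
        "min_hr_bpm": ev.min_hr,
        "onset_adj_s": ev.onset_adj,
        "offset_adj_s": ev.offset_adj,
    }
    if ev.context is not None:
        d["context"] = dataclasses.asdict(ev.context)
    return d


def _event_from_dict(d: dict) -> BradycardiaEvent:
    ctx = d.get("context")
    return BradycardiaEvent(
        onset_raw=float(d["onset_s"]),
        offset_raw=float(d["offset_s"]),
        labels=frozenset(d.get("labels", [])),
        n_phases=int(d.get("n_phases", 1)),
        min_hr=float(d.get("min_hr_bpm", float("nan"))),
        onset_adj=None if d.get("onset_adj_s") is None else float(d["onset_adj_s"]),
        offset_adj=None if d.get("offset_adj_s") is None else float(d["offset_adj_s"]),
        context=None if ctx is None else ClinicalContext(**ctx),
    )


def events_to_json(events: list[BradycardiaEvent]) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "events": [_event_to_dict(ev) for ev in events],
    }


def events_from_json(doc: dict) -> list[BradycardiaEvent]:
    if "events" not in doc:
        raise ParseError("event document missing 'events' field")
    return [_event_from_dict(d) for d in doc["events"]]


def write_events_json(events: list[BradycardiaEvent], path) -> None:
    Path(path).write_text(
        json.dumps(events_to_json(events), indent=1) + "\n", encoding="utf-8"
    )


def read_events_json(path) -> list[BradycardiaEvent]:
    return events_from_json(json.loads(Path(path).read_text(encoding="utf-8")))


def write_cohort(records: list[SyntheticRecord], config: CohortConfig, out_dir) -> None:
    """Write per-record CSV/JSON artifacts plus a cohort manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_rr_csv(rec.rr, out / f"{rec.record_id}_rr.csv")
        write_spo2_csv(rec.spo2_time, rec.spo2, out / f"{rec.record_id}_spo2.csv")
        write_events_json(rec.events, out / f"{rec.record_id}_truth.json")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
        "records": [
            {
                "record_id": rec.record_id,
                "seed": rec.seed,
                "n_events": len(rec.events),
                "periodic_breathing": rec.periodic_breathing,
            }
            for rec in records
        ],
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1) + "\n", encoding="utf-8"
    )
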