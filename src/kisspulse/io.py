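"""Readers and writers for the pipeline's file formats.

All artifacts are plain text: CSV for series and event tables, JSON for
ground truth, presets, pairing results and manifests, JSON or YAML for
configuration.  Sessions carry their acquisition metadata in a JSON sidecar
(``<name>.meta.json``) next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import SyncEvent
from .photometry import DffTrace, RawPhotometrySession, SchedulePattern
from .pulsar import LHPulse, LHSeries
from .synth import GroundTruth

__all__ = [
    "write_session",
    "read_session",
    "write_dff",
    "read_dff",
    "write_events",
    "read_events",
    "write_lh",
    "read_lh",
    "write_pulses",
    "read_pulses",
    "write_ground_truth",
    "read_ground_truth",
    "write_json",
    "read_json",
    "load_config_file",
]

_SESSION_COLS = ["t_s", "f405", "f490"]
_DFF_COLS = ["t_s", "dff_pct"]
_EVENT_COLS = ["onset_s", "peak_s", "end_s", "peak_dff", "rel_amplitude"]
_LH_COLS = ["t_min", "lh_ng_ml"]
_PULSE_COLS = ["peak_min", "peak_ng_ml", "amplitude", "run_length"]


def _check_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def write_session(session: RawPhotometrySession, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"t_s": session.t, "f405": session.f405, "f490": session.f490}
    ).to_csv(path, index=False)
    meta = {
        "animal_id": session.animal_id,
        "state": session.state,
        "schedule": asdict(session.schedule),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )
    return path


def read_session(path: str | Path) -> RawPhotometrySession:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, _SESSION_COLS, path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    schedule = SchedulePattern(**meta.get("schedule", {}))
    return RawPhotometrySession(
        t=df["t_s"].to_numpy(),
        f405=df["f405"].to_numpy(),
        f490=df["f490"].to_numpy(),
        schedule=schedule,
        animal_id=meta.get("animal_id", "unknown"),
        state=meta.get("state", "nl_diestrus"),
    )


def write_dff(trace: DffTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"t_s": trace.t, "dff_pct": trace.dff}).to_csv(path, index=False)
    meta = {
        "normalised": trace.normalised,
        "trace_mean": trace.trace_mean,
        "trace_sd": trace.trace_sd,
        "animal_id": trace.animal_id,
        "state": trace.state,
        "duration_s": trace.duration_s,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )
    return path


def read_dff(path: str | Path) -> DffTrace:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, _DFF_COLS, path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        return DffTrace(t=df["t_s"].to_numpy(), dff=df["dff_pct"].to_numpy(), **meta)
    return DffTrace.from_values(t=df["t_s"].to_numpy(), dff=df["dff_pct"].to_numpy())


def write_events(events: list[SyncEvent], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "onset_s": e.onset_t,
                "peak_s": e.peak_t,
                "end_s": e.end_t,
                "peak_dff": e.peak_dff,
                "rel_amplitude": e.rel_amplitude,
            }
            for e in events
        ],
        columns=_EVENT_COLS,
    ).to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> list[SyncEvent]:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, _EVENT_COLS, path)
    return [
        SyncEvent(
            onset_t=row.onset_s,
            peak_t=row.peak_s,
            end_t=row.end_s,
            peak_dff=row.peak_dff,
            rel_amplitude=row.rel_amplitude,
        )
        for row in df.itertuples()
    ]


def write_lh(series: LHSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"t_min": series.t, "lh_ng_ml": series.conc}).to_csv(path, index=False)
    return path


def read_lh(path: str | Path, lod: float = 0.04, assay_cap: float = 4.0) -> LHSeries:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, _LH_COLS, path)
    return LHSeries(
        t=df["t_min"].to_numpy(),
        conc=df["lh_ng_ml"].to_numpy(),
        lod=lod,
        assay_cap=assay_cap,
    )


def write_pulses(pulses: list[LHPulse], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "peak_min": p.peak_t,
                "peak_ng_ml": p.peak_conc,
                "amplitude": p.amplitude,
                "run_length": p.run_length,
            }
            for p in pulses
        ],
        columns=_PULSE_COLS,
    ).to_csv(path, index=False)
    return path


def read_pulses(path: str | Path) -> list[LHPulse]:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, _PULSE_COLS, path)
    return [
        LHPulse(
            peak_t=row.peak_min,
            peak_conc=row.peak_ng_ml,
            amplitude=row.amplitude,
            run_length=int(row.run_length),
        )
        for row in df.itertuples()
    ]


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "se_times": truth.se_times.tolist(),
        "se_amplitudes": truth.se_amplitudes.tolist(),
        "pulse_times": truth.pulse_times.tolist(),
        "pulse_amplitudes": truth.pulse_amplitudes.tolist(),
        "min_event_gap": truth.min_event_gap,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        se_times=np.asarray(payload["se_times"]),
        se_amplitudes=np.asarray(payload["se_amplitudes"]),
        pulse_times=np.asarray(payload["pulse_times"]),
        pulse_amplitudes=np.asarray(payload["pulse_amplitudes"]),
        min_event_gap=payload.get("min_event_gap", 300.0),
    )


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_config_file(path: str | Path) -> dict:
    """Load a pipeline configuration from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"{path}: unsupported config format (use .json, .yaml or .yml)")
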