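"""Readers, writers, configuration and run manifests.

All on-disk formats are plain text: trace CSV (``time_s,food1_counts,
food2_counts``), event CSV, LED-timeline CSV, cohort TSV, and YAML/JSON
configuration. Every CLI run emits a JSON manifest embedding the resolved
configuration, seed, package version and file digests, so any run can be
replayed bitwise from its manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, ParseError
from .signal_model import (
    CapacitanceTrace,
    Channel,
    InteractionEvent,
    LedTimeline,
    validate_session,
)
from .simulator import CalciumConfig, PlantedEvent, SessionConfig, SipModel
from .calcium_quant import FluorescenceTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_events_csv",
    "write_events_csv",
    "write_led_csv",
    "read_fluorescence_csv",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "load_config",
    "session_config_from_dict",
    "calcium_config_from_dict",
    "config_to_dict",
    "RunManifest",
    "write_manifest",
]

_TRACE_COLUMNS = ["time_s", "food1_counts", "food2_counts"]
_EVENT_COLUMNS = [
    "channel", "onset_index", "offset_index", "onset_s", "offset_s", "duration_s",
]


def _read_csv(path: str | Path, sep: str = ",") -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_trace_csv(
    path: str | Path, trace1: CapacitanceTrace, trace2: CapacitanceTrace
) -> None:
    """Write a two-channel session as trace CSV."""
    validate_session(trace1, trace2)
    df = pd.DataFrame(
        {
            "time_s": trace1.times,
            "food1_counts": trace1.values,
            "food2_counts": trace2.values,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(path: str | Path) -> tuple[CapacitanceTrace, CapacitanceTrace]:
    """Read a two-channel session from trace CSV.

    Rejects ragged rows and non-uniform sample spacing (tolerance 1e-9 s).
    """
    df = _read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if len(df) < 1:
        raise ParseError(f"{path}: no samples")
    na = df[_TRACE_COLUMNS].isna().any(axis=1)
    if na.any():
        # short/ragged rows surface as missing fields after parsing
        raise ParseError(
            f"{path}: ragged or incomplete data row {int(na.idxmax()) + 2}"
        )
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) > 1:
        diffs = np.diff(times)
        if np.any(np.abs(diffs - diffs[0]) > 1e-9):
            bad = int(np.argmax(np.abs(diffs - diffs[0]) > 1e-9)) + 2
            raise ParseError(
                f"{path}: non-uniform sample spacing at data row {bad}"
            )
        period = float(diffs[0])
    else:
        period = 0.010
    t0 = float(times[0])
    tr1 = CapacitanceTrace(
        df["food1_counts"].to_numpy(), period, Channel.FOOD1, t0
    )
    tr2 = CapacitanceTrace(
        df["food2_counts"].to_numpy(), period, Channel.FOOD2, t0
    )
    return validate_session(tr1, tr2)


def write_events_csv(
    path: str | Path,
    events: list[InteractionEvent] | list[PlantedEvent],
    sample_period: float,
) -> None:
    """Write detected or planted events as event CSV."""
    rows = []
    for ev in events:
        onset, offset = ev.onset_index, ev.offset_index
        rows.append(
            {
                "channel": ev.channel.value,
                "onset_index": onset,
                "offset_index": offset,
                "onset_s": onset * sample_period,
                "offset_s": offset * sample_period,
                "duration_s": (offset - onset + 1) * sample_period,
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_events_csv(path: str | Path) -> list[InteractionEvent]:
    """Read an event CSV; validates indices row by row."""
    df = _read_csv(path)
    missing = [c for c in _EVENT_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    events = []
    for i, row in df.iterrows():
        onset, offset = int(row["onset_index"]), int(row["offset_index"])
        if onset > offset or onset < 0:
            raise ParseError(
                f"{path}: invalid event at data row {i + 2}: "
                f"onset {onset} > offset {offset}"
            )
        events.append(InteractionEvent(onset, offset, Channel(row["channel"])))
    return events


def write_led_csv(path: str | Path, timeline: LedTimeline) -> None:
    """Write an LED command timeline as CSV with led_on in {0, 1}."""
    df = pd.DataFrame(
        {
            "time_s": np.arange(len(timeline)) * timeline.sample_period,
            "led_on": timeline.states.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_fluorescence_csv(
    path: str | Path, stim_onset: float = 5.0, stim_duration: float = 1.0
) -> FluorescenceTrace:
    """Read a fluorescence trace CSV (``time_s,fluorescence``)."""
    df = _read_csv(path)
    for col in ("time_s", "fluorescence"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    times = df["time_s"].to_numpy(dtype=float)
    if len(times) < 2:
        raise ParseError(f"{path}: need at least two frames")
    diffs = np.diff(times)
    if np.any(np.abs(diffs - diffs[0]) > 1e-9):
        bad = int(np.argmax(np.abs(diffs - diffs[0]) > 1e-9)) + 2
        raise ParseError(f"{path}: non-uniform frame spacing at data row {bad}")
    return FluorescenceTrace(
        df["fluorescence"].to_numpy(dtype=float),
        frame_period=float(diffs[0]),
        stim_onset=stim_onset,
        stim_duration=stim_duration,
    )


def write_cohort_tsv(path: str | Path, table: pd.DataFrame) -> None:
    """Write a per-fly cohort table as TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    try:
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text) or {}
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"{path}: cannot parse config: {exc}") from exc


def _from_dict(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ConfigurationError(
            f"{context}: unknown field(s) {unknown}; expected a subset of {sorted(names)}"
        )
    return cls(**data)


def session_config_from_dict(data: dict) -> SessionConfig:
    """Build a SessionConfig from a nested plain dict (config file shape)."""
    data = dict(data)
    for key in ("sip_food1", "sip_food2"):
        if key in data and isinstance(data[key], dict):
            data[key] = _from_dict(SipModel, data[key], key)
    return _from_dict(SessionConfig, data, "session")


def calcium_config_from_dict(data: dict) -> CalciumConfig:
    return _from_dict(CalciumConfig, data, "calcium")


def config_to_dict(config) -> dict:
    """Dataclass config -> JSON-serialisable dict."""
    return dataclasses.asdict(config)


@dataclass(frozen=True)
class RunManifest:
    """Record of one reproducible run."""

    subcommand: str
    config: dict
    seed: int | None
    version: str
    inputs: dict
    outputs: dict
    timestamp: str


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    subcommand: str,
    config: dict,
    seed: int | None,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> RunManifest:
    """Write the JSON manifest of a run; returns the manifest object."""
    manifest = RunManifest(
        subcommand=subcommand,
        config=config,
        seed=seed,
        version=__version__,
        inputs={str(p): _digest(p) for p in inputs},
        outputs={str(p): _digest(p) for p in outputs},
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    return manifest
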