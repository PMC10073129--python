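"""Trace, annotation and configuration persistence.

Two trace containers are supported and produce identical ``Trace`` values:

* CSV with a ``#``-prefixed metadata header (one ``key=value`` per line;
  ``sampling_rate_hz`` is mandatory) followed by a ``current_pA`` column;
* HDF5 with a ``current_pA`` dataset and the same keys as attributes.

Annotations serialize to JSON with 0-based half-open sample intervals.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .events import Trace
from .generate import EventAnnotation, GroundTruthAnnotation, SegmentAnnotation

__all__ = [
    "FormatError",
    "read_trace",
    "write_trace",
    "read_annotation",
    "write_annotation",
    "RunConfig",
]


class FormatError(ValueError):
    """A container is missing mandatory metadata; the message names it."""


_META_FIELDS = {
    "sampling_rate_hz": float,
    "voltage_mv": float,
    "provenance": str,
}


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "sampling_rate_hz": trace.sampling_rate,
        "voltage_mv": trace.applied_voltage_mv,
        "provenance": trace.provenance,
        "filter_state": json.dumps(trace.filter_state),
        "index_convention": "0-based half-open",
    }
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("current_pA", data=trace.current_pA)
            for k, v in meta.items():
                d.attrs[k] = v
    else:
        with open(path, "w") as f:
            for k, v in meta.items():
                f.write(f"# {k}={v}\n")
            f.write("current_pA\n")
            np.savetxt(f, trace.current_pA, fmt="%.17g")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            d = f["current_pA"]
            meta = {k: d.attrs[k] for k in d.attrs}
            samples = d[()]
    else:
        meta = {}
        rows = []
        with open(path) as f:
            for line in f:
                line = line.strip()
                if line.startswith("#"):
                    k, _, v = line.lstrip("# ").partition("=")
                    meta[k.strip()] = v.strip()
                elif line and line != "current_pA":
                    rows.append(float(line))
        samples = np.asarray(rows)
    if "sampling_rate_hz" not in meta:
        raise FormatError("trace container is missing 'sampling_rate_hz'")
    filter_state = json.loads(meta.get("filter_state", "[]"))
    return Trace(
        current_pA=samples,
        sampling_rate=float(meta["sampling_rate_hz"]),
        applied_voltage_mv=float(meta.get("voltage_mv", 100.0)),
        filter_state=[tuple(fs) for fs in filter_state],
        provenance=str(meta.get("provenance", "")),
    )


def write_annotation(annotation: GroundTruthAnnotation, path: str | Path) -> None:
    payload = {
        "index_convention": "0-based half-open",
        "events": [
            {
                "start_index": ev.start_index,
                "end_index": ev.end_index,
                "analyte_label": ev.analyte_label,
                "segments": [
                    {
                        "start_index": s.start_index,
                        "end_index": s.end_index,
                        "level_index": s.level_index,
                    }
                    for s in ev.segments
                ],
            }
            for ev in annotation.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=int))


def read_annotation(path: str | Path) -> GroundTruthAnnotation:
    payload = json.loads(Path(path).read_text())
    events = [
        EventAnnotation(
            start_index=ev["start_index"],
            end_index=ev["end_index"],
            analyte_label=ev["analyte_label"],
            segments=tuple(
                SegmentAnnotation(s["start_index"], s["end_index"], s["level_index"])
                for s in ev["segments"]
            ),
        )
        for ev in payload["events"]
    ]
    return GroundTruthAnnotation(events=events)


@dataclass
class RunConfig:
    """Seeded end-to-end pipeline configuration (JSON round-trippable)."""

    seed: int = 1
    out_dir: str = "results/pipeline"
    sampling_rate_hz: float = 25_000.0
    open_pore_current_pA: float = 500.0
    white_rms_pA: float = 10.0
    analytes: list = field(default_factory=lambda: ["free_bclxl", "bak_bh3_complex"])
    trace_duration_s: float = 30.0
    analysis_cutoff_hz: float = 100.0
    entry_threshold_fraction: float = 0.85
    exit_threshold_fraction: float = 0.95
    min_event_duration_s: float = 0.005
    titration_KD_nM: float = 19.0
    titration_Bmax: float = 1.11
    titration_concentrations_nM: list = field(
        default_factory=lambda: list(np.geomspace(1, 500, 9).round(2))
    )
    titration_events_per_point: int = 300
    competition_rate_per_s: float = 0.002
    competition_windows_s: list = field(
        default_factory=lambda: [0.0, 600.0, 1200.0, 2400.0]
    )
    competition_events_per_window: int = 200

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)
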