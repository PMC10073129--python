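"""Seeded end-to-end demo pipeline: simulate → detect → levels → noise →
fingerprint → titrate → compete.

Every stage writes its table under the configured output directory; the
run manifest lists all artifacts with a hash of the configuration, so a
bundle is self-describing and two runs with the same (config, seed) are
numerically identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import profiles
from .events import detect_events, estimate_open_current, inter_event_intervals
from .fingerprint import TitrationSeries, fingerprint_events, fit_binding
from .generate import NoiseModel, generate_competition_timecourse, generate_titration, generate_event_train
from .io import RunConfig, write_annotation, write_trace
from .levels import open_probabilities, segment_levels
from .noise import cohort_IN
from .pipelinestage import StageError

__all__ = ["ResultBundle", "run_pipeline"]


@dataclass
class ResultBundle:
    out_dir: Path
    config_hash: str
    artifacts: dict = field(default_factory=dict)  # name -> relative path
    summary: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, rel in self.artifacts.items():
            if not (self.out_dir / rel).exists():
                raise FileNotFoundError(f"manifest artifact {name} missing: {rel}")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> ResultBundle:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(out_dir=out, config_hash=_config_hash(config))
    rng_root = np.random.default_rng(config.seed)
    noise = NoiseModel(white_rms=config.white_rms_pA)

    summary: dict = {"analytes": {}}
    points_rows = []
    for analyte in config.analytes:
        stage = f"simulate[{analyte}]"
        try:
            profile = profiles.make_profile(analyte, sampling_rate=config.sampling_rate_hz)
            trace, ann = generate_event_train(
                profile,
                noise,
                config.open_pore_current_pA,
                config.sampling_rate_hz,
                config.trace_duration_s,
                seed=np.random.default_rng(rng_root.integers(2**31)),
            )
            write_trace(trace, out / f"trace_{analyte}.h5")
            write_annotation(ann, out / f"annotation_{analyte}.json")
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(stage, exc) from exc

        stage = f"detect[{analyte}]"
        try:
            Io = estimate_open_current(trace)
            events = detect_events(
                trace,
                Io,
                config.entry_threshold_fraction,
                config.exit_threshold_fraction,
                config.min_event_duration_s,
            )
            ev_df = pd.DataFrame(
                {
                    "start_index": [e.start_index for e in events],
                    "end_index": [e.end_index for e in events],
                    "dwell_s": [e.dwell_time for e in events],
                    "dIoverIo_pct": [e.mean_blockade_dIoverIo for e in events],
                    "Ires_pct": [e.median_residual_Ires for e in events],
                }
            )
            ev_df.to_csv(out / f"events_{analyte}.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        stage = f"levels[{analyte}]"
        try:
            segments = []
            for ev in events:
                segments.extend(segment_levels(ev, trace))
            stats = open_probabilities(segments, trace.sampling_rate)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        stage = f"noise[{analyte}]"
        try:
            in_results, dropped = cohort_IN(events, trace, config.analysis_cutoff_hz)
            in_vals = np.array([r.I_N for r in in_results])
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        stage = f"fingerprint[{analyte}]"
        try:
            pts = fingerprint_events(events, trace, config.analysis_cutoff_hz)
            for p in pts:
                points_rows.append(
                    {
                        "analyte": analyte,
                        "event_id": p.event_id,
                        "dIoverIo_pct": p.dIoverIo_pct,
                        "IN_pA": p.IN_pA,
                        "wall_time_s": p.wall_time_s,
                    }
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        waits = inter_event_intervals(events, trace.sampling_rate)
        summary["analytes"][analyte] = {
            "Io_pA": Io,
            "n_events": len(events),
            "open_probability_pct": stats.open_probability_pct,
            "IN_mean_pA": float(in_vals.mean()) if in_vals.size else None,
            "IN_sd_pA": float(in_vals.std()) if in_vals.size else None,
            "IN_events_dropped_short": dropped,
            "mean_dwell_s": float(np.mean([e.dwell_time for e in events])) if events else None,
            "mean_wait_s": float(waits.mean()) if waits.size else None,
        }

    pd.DataFrame(points_rows).to_csv(out / "fingerprint_points.csv", index=False)

    try:
        tit = generate_titration(
            config.titration_KD_nM,
            config.titration_Bmax,
            config.titration_concentrations_nM,
            config.titration_events_per_point,
            seed=np.random.default_rng(rng_root.integers(2**31)),
        )
        tit.to_csv(out / "titration.csv", index=False)
        fit = fit_binding(TitrationSeries(tit))
        summary["binding"] = {
            "K_D_nM": fit.K_D,
            "B_max": fit.B_max,
            "K_D_ci95_nM": list(fit.K_D_ci95),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("titrate", exc) from exc

    try:
        comp = generate_competition_timecourse(
            "bak_bh3_complex",
            "abt737_complex",
            config.competition_rate_per_s,
            config.competition_windows_s,
            config.competition_events_per_window,
            seed=np.random.default_rng(rng_root.integers(2**31)),
        )
        comp.to_csv(out / "competition.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("compete", exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    bundle.summary = summary
    bundle.artifacts = {
        p.name: p.name for p in sorted(out.iterdir()) if p.is_file()
    }
    (out / "manifest.json").write_text(
        json.dumps({"config_hash": bundle.config_hash, "artifacts": bundle.artifacts},
                   indent=1)
    )
    bundle.artifacts["manifest.json"] = "manifest.json"
    bundle.validate()
    return bundle
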