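"""Plain-text table and TIFF interchange, run configuration, and the pipeline.

Trace tables are delimited text (CSV) with unit-suffixed headers
(``t_s``, ``Lp_um``, ``P_Pa``, ``Rp_um``, ``Rc_um``); kymographs are
single-channel grayscale TIFFs with a YAML sidecar carrying pixel/frame
calibration.  Readers validate rather than coerce: a non-monotone time
column or a missing mandatory column is a named error, not a warning.
Every pipeline output embeds the configuration hash and seed so reruns are
auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .creep import AspirationTrace, aggregate_params, fit_model, select_model
from .fusion import (
    DegenerateEventError,
    FusionEvent,
    fit_capillary_velocity,
    fit_relaxation,
)
from .kymograph import Kymograph, segment_front, track_to_trace
from .models import Interface, ModelClass, StressContext
from .tension import PressureSeries, cohort_tension, estimate_tension

__all__ = [
    "RunConfig",
    "TraceTableError",
    "read_trace_table",
    "write_trace_table",
    "read_kymograph",
    "write_kymograph",
    "read_fusion_table",
    "write_fusion_table",
    "run_pipeline",
]

TRACE_COLUMNS = ["trace_id", "nucleolus_id", "phase", "t_s", "Lp_um", "P_Pa", "Rp_um", "Rc_um"]


class TraceTableError(ValueError):
    """A trace table violates the declared column or monotonicity contract."""


@dataclass
class RunConfig:
    """Pipeline configuration; serialized alongside every output.

    Units are fixed package-wide (Pa, um, s, uN/m, Pa*s) and declared here
    only so output files are self-describing.
    """

    seed: int
    model_selection_threshold: float = 2.0
    segmentation_method: str = "otsu"
    tension_weighting: str = "inverse_variance"
    geometric_prefactor: float = 1.0
    units: Dict[str, str] = field(
        default_factory=lambda: {
            "pressure": "Pa",
            "length": "um",
            "time": "s",
            "tension": "uN/m",
            "viscosity": "Pa.s",
        }
    )

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError("config must declare an explicit seed")
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def write_trace_table(traces: Sequence[AspirationTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for t, lp in zip(tr.times, tr.Lp):
            rows.append(
                {
                    "trace_id": tr.trace_id,
                    "nucleolus_id": tr.nucleolus_id,
                    "phase": tr.phase,
                    "t_s": t,
                    "Lp_um": lp,
                    "P_Pa": tr.P,
                    "Rp_um": tr.Rp,
                    "Rc_um": tr.Rc,
                    "necking": int(tr.necking_flag),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trace_table(path: str | Path) -> List[AspirationTrace]:
    """Read and validate a trace table; rejects malformed traces by name."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceTableError(f"missing mandatory column(s): {missing}")
    if df.duplicated(subset=["trace_id", "t_s"]).any():
        dupes = df[df.duplicated(subset=["trace_id", "t_s"])]["trace_id"].unique()
        raise TraceTableError(f"duplicate (trace_id, t) rows in {list(dupes)}")
    traces = []
    for tid, g in df.groupby("trace_id", sort=False):
        t = g["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TraceTableError(f"trace {tid!r}: time column not strictly increasing")
        rc = float(g["Rc_um"].iloc[0])
        traces.append(
            AspirationTrace(
                times=t,
                Lp=g["Lp_um"].to_numpy(dtype=float),
                P=float(g["P_Pa"].iloc[0]),
                Rp=float(g["Rp_um"].iloc[0]),
                Rc=math.inf if (np.isnan(rc) or rc <= 0) else rc,
                phase=str(g["phase"].iloc[0]),
                trace_id=str(tid),
                nucleolus_id=str(g["nucleolus_id"].iloc[0]),
                necking_flag=bool(g["necking"].iloc[0]) if "necking" in g else False,
            )
        )
    return traces


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Single-channel grayscale TIFF plus a YAML calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, kymo.intensity.astype(np.float32))
    sidecar = {
        "pixel_size_um": kymo.pixel_size,
        "frame_interval_s": kymo.frame_interval,
        "channel": kymo.channel,
    }
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    sidecar_path = path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing calibration sidecar {sidecar_path.name} for {path.name}"
        )
    with open(sidecar_path) as fh:
        cal = yaml.safe_load(fh)
    return Kymograph(
        intensity=tifffile.imread(path),
        pixel_size=float(cal["pixel_size_um"]),
        frame_interval=float(cal["frame_interval_s"]),
        channel=str(cal.get("channel", "")),
    )


def write_fusion_table(events: Sequence[FusionEvent], path: str | Path) -> None:
    rows = []
    for ev in events:
        for t, ar in zip(ev.times, ev.AR):
            rows.append(
                {
                    "event_id": ev.event_id,
                    "t_s": t,
                    "AR": ar,
                    "major_axis0_um": ev.major_axis0,
                    "minor_axis0_um": ev.minor_axis0,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fusion_table(path: str | Path) -> List[FusionEvent]:
    df = pd.read_csv(path)
    required = ["event_id", "t_s", "AR", "major_axis0_um", "minor_axis0_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceTableError(f"missing mandatory column(s): {missing}")
    events = []
    for eid, g in df.groupby("event_id", sort=False):
        events.append(
            FusionEvent(
                times=g["t_s"].to_numpy(dtype=float),
                AR=g["AR"].to_numpy(dtype=float),
                major_axis0=float(g["major_axis0_um"].iloc[0]),
                minor_axis0=float(g["minor_axis0_um"].iloc[0]),
                event_id=str(eid),
            )
        )
    return events


def _stress_context(trace: AspirationTrace, gamma: float, prefactor: float) -> StressContext:
    return StressContext(
        applied_pressure=trace.P,
        interfaces=(Interface(gamma, trace.Rp, trace.Rc),),
        geometric_prefactor=prefactor,
    )


def run_pipeline(
    config: RunConfig,
    *,
    traces: Optional[Sequence[AspirationTrace]] = None,
    kymographs: Optional[Sequence[Kymograph]] = None,
    kymograph_meta: Optional[Sequence[dict]] = None,
    fusion_events: Optional[Sequence[FusionEvent]] = None,
    pressure_series: Optional[Sequence[PressureSeries]] = None,
    gamma: float = 0.0,
    stages: Sequence[str] = ("extract", "fit", "tension", "fusion"),
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Run the requested stages and return a machine-readable summary.

    ``extract`` converts kymographs to traces (necking-flagged ones are
    excluded from fitting and counted); ``fit`` selects a model per trace and
    aggregates per-phase cohort parameters (``gamma`` supplies the Laplace
    correction); ``tension`` infers interfacial tension from pressure series;
    ``fusion`` fits relaxations and the capillary-velocity slope.  Raises on
    missing stage inputs rather than silently skipping.
    """
    stages = list(stages)
    summary: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": stages}
    all_traces: List[AspirationTrace] = list(traces or [])

    if "extract" in stages:
        if not kymographs:
            raise ValueError("extract stage requested but no kymographs given")
        meta = kymograph_meta or [{} for _ in kymographs]
        n_excluded = 0
        for i, (kymo, md) in enumerate(zip(kymographs, meta)):
            track = segment_front(kymo, method=config.segmentation_method)
            tr = track_to_trace(
                track,
                kymo,
                P=md.get("P", 20.0),
                Rp=md.get("Rp", 1.0),
                Rc=md.get("Rc", math.inf),
                phase=md.get("phase", "GC"),
                trace_id=md.get("trace_id", f"kymo_{i}"),
                nucleolus_id=md.get("nucleolus_id", f"kymo_{i}"),
            )
            if tr.necking_flag:
                n_excluded += 1
            all_traces.append(tr)
        summary["extract"] = {
            "n_kymographs": len(kymographs),
            "n_necking_excluded": n_excluded,
        }

    if "fit" in stages:
        usable = [t for t in all_traces if not t.necking_flag]
        if not usable:
            raise ValueError("fit stage requested but no usable traces available")
        fit_summary = {}
        by_phase: Dict[str, list] = {}
        for tr in usable:
            by_phase.setdefault(tr.phase, []).append(tr)
        for phase, group in by_phase.items():
            winners, fits, ctxs = [], [], []
            for tr in group:
                eps = (tr.Lp - tr.L0) / tr.Rp
                winner, candidates = select_model(
                    eps, tr.times, mse_ratio_threshold=config.model_selection_threshold,
                    trace_id=tr.trace_id, nucleolus_id=tr.nucleolus_id,
                )
                winners.append(winner)
                fits.append(candidates[winner])
                ctxs.append(_stress_context(tr, gamma, config.geometric_prefactor))
            # cohort aggregation under the majority model class
            counts = {m: winners.count(m) for m in set(winners)}
            majority = max(counts, key=counts.get)
            maj_fits = [
                fit_model((tr.Lp - tr.L0) / tr.Rp, tr.times, majority,
                          trace_id=tr.trace_id, nucleolus_id=tr.nucleolus_id)
                for tr in group
            ]
            cohort = aggregate_params(
                maj_fits,
                [_stress_context(tr, gamma, config.geometric_prefactor) for tr in group],
                model=majority,
                geometric_prefactor=config.geometric_prefactor,
            )
            fit_summary[phase] = {
                "n_traces": len(group),
                "selected_model": majority.value,
                "model_votes": {m.value: c for m, c in counts.items()},
                "cohort": {
                    name: {
                        "mean": est.mean,
                        "sem": est.sem,
                        "propagated": est.propagated_uncertainty,
                        "n_nucleoli": est.n_nucleoli,
                        "n_measurements": est.n_measurements,
                    }
                    for name, est in cohort.items()
                },
            }
        summary["fit"] = fit_summary

    if "tension" in stages:
        if not pressure_series:
            raise ValueError(
                "tension stage requested but no pressure series available "
                "(run fits across pressures first)"
            )
        ests = [estimate_tension(s, weighting=config.tension_weighting) for s in pressure_series]
        mean, sem = cohort_tension(ests)
        summary["tension"] = {
            "per_sample": {
                e.sample_id: {"gamma_uN_per_m": e.gamma, "laplace_Pa": e.laplace_pressure}
                for e in ests
            },
            "cohort_gamma_uN_per_m": mean,
            "cohort_sem": sem,
        }

    if "fusion" in stages:
        if not fusion_events:
            raise ValueError("fusion stage requested but no fusion events given")
        fitted = []
        n_degenerate = 0
        for ev in fusion_events:
            try:
                fit_relaxation(ev)
                fitted.append(ev)
            except DegenerateEventError:
                n_degenerate += 1
        summary["fusion"] = {"n_events": len(fusion_events), "n_degenerate": n_degenerate}
        if len(fitted) >= 3:
            cv = fit_capillary_velocity(fitted)
            summary["fusion"]["inverse_capillary_velocity_s_per_um"] = cv.slope
            summary["fusion"]["slope_err"] = cv.slope_err

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        if all_traces:
            write_trace_table(all_traces, out / "traces.csv")
    return summary
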