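"""End-to-end orchestration of the screening and stretch analyses.

A run is described by one declarative :class:`RunConfig`; every output CSV
carries a comment header with the config hash and package version so reruns
are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, beatkinetics, cellmech, motionflow, screenstats
from .beatkinetics import BeatDetectionConfig
from .cellmech import CellGeometry, StressTrace, StretchProtocol
from .core import FrameSequence, MotionSignal
from .motionflow import FlowConfig

__all__ = ["RunConfig", "run_screen_pipeline", "run_stretch_pipeline"]

log = logging.getLogger("cardiomotion")


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one pipeline run."""

    flow: FlowConfig = field(default_factory=FlowConfig)
    detection: BeatDetectionConfig = field(default_factory=BeatDetectionConfig)
    metric: str = "mean_relaxation_velocity"
    z_threshold: float = 2.0
    min_replicates: int = 2
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "flow": vars(self.flow),
                "detection": vars(self.detection),
                "metric": self.metric,
                "z_threshold": self.z_threshold,
                "min_replicates": self.min_replicates,
                "seed": self.seed,
                "version": __version__,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamped_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cardiomotion {__version__} config_hash={cfg.config_hash()}\n")
        df.to_csv(fh, index=False)


def well_metrics_from_signal(
    sig: MotionSignal, cfg: RunConfig
) -> dict[str, float]:
    """Contractility summary of one well's motion signal as a flat dict."""
    beats = beatkinetics.detect_beats(sig, cfg.detection)
    if not beats:
        return {"n_beats": 0}
    _, summary = beatkinetics.extract_metrics(sig, beats, cfg.detection)
    return vars(summary).copy()


def run_screen_pipeline(
    inputs: dict[tuple, FrameSequence | MotionSignal],
    plate_map: pd.DataFrame,
    cfg: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Motion extraction -> beat kinetics -> plate statistics, per well.

    ``inputs`` maps (replicate, plate_id, well) to either a raw
    :class:`FrameSequence` (run through optical flow first) or an already
    extracted :class:`MotionSignal`. ``plate_map`` needs columns replicate,
    plate_id, well, mirna_id and optionally is_negative_control; every input
    key must appear in the plate map. Wells that fail to process are recorded
    in a failure manifest and the run continues.

    Returns {"metrics": ..., "zscores": ..., "hits": ..., "failures": ...}
    and writes stamped CSVs to ``outdir`` when given.
    """
    cfg = cfg or RunConfig()
    if plate_map.empty:
        raise ValueError("plate map is empty")
    key_cols = ["replicate", "plate_id", "well"]
    for col in key_cols + ["mirna_id"]:
        if col not in plate_map.columns:
            raise ValueError(f"plate map is missing column: {col}")
    mapped = {tuple(r) for r in plate_map[key_cols].itertuples(index=False)}
    unmapped = sorted(set(inputs) - mapped)
    if unmapped:
        raise ValueError(f"inputs not covered by the plate map: {unmapped[:5]}")

    rows, failures = [], []
    for key, obj in inputs.items():
        replicate, plate_id, well = key
        try:
            if isinstance(obj, FrameSequence):
                sig = motionflow.motion_signal(obj, cfg.flow)
            else:
                sig = obj
            metrics = well_metrics_from_signal(sig, cfg)
            if metrics.get("n_beats", 0) == 0:
                raise ValueError("no beats detected")
            rows.append(
                {"replicate": replicate, "plate_id": plate_id, "well": well, **metrics}
            )
        except Exception as exc:  # noqa: BLE001 - failed wells must not kill the run
            log.warning("well %s failed: %s", key, exc)
            failures.append(
                {
                    "replicate": replicate,
                    "plate_id": plate_id,
                    "well": well,
                    "error": str(exc),
                }
            )
    metrics_df = pd.DataFrame(rows).sort_values(key_cols, ignore_index=True)
    merged = metrics_df.merge(plate_map, on=key_cols, how="left")
    zs = screenstats.plate_zscores(merged, value_col=cfg.metric)
    hits = screenstats.call_hits(
        zs, z_threshold=cfg.z_threshold, min_replicates=cfg.min_replicates
    )
    out = {
        "metrics": metrics_df,
        "zscores": zs,
        "hits": hits,
        "failures": pd.DataFrame(failures),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            _stamped_csv(df, outdir / f"{name}.csv", cfg)
    return out


def run_stretch_pipeline(
    trace: StressTrace,
    protocol: StretchProtocol,
    geometry: CellGeometry | None = None,
    in_force_units: bool = False,
    cfg: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Staircase segmentation -> step decomposition -> curves -> SLS fit.

    When the trace is recorded in uN (``in_force_units``), a
    :class:`CellGeometry` is required to convert to kPa; omit both to run the
    whole decomposition directly in force units.
    """
    cfg = cfg or RunConfig()
    if in_force_units:
        if geometry is None:
            raise ValueError(
                "kPa output requested for a force-units trace: supply "
                "`geometry` (thickness is not optional)"
            )
        trace = StressTrace(
            t=trace.t,
            stress_kpa=cellmech.stress_from_force(trace.stress_kpa, geometry),
            strain_schedule=trace.strain_schedule,
            source_id=trace.source_id,
        )
    windows = cellmech.segment_staircase(trace, protocol)
    steps = cellmech.step_mechanics(trace, windows)
    curve, rho = cellmech.length_tension(steps)
    fit = cellmech.fit_sls(trace, protocol, windows)
    out = {
        "steps": steps,
        "curve": curve,
        "spearman_rho": rho,
        "fit": fit,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _stamped_csv(curve, outdir / "length_tension.csv", cfg)
        steps_df = pd.DataFrame(
            [
                {
                    "step_index": s.step_index,
                    "strain_pct": s.strain_pct,
                    "peak_stress_kpa": s.peak_stress_kpa,
                    "steady_state_stress_kpa": s.steady_state_stress_kpa,
                    "relaxation_stress_kpa": s.relaxation_stress_kpa,
                    "flagged": s.flagged,
                }
                for s in steps
            ]
        )
        _stamped_csv(steps_df, outdir / "step_mechanics.csv", cfg)
    return out
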