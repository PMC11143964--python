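"""Synthetic-data generators with known ground truth.

Every downstream stage (optical-flow motion extraction, beat kinetics,
plate statistics, post tracking, staircase mechanics) is exercised on data
produced here, so the true waveform / deflection / stress / hit labels are
always emitted next to the artifact. Seeds are explicit arguments; no global
random state is touched, and regeneration with the same seed is
bit-identical.

The beating-monolayer videos are a speckle texture advected by a uniaxial,
spatially smooth, temporally periodic displacement field (contraction toward
a vertical center line, the way a monolayer shortens). The field's spatial
profile is normalized so that the spatial-mean speed at any instant equals
the prescribed beat waveform — the quantity the optical-flow stage should
recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cellmech import (
    SLSParams,
    StepMechanics,
    StressTrace,
    StretchProtocol,
    sls_staircase_response,
    sls_step_truth,
)
from .core import FrameSequence, MotionSignal, write_json_sidecar

__all__ = [
    "BeatWaveformParams",
    "PlantedScreenDesign",
    "PostBlobSpec",
    "beat_waveform",
    "generate_beating_video",
    "generate_staircase_trace",
    "generate_screen_dataset",
    "generate_post_track",
    "save_video_with_truth",
]


# --------------------------------------------------------------------- beats
@dataclass(frozen=True)
class BeatWaveformParams:
    """Parameters of the periodic contraction/relaxation speed waveform.

    Each beat is a contraction half-sine (duration ``contraction_duration_s``,
    peak ``peak_contraction_velocity``) followed by a relaxation half-sine and
    a quiescent interval filling the rest of the period. Velocities are in
    px/s for video synthesis (um/s if a pixel size is attached downstream).
    The defaults describe a healthy spontaneously beating monolayer at 1 Hz
    whose contraction and relaxation displacements balance, so the tissue
    returns to its resting configuration every beat.
    """

    beat_rate_hz: float = 1.0
    peak_contraction_velocity: float = 40.0
    peak_relaxation_velocity: float = 25.0
    contraction_duration_s: float = 0.20
    relaxation_duration_s: float = 0.32
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beat_rate_hz <= 0:
            raise ValueError("beat_rate_hz must be positive")
        if self.peak_contraction_velocity < 0 or self.peak_relaxation_velocity < 0:
            raise ValueError("velocities must be non-negative")
        period = 1.0 / self.beat_rate_hz
        if self.contraction_duration_s + self.relaxation_duration_s > period + 1e-12:
            raise ValueError("contraction + relaxation must fit within one period")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def period_s(self) -> float:
        return 1.0 / self.beat_rate_hz

    @property
    def quiescent_fraction(self) -> float:
        return 1.0 - (
            self.contraction_duration_s + self.relaxation_duration_s
        ) * self.beat_rate_hz


def beat_waveform(params: BeatWaveformParams, t: np.ndarray) -> np.ndarray:
    """Signed displacement velocity at times ``t``.

    Positive during contraction (motion toward the center line), negative
    during relaxation. The unsigned speed ``|beat_waveform|`` is the motion
    amplitude a flow-based analysis should recover.
    """
    t = np.asarray(t, dtype=float)
    ph = np.mod(t, params.period_s)
    v = np.zeros_like(ph)
    tc, tr = params.contraction_duration_s, params.relaxation_duration_s
    in_c = ph < tc
    v[in_c] = params.peak_contraction_velocity * np.sin(np.pi * ph[in_c] / tc)
    in_r = (ph >= tc) & (ph < tc + tr)
    v[in_r] = -params.peak_relaxation_velocity * np.sin(np.pi * (ph[in_r] - tc) / tr)
    return v


def _speckle(rng: np.random.Generator, shape, texture_density: float) -> np.ndarray:
    """Band-limited speckle texture in [0, 1]; higher density = finer grain."""
    sigma = max(0.8, 2.0 / texture_density)
    tex = ndimage.gaussian_filter(rng.random(shape), sigma)
    lo, hi = tex.min(), tex.max()
    return (tex - lo) / (hi - lo)


def generate_beating_video(
    params: BeatWaveformParams,
    n_frames: int = 370,
    frame_interval_s: float = 1.0 / 37.0,
    image_size: int = 128,
    texture_density: float = 1.0,
) -> tuple[FrameSequence, MotionSignal]:
    """Synthesize a beating-monolayer movie plus its ground-truth motion signal.

    Frames advect a fixed speckle texture with the displacement field
    ``u(x, t) = -d(t) * phi(x) * x_hat`` where ``phi`` is an odd profile about
    the vertical center line with spatial-mean magnitude 1, and ``d(t)`` is
    the integral of the (noisy) beat waveform. The returned ground truth is
    the realized per-frame-pair spatial-mean speed ``|Δd|/Δt``, stamped at
    pair midpoints — exactly what the optical-flow stage estimates.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if image_size < 64:
        raise ValueError("image_size must be at least 64 px per side")
    rng = np.random.default_rng(params.seed)

    t = np.arange(n_frames) * frame_interval_s
    v = beat_waveform(params, t)
    if params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, size=v.shape)
    # cumulative displacement amplitude (trapezoid; exact for the stored truth)
    d = np.concatenate(
        [[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * frame_interval_s)]
    )

    # odd profile about the center line, spatial-mean |phi| = 1
    x = np.arange(image_size)
    phi = np.sin(np.pi * (x - image_size / 2) / image_size) / (2.0 / np.pi)
    max_step = np.max(np.abs(np.diff(d))) * np.max(np.abs(phi))
    if max_step > 0.25 * image_size:
        raise ValueError(
            "per-frame displacement exceeds 25% of the image size; "
            "optical flow would be unrecoverable — lower the velocities or "
            "raise the frame rate"
        )

    pad = int(np.ceil(np.max(np.abs(d)) * np.max(np.abs(phi)))) + 8
    base = _speckle(rng, (image_size + 2 * pad, image_size + 2 * pad), texture_density)
    yy, xx = np.meshgrid(np.arange(image_size), x, indexing="ij")
    frames = np.empty((n_frames, image_size, image_size), dtype=np.float32)
    for k in range(n_frames):
        if d[k] == 0.0:
            frames[k] = base[pad : pad + image_size, pad : pad + image_size]
            continue
        src_x = xx + d[k] * phi[xx]  # inverse warp of contraction by -d*phi
        frames[k] = ndimage.map_coordinates(
            base, [yy + pad, src_x + pad], order=3, mode="reflect"
        )

    speed = np.abs(np.diff(d)) / frame_interval_s
    truth = MotionSignal(
        t=t[:-1] + frame_interval_s / 2.0,
        v=speed,
        units="px_per_s",
        source_id="synthgen",
        meta={"params": params.__dict__.copy()},
    )
    seq = FrameSequence(
        frames=frames, frame_interval_s=frame_interval_s, source_id="synthgen"
    )
    return seq, truth


def save_video_with_truth(
    seq: FrameSequence, truth: MotionSignal, stem: str | Path
) -> None:
    """Write <stem>.tif, <stem>_truth.csv and a JSON sidecar with metadata."""
    stem = Path(stem)
    seq.to_tiff(stem.with_suffix(".tif"))
    truth.to_csv(stem.parent / f"{stem.name}_truth.csv")
    write_json_sidecar(
        stem.with_suffix(".json"),
        {
            "frame_interval_s": seq.frame_interval_s,
            "n_frames": seq.n_frames,
            "ground_truth": truth.meta,
        },
    )


# ----------------------------------------------------------------- staircase
def generate_staircase_trace(
    sls: SLSParams,
    protocol: StretchProtocol,
    noise_sd_kpa: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 100.0,
) -> tuple[StressTrace, list[StepMechanics]]:
    """Exact SLS staircase stress trace plus the analytic per-step decomposition.

    The noise-free response is the closed-form piecewise solution of the
    Zener model under the commanded ramp/hold schedule; optional additive
    Gaussian noise emulates transducer noise.
    """
    rng = np.random.default_rng(seed)
    n = int(round(protocol.total_duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    stress = sls_staircase_response(t, sls, protocol)
    if noise_sd_kpa > 0:
        stress = stress + rng.normal(0.0, noise_sd_kpa, size=stress.shape)
    schedule = np.array(
        [protocol.cumulative_strain(k + 1) for k in range(protocol.n_steps)]
    )
    trace = StressTrace(
        t=t, stress_kpa=stress, strain_schedule=schedule, source_id="synthgen"
    )
    return trace, sls_step_truth(sls, protocol)


# -------------------------------------------------------------------- screen
@dataclass(frozen=True)
class PlantedScreenDesign:
    """Design of a synthetic multi-plate miRNA screen with planted hits.

    Non-hit wells are i.i.d. normal around the plate mean; wells carrying a
    planted hit are shifted by ``hit_effect_z`` plate-SD units. Replicates are
    independent re-draws of the same design (the screen was run in
    triplicate).
    """

    n_plates: int = 1
    wells_per_plate: int = 384
    n_replicates: int = 3
    n_control_wells: int = 16
    hit_ids: tuple[str, ...] = ()
    hit_effect_z: float = 6.0
    baseline_mean: float = 100.0
    well_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.wells_per_plate < 2:
            raise ValueError(
                "wells_per_plate must be >= 2 (plate SD undefined otherwise)"
            )
        if self.n_control_wells >= self.wells_per_plate:
            raise ValueError("control wells must leave room for library wells")


def _well_address(i: int) -> str:
    return f"{chr(ord('A') + i // 24)}{i % 24 + 1:02d}"


def generate_screen_dataset(
    design: PlantedScreenDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate well-level metric tables for every replicate.

    Returns ``(wells, truth)``: one row per (replicate, plate, well) with the
    simulated metric value, and the true hit labels. Each library well hosts
    one miRNA mimic; hit identities listed in ``design.hit_ids`` are placed on
    their plates and shifted by ``hit_effect_z`` plate-SDs in every replicate.
    """
    rng = np.random.default_rng(design.seed)
    n_lib = design.wells_per_plate - design.n_control_wells
    mirna_ids = [
        f"miR-{p * n_lib + j + 1:04d}" for p in range(design.n_plates) for j in range(n_lib)
    ]
    for h in design.hit_ids:
        if h not in mirna_ids:
            raise ValueError(f"hit id {h!r} is not on any plate")
    rows = []
    for rep in range(1, design.n_replicates + 1):
        for p in range(design.n_plates):
            plate_id = f"P{p + 1:02d}"
            values = rng.normal(
                design.baseline_mean, design.well_noise_sd, design.wells_per_plate
            )
            for i in range(design.wells_per_plate):
                is_ctrl = i < design.n_control_wells
                mid = "miR-neg" if is_ctrl else mirna_ids[p * n_lib + (i - design.n_control_wells)]
                val = values[i]
                if mid in design.hit_ids:
                    val += design.hit_effect_z * design.well_noise_sd
                rows.append(
                    {
                        "replicate": rep,
                        "plate_id": plate_id,
                        "well": _well_address(i),
                        "mirna_id": mid,
                        "is_negative_control": is_ctrl,
                        "value": val,
                    }
                )
    wells = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "mirna_id": sorted(set(mirna_ids)),
        }
    )
    truth["is_true_hit"] = truth["mirna_id"].isin(design.hit_ids)
    return wells, truth


# --------------------------------------------------------------- post videos
@dataclass(frozen=True)
class PostBlobSpec:
    """Image-space geometry of the two bright post tips.

    Tips are rendered as Gaussian blobs of full width ``tip_diameter_px``
    separated by ``tip_separation_px`` along the x axis.
    """

    tip_separation_px: float = 60.0
    tip_diameter_px: float = 12.0
    image_size: int = 128
    peak_intensity: float = 1.0
    background: float = 0.05

    def __post_init__(self) -> None:
        if self.tip_separation_px <= self.tip_diameter_px:
            raise ValueError("tip separation must exceed tip diameter")


def generate_post_track(
    twitch: BeatWaveformParams,
    blobs: PostBlobSpec,
    n_frames: int = 200,
    frame_interval_s: float = 0.01,
    deflection_scale: float = 1.0,
    noise_sd: float = 0.0,
) -> tuple[FrameSequence, pd.DataFrame]:
    """Render a two-post tip movie with a known sub-pixel deflection trace.

    Both tips move toward each other by half the twitch displacement
    ``d(t) * deflection_scale`` (the tissue pulls the posts inward during each
    twitch), so the inter-tip distance shrinks by the full deflection.
    Returns the frames and a truth table (t, x/y per tip, deflection_px).
    """
    rng = np.random.default_rng(twitch.seed)
    t = np.arange(n_frames) * frame_interval_s
    v = beat_waveform(twitch, t)
    if twitch.noise_sd > 0:
        v = v + rng.normal(0.0, twitch.noise_sd, size=v.shape)
    d = (
        np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * frame_interval_s)])
        * deflection_scale
    )

    size = blobs.image_size
    cy = size / 2.0
    cx1 = size / 2.0 - blobs.tip_separation_px / 2.0
    cx2 = size / 2.0 + blobs.tip_separation_px / 2.0
    sigma = blobs.tip_diameter_px / 2.355  # FWHM -> sigma
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")

    frames = np.empty((n_frames, size, size), dtype=np.float32)
    rows = []
    for k in range(n_frames):
        x1 = cx1 + d[k] / 2.0
        x2 = cx2 - d[k] / 2.0
        img = blobs.background + blobs.peak_intensity * (
            np.exp(-((xx - x1) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
            + np.exp(-((xx - x2) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        )
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[k] = img
        rows.append(
            {
                "t": t[k],
                "x1": x1,
                "y1": cy,
                "x2": x2,
                "y2": cy,
                "deflection_px": d[k],
            }
        )
    seq = FrameSequence(
        frames=frames, frame_interval_s=frame_interval_s, source_id="synthgen-posts"
    )
    return seq, pd.DataFrame(rows)
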