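"""Engineered-cardiac-tissue force analysis.

Macrotissues are anchored between two flexible PDMS posts; each twitch bends
the posts inward. The tips are tracked by intensity-weighted centroids,
tissue deflection is the baseline-subtracted change of the inter-tip
distance (common-mode stage drift cancels in the difference), and force
follows the tip-loaded cantilever relation F = 3 E I delta / L^3 with
I = pi r^4 / 4.

Ring-shaped organoids are analyzed as motion signals; their pre-/post-
transfection time course is normalized per tissue against its own baseline
recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beatkinetics
from .beatkinetics import BeatDetectionConfig
from .core import FrameSequence, MotionSignal

__all__ = [
    "PostGeometry",
    "Roi",
    "PostTrack",
    "ForceTrace",
    "TwitchMetrics",
    "track_posts",
    "deflection_to_force",
    "twitch_metrics",
    "normalize_timecourse",
]


@dataclass(frozen=True)
class PostGeometry:
    """Mechanical constants of one flexible post (tip-loaded cantilever).

    There are no silent defaults: the elastic modulus, post length and
    radius are not universal and must be supplied for each post batch.
    """

    elastic_modulus_kpa: float
    length_mm: float
    radius_mm: float

    def __post_init__(self) -> None:
        if min(self.elastic_modulus_kpa, self.length_mm, self.radius_mm) <= 0:
            raise ValueError("all post geometry constants must be positive")

    @property
    def second_moment_mm4(self) -> float:
        """Area second moment of the circular cross-section, pi r^4 / 4."""
        return np.pi * self.radius_mm**4 / 4.0


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest (pixels): x, y of top-left corner, w, h."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ROI must have positive size")


@dataclass
class PostTrack:
    """Sub-pixel tip centroids per frame and derived tissue deflection."""

    t: np.ndarray
    centroids_px: np.ndarray  # shape (n_frames, 2 posts, 2) as (x, y)
    deflection_px: np.ndarray
    pixel_size_um: float | None = None
    gap_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def deflection_um(self) -> np.ndarray:
        if self.pixel_size_um is None:
            raise ValueError("pixel size unknown; deflection only available in px")
        return self.deflection_px * self.pixel_size_um

    def tip_distance_px(self) -> np.ndarray:
        d = self.centroids_px[:, 1, :] - self.centroids_px[:, 0, :]
        return np.hypot(d[:, 0], d[:, 1])


@dataclass
class ForceTrace:
    """Twitch force over time (uN)."""

    t: np.ndarray
    force_un: np.ndarray
    source_id: str = ""

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.t, "force_un": self.force_un}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class TwitchMetrics:
    """Per-recording twitch-force summary."""

    developed_force_un: float
    beat_rate_bpm: float
    mean_contraction_velocity: float
    max_contraction_velocity: float
    mean_relaxation_velocity: float
    max_relaxation_velocity: float
    n_twitches: int


def _roi_centroid(frame: np.ndarray, roi: Roi) -> tuple[float, float, bool]:
    """Intensity-weighted centroid inside a ROI, background-subtracted.

    Returns (x, y) in full-frame pixel coordinates and an edge flag raised
    when the centroid falls within one pixel of the ROI border (tip about to
    leave the ROI).
    """
    patch = frame[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w].astype(float)
    patch = patch - np.percentile(patch, 10)
    patch[patch < 0] = 0.0
    total = patch.sum()
    if total <= 0:
        return roi.x + roi.w / 2.0, roi.y + roi.h / 2.0, True
    yy, xx = np.mgrid[0 : roi.h, 0 : roi.w]
    cx = float((xx * patch).sum() / total)
    cy = float((yy * patch).sum() / total)
    near_edge = cx < 1 or cy < 1 or cx > roi.w - 2 or cy > roi.h - 2
    return roi.x + cx, roi.y + cy, near_edge


def track_posts(
    seq: FrameSequence,
    roi_pair: tuple[Roi, Roi],
    baseline_percentile: float = 10.0,
) -> PostTrack:
    """Track both post tips and derive the tissue deflection trace.

    Deflection is the diastolic-baseline inter-tip distance minus the
    instantaneous inter-tip distance (positive during a twitch, when the
    posts are pulled toward each other). The diastolic baseline is the
    rolling high percentile of the distance — implemented as the global
    ``100 - baseline_percentile`` percentile, robust to incomplete
    relaxation. Frames whose centroid touches a ROI border are flagged as
    gaps, not silently interpolated.
    """
    n = seq.n_frames
    centroids = np.empty((n, 2, 2))
    gaps = []
    for k in range(n):
        for j, roi in enumerate(roi_pair):
            cx, cy, edge = _roi_centroid(seq.frames[k], roi)
            centroids[k, j] = (cx, cy)
            if edge:
                gaps.append(k)
    track = PostTrack(
        t=seq.times(),
        centroids_px=centroids,
        deflection_px=np.zeros(n),
        pixel_size_um=seq.pixel_size_um,
        gap_frames=np.unique(gaps),
    )
    dist = track.tip_distance_px()
    baseline = float(np.percentile(dist, 100.0 - baseline_percentile))
    track.deflection_px = baseline - dist
    if len(track.gap_frames):
        warnings.warn(
            f"{len(track.gap_frames)} frame(s) with tip centroid at the ROI "
            "border; treat these as tracking gaps",
            stacklevel=2,
        )
    return track


def deflection_to_force(
    track_or_deflection_um: PostTrack | np.ndarray,
    post: PostGeometry,
    t: np.ndarray | None = None,
) -> ForceTrace:
    """Convert tip deflection (um) to force (uN) via F = 3 E I delta / L^3.

    Unit bookkeeping: E [kPa] = 1e3 Pa, I [mm^4] = 1e-12 m^4, delta [um] =
    1e-6 m, L [mm] = 1e-3 m; the combination lands at 1e-15 N per unit, i.e.
    1e-9 uN, handled below.
    """
    if isinstance(track_or_deflection_um, PostTrack):
        delta_um = track_or_deflection_um.deflection_um
        t = track_or_deflection_um.t
    else:
        delta_um = np.asarray(track_or_deflection_um, dtype=float)
        if t is None:
            raise ValueError("supply a time axis for a bare deflection array")
    e_pa = post.elastic_modulus_kpa * 1e3
    i_m4 = post.second_moment_mm4 * 1e-12
    l_m = post.length_mm * 1e-3
    force_n = 3.0 * e_pa * i_m4 * (delta_um * 1e-6) / l_m**3
    return ForceTrace(t=np.asarray(t, dtype=float), force_un=force_n * 1e6)


def twitch_metrics(
    force: ForceTrace,
    pacing_hz: float | None = None,
    cfg: BeatDetectionConfig | None = None,
) -> tuple[pd.DataFrame, TwitchMetrics]:
    """Twitch readouts of a force trace.

    Beat segmentation is delegated to the motion-signal machinery: the
    unsigned force rate |dF/dt| is a two-lobe speed trace per twitch
    (contraction upstroke, relaxation decay), so the same cycle detector
    applies. Developed force = mean over twitches of (peak force - preceding
    diastolic baseline); the velocity readouts are per-phase statistics of
    |dF/dt| in uN/s.
    """
    t, f = force.t, force.force_un
    if len(t) < 4:
        raise ValueError("force trace too short")
    speed = np.abs(np.gradient(f, t))
    sig = MotionSignal(t=t, v=speed, units="signal_per_s", source_id="force-rate")
    cfg = cfg or BeatDetectionConfig(pacing_hz=pacing_hz)
    beats = beatkinetics.detect_beats(sig, cfg)
    if not beats:
        return pd.DataFrame(), TwitchMetrics(
            developed_force_un=np.nan,
            beat_rate_bpm=np.nan,
            mean_contraction_velocity=np.nan,
            max_contraction_velocity=np.nan,
            mean_relaxation_velocity=np.nan,
            max_relaxation_velocity=np.nan,
            n_twitches=0,
        )
    per_beat, summary = beatkinetics.extract_metrics(sig, beats, cfg)
    diastolic = beatkinetics.rolling_baseline(
        f, window=max(5, len(f) // 4), percentile=10.0
    )
    developed = []
    for b in beats:
        peak_f = float(np.max(f[b.start_idx : b.end_idx + 1]))
        developed.append(peak_f - float(diastolic[b.start_idx]))
    per_beat = per_beat.assign(developed_force_un=developed)
    metrics = TwitchMetrics(
        developed_force_un=float(np.mean(developed)),
        beat_rate_bpm=summary.beat_rate_bpm,
        mean_contraction_velocity=summary.mean_contraction_velocity,
        max_contraction_velocity=summary.max_contraction_velocity,
        mean_relaxation_velocity=summary.mean_relaxation_velocity,
        max_relaxation_velocity=summary.max_relaxation_velocity,
        n_twitches=len(beats),
    )
    return per_beat, metrics


def normalize_timecourse(
    records: pd.DataFrame,
    value_col: str = "value",
    baseline_h: float = 0.0,
) -> pd.DataFrame:
    """Normalize a transfection time course per tissue.

    For post-transfection timepoints the ratio is value(t) / value(0 h) of
    the same tissue. The 0 h records themselves are expressed relative to the
    group mean of all 0 h values, so baseline spread remains visible while
    later timepoints read as fold change over the tissue's own baseline.
    Tissues with a zero or missing baseline are excluded with a diagnostic.

    ``records`` needs columns tissue_id, group, timepoint_h and ``value_col``.
    """
    for col in ("tissue_id", "group", "timepoint_h", value_col):
        if col not in records.columns:
            raise ValueError(f"missing column: {col}")
    out = records.copy()
    base = (
        out[out["timepoint_h"] == baseline_h]
        .set_index("tissue_id")[value_col]
        .to_dict()
    )
    missing = sorted(set(out["tissue_id"]) - set(base))
    if missing:
        raise ValueError(f"tissue(s) without a {baseline_h} h baseline: {missing}")
    zero = sorted(tid for tid, v in base.items() if v == 0 or pd.isna(v))
    if zero:
        warnings.warn(
            f"excluding tissue(s) with zero/missing baseline: {zero}", stacklevel=2
        )
        out = out[~out["tissue_id"].isin(zero)].copy()
    group_base = (
        out[out["timepoint_h"] == baseline_h]
        .groupby("group")[value_col]
        .mean()
        .to_dict()
    )
    ratios = np.empty(len(out))
    for i, (_, row) in enumerate(out.iterrows()):
        if row["timepoint_h"] == baseline_h:
            ratios[i] = row[value_col] / group_base[row["group"]]
        else:
            ratios[i] = row[value_col] / base[row["tissue_id"]]
    out["normalized_ratio"] = ratios
    return out
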