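"""Beat-cycle detection and contractility readouts from motion signals.

The motion-amplitude trace of a beating monolayer is an unsigned speed: every
twitch appears as a contraction-speed lobe followed by a relaxation-speed
lobe, separated by a quiescent interval. A beat cycle therefore pairs one
contraction peak with the next relaxation peak inside the same active burst.

Per-beat readouts follow the screening convention: amplitude of contraction
(time-integral of speed over the contraction phase — a displacement proxy),
beating frequency, maximum and mean per-phase velocities, the whole-cycle
contraction-time integral (AUC), the 10%-to-90% contraction time, the
90%-to-10% relaxation time, and the peak duration (10%-to-10% width of the
twitch complex by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import MotionSignal

__all__ = [
    "BeatCycle",
    "BeatDetectionConfig",
    "ContractilityMetrics",
    "TransientMetrics",
    "detect_beats",
    "extract_metrics",
    "averaged_cycle",
    "transient_metrics",
]


@dataclass(frozen=True)
class BeatCycle:
    """Sample-index landmarks of one beat on an unsigned speed trace."""

    start_idx: int
    contraction_peak_idx: int
    trough_idx: int
    relaxation_peak_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        ordered = (
            self.start_idx
            <= self.contraction_peak_idx
            <= self.trough_idx
            <= self.relaxation_peak_idx
            <= self.end_idx
        )
        if not ordered:
            raise ValueError("beat landmarks must be ordered in time")


@dataclass(frozen=True)
class BeatDetectionConfig:
    """Detection thresholds.

    prominence_k : peak prominence in units of the robust (MAD-based) SD of
        the signal.
    min_distance_frac : minimum distance between peaks as a fraction of the
        expected period — only enforced when ``pacing_hz`` is supplied (the
        macrotissue recordings are paced).
    active_frac : burst threshold as a fraction of the 95th-percentile
        amplitude above baseline; a beat is an above-threshold burst holding
        both lobes.
    merge_gap_frac : bursts separated by less than this fraction of the
        expected period are merged — the speed trace touches zero at the
        contraction/relaxation turning point inside a beat, which must not
        split the beat in two.
    baseline_percentile / baseline_window_periods : rolling-percentile
        baseline over a window of N expected periods.
    """

    prominence_k: float = 4.0
    min_distance_frac: float = 0.25
    pacing_hz: float | None = None
    active_frac: float = 0.12
    merge_gap_frac: float = 0.25
    baseline_percentile: float = 10.0
    baseline_window_periods: float = 2.0
    peak_width_frac: float = 0.10  # 10%-to-10% peak-duration convention


def robust_sd(x: np.ndarray) -> float:
    """SD estimate from the median absolute deviation (Gaussian-consistent)."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def rolling_baseline(
    v: np.ndarray, window: int, percentile: float = 10.0
) -> np.ndarray:
    """Rolling low-percentile baseline (centered window, edge-padded)."""
    window = max(3, int(window))
    s = pd.Series(v)
    base = (
        s.rolling(window, center=True, min_periods=1)
        .quantile(percentile / 100.0)
        .to_numpy()
    )
    return base


def _expected_period_samples(
    sig: MotionSignal, cfg: BeatDetectionConfig, peaks: np.ndarray
) -> float:
    if cfg.pacing_hz:
        return 1.0 / cfg.pacing_hz / sig.dt
    if len(peaks) > 2:
        # two speed peaks per beat: every-other-peak spacing is one period
        return float(np.median(peaks[2:] - peaks[:-2]))
    return max(len(sig.v) / 4.0, 3.0)


def detect_beats(
    sig: MotionSignal, cfg: BeatDetectionConfig | None = None
) -> list[BeatCycle]:
    """Segment a motion-amplitude trace into beat cycles.

    Peaks with prominence above ``prominence_k`` robust-SDs are grouped into
    contiguous above-threshold bursts; each burst containing at least two
    peaks becomes one cycle (first prominent peak = contraction, last
    prominent peak = relaxation, inter-peak minimum = trough). Bursts clipped
    by the signal edges are discarded. A flat trace yields an empty list.
    """
    cfg = cfg or BeatDetectionConfig()
    v = sig.v
    if len(v) < 3:
        raise ValueError("signal too short for beat detection")
    sd = robust_sd(v)
    span = float(np.percentile(v, 99) - np.median(v))
    if sd == 0 and span == 0:
        return []
    prominence = cfg.prominence_k * sd if sd > 0 else 0.1 * span
    distance = None
    if cfg.pacing_hz:
        distance = max(1, int(cfg.min_distance_frac / cfg.pacing_hz / sig.dt))
    peaks, props = find_peaks(v, prominence=prominence, distance=distance)
    if len(peaks) < 2:
        return []

    period_samples = _expected_period_samples(sig, cfg, peaks)
    base = rolling_baseline(
        v,
        window=period_samples * cfg.baseline_window_periods,
        percentile=cfg.baseline_percentile,
    )
    amp = float(np.percentile(v[peaks], 95) - np.median(base))
    thr = base + cfg.active_frac * amp

    active = v > thr
    # contiguous active runs
    runs = []
    i = 0
    while i < len(v):
        if active[i]:
            j = i
            while j + 1 < len(v) and active[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs split by the intra-beat trough (speed touches zero between
    # the contraction and relaxation lobes)
    merge_gap = cfg.merge_gap_frac * period_samples
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    runs = merged

    cycles: list[BeatCycle] = []
    prom_by_peak = dict(zip(peaks.tolist(), props["prominences"].tolist()))
    # the rolling baseline is unreliable within a couple of samples of the
    # record edges, so treat bursts starting/ending there as clipped
    edge_guard = max(1, int(round(0.05 * period_samples)))
    for i0, j0 in runs:
        if i0 < edge_guard or j0 > len(v) - 1 - edge_guard:
            continue  # clipped by the record edge: incomplete cycle
        inside = [p for p in peaks if i0 <= p <= j0]
        if len(inside) < 2:
            continue
        if len(inside) > 2:
            # keep the two most prominent, in time order
            inside = sorted(
                sorted(inside, key=lambda p: -prom_by_peak[p])[:2]
            )
        c_peak, r_peak = inside[0], inside[1]
        trough = c_peak + int(np.argmin(v[c_peak : r_peak + 1]))
        # widen the window to the surrounding baseline crossings
        start = i0 - 1 if i0 > 0 else i0
        end = j0 + 1 if j0 < len(v) - 1 else j0
        cycles.append(
            BeatCycle(
                start_idx=start,
                contraction_peak_idx=int(c_peak),
                trough_idx=int(trough),
                relaxation_peak_idx=int(r_peak),
                end_idx=end,
            )
        )
    return cycles


@dataclass(frozen=True)
class ContractilityMetrics:
    """Mean-over-beats summary of the screening readouts."""

    amplitude: float
    beat_rate_bpm: float
    mean_contraction_velocity: float
    max_contraction_velocity: float
    mean_relaxation_velocity: float
    max_relaxation_velocity: float
    auc: float
    t_con_10_90_s: float
    t_rel_90_10_s: float
    peak_duration_s: float
    n_beats: int


def _crossing_times(
    t: np.ndarray, cum: np.ndarray, lo_frac: float, hi_frac: float
) -> float:
    """Time between ``lo_frac`` and ``hi_frac`` crossings of a cumulative curve."""
    total = cum[-1]
    if total <= 0:
        return np.nan
    t_lo = float(np.interp(lo_frac * total, cum, t))
    t_hi = float(np.interp(hi_frac * total, cum, t))
    return t_hi - t_lo


def _width_times(
    t: np.ndarray, v: np.ndarray, level: float
) -> tuple[float, float]:
    """First and last times at which ``v`` exceeds ``level`` (interpolated)."""
    above = v >= level
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return np.nan, np.nan
    i0, i1 = idx[0], idx[-1]
    t0 = t[i0]
    if i0 > 0 and v[i0] != v[i0 - 1]:
        t0 = t[i0 - 1] + (level - v[i0 - 1]) / (v[i0] - v[i0 - 1]) * (
            t[i0] - t[i0 - 1]
        )
    t1 = t[i1]
    if i1 < len(v) - 1 and v[i1] != v[i1 + 1]:
        t1 = t[i1] + (v[i1] - level) / (v[i1] - v[i1 + 1]) * (t[i1 + 1] - t[i1])
    return float(t0), float(t1)


def extract_metrics(
    sig: MotionSignal,
    beats: list[BeatCycle],
    cfg: BeatDetectionConfig | None = None,
) -> tuple[pd.DataFrame, ContractilityMetrics]:
    """Per-beat readout table and its mean-over-beats summary.

    The contraction phase of a beat runs from its start to the inter-peak
    trough, the relaxation phase from the trough to its end. Amplitude is the
    time-integral of speed over the contraction phase; AUC integrates the
    whole cycle.
    """
    if not beats:
        raise ValueError("no beats to extract metrics from")
    cfg = cfg or BeatDetectionConfig()
    t, v = sig.t, sig.v
    rows = []
    for b in beats:
        con = slice(b.start_idx, b.trough_idx + 1)
        rel = slice(b.trough_idx, b.end_idx + 1)
        whole = slice(b.start_idx, b.end_idx + 1)
        amp = float(np.trapezoid(v[con], t[con]))
        auc = float(np.trapezoid(v[whole], t[whole]))
        cum_con = np.concatenate(
            [[0.0], np.cumsum(np.diff(t[con]) * 0.5 * (v[con][1:] + v[con][:-1]))]
        )
        cum_rel = np.concatenate(
            [[0.0], np.cumsum(np.diff(t[rel]) * 0.5 * (v[rel][1:] + v[rel][:-1]))]
        )
        frac = cfg.peak_width_frac
        lvl_c = frac * v[b.contraction_peak_idx]
        lvl_r = frac * v[b.relaxation_peak_idx]
        t_up, _ = _width_times(t[con], v[con], lvl_c)
        _, t_down = _width_times(t[rel], v[rel], lvl_r)
        rows.append(
            {
                "t_peak_s": t[b.contraction_peak_idx],
                "amplitude": amp,
                "auc": auc,
                "max_contraction_velocity": float(np.max(v[con])),
                "mean_contraction_velocity": float(np.mean(v[con])),
                "max_relaxation_velocity": float(np.max(v[rel])),
                "mean_relaxation_velocity": float(np.mean(v[rel])),
                "t_con_10_90_s": _crossing_times(t[con], cum_con, 0.1, 0.9),
                "t_rel_90_10_s": _crossing_times(t[rel], cum_rel, 0.1, 0.9),
                "peak_duration_s": t_down - t_up,
            }
        )
    per_beat = pd.DataFrame(rows)
    if len(beats) >= 2:
        periods = np.diff(per_beat["t_peak_s"].to_numpy())
        beat_rate = 60.0 / float(np.median(periods))
    else:
        beat_rate = np.nan
    summary = ContractilityMetrics(
        amplitude=float(per_beat["amplitude"].mean()),
        beat_rate_bpm=beat_rate,
        mean_contraction_velocity=float(per_beat["mean_contraction_velocity"].mean()),
        max_contraction_velocity=float(per_beat["max_contraction_velocity"].mean()),
        mean_relaxation_velocity=float(per_beat["mean_relaxation_velocity"].mean()),
        max_relaxation_velocity=float(per_beat["max_relaxation_velocity"].mean()),
        auc=float(per_beat["auc"].mean()),
        t_con_10_90_s=float(per_beat["t_con_10_90_s"].mean()),
        t_rel_90_10_s=float(per_beat["t_rel_90_10_s"].mean()),
        peak_duration_s=float(per_beat["peak_duration_s"].mean()),
        n_beats=len(beats),
    )
    return per_beat, summary


def averaged_cycle(
    sig: MotionSignal, beats: list[BeatCycle], n_points: int = 101
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean contraction/relaxation cycle aligned on the contraction peak.

    Each cycle is split at its contraction peak; the pre-peak and post-peak
    segments are resampled to fixed lengths, so every cycle contributes the
    same number of points before and after the alignment landmark. Returns
    (relative position in [0, 1], pointwise mean, pointwise SD).
    """
    if len(beats) < 2:
        raise ValueError("need at least 2 beats to average")
    n_pre = n_points // 3
    n_post = n_points - n_pre
    stack = []
    for b in beats:
        pre = sig.v[b.start_idx : b.contraction_peak_idx + 1]
        post = sig.v[b.contraction_peak_idx : b.end_idx + 1]
        pre_r = np.interp(
            np.linspace(0, 1, n_pre), np.linspace(0, 1, max(len(pre), 2)),
            pre if len(pre) > 1 else np.repeat(pre, 2),
        )
        post_r = np.interp(
            np.linspace(0, 1, n_post), np.linspace(0, 1, max(len(post), 2)),
            post if len(post) > 1 else np.repeat(post, 2),
        )
        stack.append(np.concatenate([pre_r, post_r]))
    stack = np.asarray(stack)
    x = np.linspace(0.0, 1.0, n_pre + n_post)
    return x, stack.mean(axis=0), stack.std(axis=0)


# ------------------------------------------------------- calcium-style traces
@dataclass(frozen=True)
class TransientMetrics:
    """Generic fluorescence-transient readouts.

    ``falling_slope`` is signed (negative): the steepest instantaneous decay
    rate of the transient.
    """

    amplitude: float
    rising_slope: float
    falling_slope: float
    t_peak_s: float


def transient_metrics(
    t: np.ndarray,
    y: np.ndarray,
    prominence_k: float = 4.0,
    baseline_percentile: float = 10.0,
) -> list[TransientMetrics]:
    """Amplitude, rising slope and falling slope of each detected transient.

    Amplitude = peak minus the preceding baseline (rolling low percentile);
    rising slope = maximum first derivative on the upstroke; falling slope =
    minimum first derivative on the decay. A flat trace yields an empty list.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    sd = robust_sd(y)
    span = float(np.ptp(y))
    if span == 0:
        return []
    prominence = prominence_k * sd if sd > 0 else 0.1 * span
    peaks, _ = find_peaks(y, prominence=prominence)
    if len(peaks) == 0:
        return []
    base = rolling_baseline(y, window=max(5, len(y) // 4), percentile=baseline_percentile)
    dydt = np.gradient(y, t)
    out = []
    bounds = np.concatenate([[0], (peaks[:-1] + peaks[1:]) // 2, [len(y) - 1]])
    for i, p in enumerate(peaks):
        lo, hi = int(bounds[i]), int(bounds[i + 1])
        up = slice(lo, p + 1)
        down = slice(p, hi + 1)
        out.append(
            TransientMetrics(
                amplitude=float(y[p] - base[p]),
                rising_slope=float(np.max(dydt[up])),
                falling_slope=float(np.min(dydt[down])),
                t_peak_s=float(t[p]),
            )
        )
    return out
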