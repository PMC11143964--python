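"""Single-cell staircase-stretch mechanics.

A micropatterned, rod-shaped cardiomyocyte (120 x 30 um islands) is glued
between a force transducer and a piezo motor and stretched in a staircase:
repeated ramps of ``step_size_um`` at ``ramp_velocity_um_s``, each followed by
a hold of ``step_interval_s``. The stress during each hold is decomposed into

* peak stress        — maximal stress around the end of the ramp
                       (elastic + viscous contributions),
* steady-state stress — the equilibrated stress late in the hold
                       (purely elastic), and
* relaxation stress  — peak minus steady state (the viscous response).

The minimal constitutive law exhibiting exactly this decomposition is the
standard linear solid (Zener) model: a spring ``E_parallel`` in parallel with
a Maxwell arm (spring ``E_series`` in series with a dashpot ``eta``,
time constant ``tau = eta / E_series``). Its exact staircase response is
implemented here both as the synthetic-data forward model and as the model
fitted back to measured traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "StretchProtocol",
    "CellGeometry",
    "SLSParams",
    "StressTrace",
    "StepWindow",
    "StepMechanics",
    "StepMechanicsConfig",
    "SLSFit",
    "sls_staircase_response",
    "segment_staircase",
    "step_mechanics",
    "stress_from_force",
    "length_tension",
    "fit_sls",
]


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class StretchProtocol:
    """Commanded staircase-stretch protocol of the piezo motor.

    Defaults follow the single-cell distensibility protocol: 6 um increments
    at 62.5 um/s, one step every 10 s, on a 120 um long cell (so each step is
    a 5% strain increment).
    """

    step_size_um: float = 6.0
    ramp_velocity_um_s: float = 62.5
    step_interval_s: float = 10.0
    n_steps: int = 5
    initial_length_um: float = 120.0

    def __post_init__(self) -> None:
        for name in (
            "step_size_um",
            "ramp_velocity_um_s",
            "step_interval_s",
            "initial_length_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.ramp_duration_s >= self.step_interval_s:
            raise ValueError("ramp must finish within the step interval")

    @property
    def ramp_duration_s(self) -> float:
        return self.step_size_um / self.ramp_velocity_um_s

    @property
    def strain_increment(self) -> float:
        """Strain added per step (dimensionless)."""
        return self.step_size_um / self.initial_length_um

    def cumulative_strain(self, k: int) -> float:
        """Cumulative strain after ``k`` completed steps (exact bookkeeping)."""
        return k * self.step_size_um / self.initial_length_um

    @property
    def total_duration_s(self) -> float:
        return self.n_steps * self.step_interval_s


@dataclass(frozen=True)
class CellGeometry:
    """Micropatterned cell geometry used to convert force to stress."""

    length_um: float = 120.0
    width_um: float = 30.0
    thickness_um: float = 10.0

    def __post_init__(self) -> None:
        if min(self.length_um, self.width_um, self.thickness_um) <= 0:
            raise ValueError("all geometry dimensions must be positive")

    @property
    def cross_section_um2(self) -> float:
        return self.width_um * self.thickness_um


@dataclass(frozen=True)
class SLSParams:
    """Standard-linear-solid (Zener) parameters.

    ``e_parallel_kpa`` is the equilibrium spring; the Maxwell arm is
    ``e_series_kpa`` in series with viscosity ``eta_kpa_s``;
    ``tau = eta / E_series`` is the relaxation time constant.
    """

    e_parallel_kpa: float
    e_series_kpa: float
    eta_kpa_s: float

    def __post_init__(self) -> None:
        if min(self.e_parallel_kpa, self.e_series_kpa, self.eta_kpa_s) <= 0:
            raise ValueError("all SLS parameters must be strictly positive")

    @property
    def tau_s(self) -> float:
        return self.eta_kpa_s / self.e_series_kpa

    @classmethod
    def from_tau(
        cls, e_parallel_kpa: float, e_series_kpa: float, tau_s: float
    ) -> "SLSParams":
        return cls(e_parallel_kpa, e_series_kpa, tau_s * e_series_kpa)


@dataclass
class StressTrace:
    """A stress (or force) time series from a staircase-stretch experiment."""

    t: np.ndarray
    stress_kpa: np.ndarray
    strain_schedule: np.ndarray | None = None  # cumulative strain per step
    source_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.stress_kpa = np.asarray(self.stress_kpa, dtype=float)
        if self.t.shape != self.stress_kpa.shape or self.t.ndim != 1:
            raise ValueError("t and stress must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.strain_schedule is not None:
            ss = np.asarray(self.strain_schedule, dtype=float)
            if np.any(np.diff(ss) < 0):
                raise ValueError("scheduled strain must be non-decreasing")
            self.strain_schedule = ss

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.t, "stress_kpa": self.stress_kpa}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "StressTrace":
        df = pd.read_csv(path, comment="#")
        col = "stress_kpa" if "stress_kpa" in df else df.columns[1]
        return cls(t=df["time_s"].to_numpy(), stress_kpa=df[col].to_numpy(),
                   source_id=str(path))


@dataclass(frozen=True)
class StepWindow:
    """Sample-index windows of one staircase step (ramp then hold)."""

    step_index: int
    ramp: slice
    hold: slice
    strain: float  # cumulative strain during the hold


@dataclass(frozen=True)
class StepMechanics:
    """Peak / steady-state / relaxation decomposition of one step."""

    step_index: int
    strain_pct: float
    peak_stress_kpa: float
    steady_state_stress_kpa: float
    flagged: bool = False

    @property
    def relaxation_stress_kpa(self) -> float:
        # definition identity: viscous response = peak - steady state
        return self.peak_stress_kpa - self.steady_state_stress_kpa


@dataclass(frozen=True)
class StepMechanicsConfig:
    """Windows for the per-step decomposition.

    peak stress is searched over the ramp plus the first ``peak_extra_s`` of
    the hold; steady-state stress is averaged over the final
    ``steady_window_s`` of the hold. ``despike`` median-filters the steady
    window first (for traces with spontaneous twitches riding on the holds).
    """

    peak_extra_s: float = 0.5
    steady_window_s: float = 2.0
    despike: bool = False
    despike_kernel_s: float = 0.5
    noise_flag_cv: float = 0.1  # flag steady estimate when CV exceeds this


# ------------------------------------------------------------ forward model
def _strain_and_maxwell(
    t: np.ndarray, params: SLSParams, protocol: StretchProtocol
) -> tuple[np.ndarray, np.ndarray]:
    """Exact strain schedule and Maxwell-arm stress at times ``t``.

    The Maxwell arm obeys ``s' + s/tau = E_series * strain_rate``; on each
    linear ramp (rate R) the exact solution is
    ``s(t) = s0 e^{-dt/tau} + E_series R tau (1 - e^{-dt/tau})`` and on each
    hold it decays as ``s0 e^{-dt/tau}``. Integrating piecewise segment by
    segment is exact (no ODE solver error).
    """
    tau = params.tau_s
    rate = protocol.ramp_velocity_um_s / protocol.initial_length_um
    t_ramp = protocol.ramp_duration_s
    d_eps = protocol.strain_increment

    strain = np.zeros_like(t)
    s_m = np.zeros_like(t)
    s0 = 0.0  # Maxwell stress carried across segments
    for k in range(protocol.n_steps):
        t0 = k * protocol.step_interval_s
        t1 = t0 + t_ramp
        t2 = (k + 1) * protocol.step_interval_s
        eps0 = k * d_eps
        in_ramp = (t >= t0) & (t < t1)
        dt_r = t[in_ramp] - t0
        strain[in_ramp] = eps0 + rate * dt_r
        s_m[in_ramp] = s0 * np.exp(-dt_r / tau) + params.e_series_kpa * rate * tau * (
            1.0 - np.exp(-dt_r / tau)
        )
        s_ramp_end = s0 * np.exp(-t_ramp / tau) + params.e_series_kpa * rate * tau * (
            1.0 - np.exp(-t_ramp / tau)
        )
        in_hold = (t >= t1) & (t < t2)
        dt_h = t[in_hold] - t1
        strain[in_hold] = eps0 + d_eps
        s_m[in_hold] = s_ramp_end * np.exp(-dt_h / tau)
        s0 = s_ramp_end * np.exp(-(t2 - t1) / tau)
    # times at/after the end of the protocol stay at final strain
    t_end = protocol.total_duration_s
    after = t >= t_end
    if np.any(after):
        strain[after] = protocol.n_steps * d_eps
        s_m[after] = s0 * np.exp(-(t[after] - t_end) / tau)
    return strain, s_m


def sls_staircase_response(
    t: np.ndarray, params: SLSParams, protocol: StretchProtocol
) -> np.ndarray:
    """Noise-free SLS stress (kPa) under the staircase protocol at times ``t``."""
    strain, s_m = _strain_and_maxwell(np.asarray(t, dtype=float), params, protocol)
    return params.e_parallel_kpa * strain + s_m


def sls_step_truth(
    params: SLSParams, protocol: StretchProtocol
) -> list[StepMechanics]:
    """Analytic per-step decomposition of the noise-free staircase response.

    Peak is the model stress at ramp end; steady state is the model stress at
    the end of the hold (-> ``E_parallel * strain`` once the hold is long
    compared with tau).
    """
    out = []
    for k in range(protocol.n_steps):
        t_peak = k * protocol.step_interval_s + protocol.ramp_duration_s
        t_end = (k + 1) * protocol.step_interval_s
        peak, steady = sls_staircase_response(
            np.array([t_peak, t_end - 1e-12]), params, protocol
        )
        out.append(
            StepMechanics(
                step_index=k,
                strain_pct=100.0 * protocol.cumulative_strain(k + 1),
                peak_stress_kpa=float(peak),
                steady_state_stress_kpa=float(steady),
            )
        )
    return out


# ------------------------------------------------------------------ analysis
def segment_staircase(
    trace: StressTrace, protocol: StretchProtocol
) -> list[StepWindow]:
    """Split a trace into (ramp, hold) windows from the commanded protocol clock.

    Segmentation trusts the motor schedule rather than inferring ramps from
    the stress signal (robust at low signal-to-noise). The trace must cover
    the full protocol; otherwise the number of complete steps found is
    reported in the error.
    """
    t = trace.t - trace.t[0]
    # a step is complete when sampling reaches the end of its hold
    # (to within one sample interval)
    dt = float(np.median(np.diff(t)))
    n_complete = int(np.floor((t[-1] + dt + 1e-9) / protocol.step_interval_s))
    if n_complete < protocol.n_steps:
        raise ValueError(
            f"trace covers only {n_complete} complete steps of the "
            f"{protocol.n_steps}-step protocol"
        )
    windows = []
    for k in range(protocol.n_steps):
        t0 = k * protocol.step_interval_s
        t1 = t0 + protocol.ramp_duration_s
        t2 = (k + 1) * protocol.step_interval_s
        i0, i1, i2 = np.searchsorted(t, [t0, t1, t2])
        windows.append(
            StepWindow(
                step_index=k,
                ramp=slice(i0, max(i1, i0 + 1)),
                hold=slice(max(i1, i0 + 1), max(i2, i1 + 1)),
                strain=protocol.cumulative_strain(k + 1),
            )
        )
    return windows


def step_mechanics(
    trace: StressTrace,
    windows: list[StepWindow],
    cfg: StepMechanicsConfig | None = None,
) -> list[StepMechanics]:
    """Measure peak / steady-state / relaxation stress for each step."""
    cfg = cfg or StepMechanicsConfig()
    dt = float(np.median(np.diff(trace.t)))
    n_extra = int(round(cfg.peak_extra_s / dt))
    n_steady = max(1, int(round(cfg.steady_window_s / dt)))
    out = []
    for w in windows:
        peak_stop = min(w.hold.start + n_extra, w.hold.stop)
        seg = trace.stress_kpa[w.ramp.start : peak_stop]
        peak = float(np.max(seg)) if len(seg) else float("nan")
        hold = trace.stress_kpa[w.hold]
        tail = hold[-n_steady:] if len(hold) >= n_steady else hold
        if cfg.despike and len(tail) > 3:
            from scipy.signal import medfilt

            k = int(round(cfg.despike_kernel_s / dt)) | 1  # odd kernel
            k = min(k, (len(tail) - 1) | 1)
            tail = medfilt(tail, kernel_size=max(3, k))
        steady = float(np.mean(tail))
        sd = float(np.std(tail))
        flagged = bool(
            steady != 0 and sd / max(abs(steady), 1e-12) > cfg.noise_flag_cv
        )
        out.append(
            StepMechanics(
                step_index=w.step_index,
                strain_pct=100.0 * w.strain,
                peak_stress_kpa=peak,
                steady_state_stress_kpa=steady,
                flagged=flagged,
            )
        )
    return out


def stress_from_force(
    force_un: np.ndarray | float, geometry: CellGeometry
) -> np.ndarray | float:
    """Convert axial force (uN) to engineering stress (kPa).

    sigma = F / A; 1 uN / um^2 = 1 MPa, hence the factor 1000 to kPa.
    """
    area = geometry.cross_section_um2
    if area <= 0:
        raise ValueError("cross-sectional area must be positive")
    return np.asarray(force_un, dtype=float) * 1000.0 / area if np.ndim(
        force_un
    ) else float(force_un) * 1000.0 / area


def length_tension(steps: list[StepMechanics]) -> tuple[pd.DataFrame, float]:
    """Length-tension curve and its monotonicity.

    Returns the per-strain table (sorted by strain) and the Spearman rank
    correlation of steady-state stress against strain — positive when the
    cell follows the Frank-Starling relationship (tension rising with
    stretch).
    """
    if len(steps) < 2:
        raise ValueError("need at least 2 steps for a length-tension curve")
    df = pd.DataFrame(
        {
            "strain_pct": [s.strain_pct for s in steps],
            "peak_stress_kpa": [s.peak_stress_kpa for s in steps],
            "steady_state_stress_kpa": [s.steady_state_stress_kpa for s in steps],
            "relaxation_stress_kpa": [s.relaxation_stress_kpa for s in steps],
        }
    ).sort_values("strain_pct", ignore_index=True)
    rho = stats.spearmanr(df["strain_pct"], df["steady_state_stress_kpa"]).statistic
    return df, float(rho)


# ----------------------------------------------------------------- model fit
@dataclass
class SLSFit:
    """Result of fitting the SLS model to a staircase trace."""

    params: SLSParams
    tau_identifiable: bool
    residual_rms_kpa: float
    diagnostics: dict = field(default_factory=dict)


def _initial_estimates(
    trace: StressTrace, windows: list[StepWindow], protocol: StretchProtocol
) -> tuple[float, float, float]:
    """Closed-form starting values: E_parallel from the steady-vs-strain
    slope, tau from a log-linear fit of the first hold decay, E_series from
    the ramp-corrected relaxation amplitude."""
    steps = step_mechanics(trace, windows)
    strain = np.array([w.strain for w in windows])
    steady = np.array([s.steady_state_stress_kpa for s in steps])
    e_par = max(float(np.polyfit(strain, steady, 1)[0]), 1e-6)

    # tau: log-linear fit of (stress - steady) on the first hold
    w0, s0 = windows[0], steps[0]
    hold_t = trace.t[w0.hold] - trace.t[w0.hold.start]
    hold_y = trace.stress_kpa[w0.hold] - s0.steady_state_stress_kpa
    pos = hold_y > max(1e-9, 0.02 * abs(s0.relaxation_stress_kpa))
    if pos.sum() >= 3:
        slope = np.polyfit(hold_t[pos], np.log(hold_y[pos]), 1)[0]
        tau = -1.0 / slope if slope < 0 else trace.duration_s
    else:
        tau = trace.duration_s
    tau = float(np.clip(tau, 1e-3, 100.0 * trace.duration_s))

    # E_series: mean relaxation amplitude corrected for the finite ramp
    t_r = protocol.ramp_duration_s
    ramp_factor = (tau / t_r) * (1.0 - np.exp(-t_r / tau))
    relax = np.array([s.relaxation_stress_kpa for s in steps])
    d_eps = protocol.strain_increment
    e_ser = max(float(np.mean(relax)) / (d_eps * ramp_factor), 1e-6)
    return e_par, e_ser, tau


def fit_sls(
    trace: StressTrace,
    protocol: StretchProtocol,
    windows: list[StepWindow] | None = None,
) -> SLSFit:
    """Estimate SLS parameters (E_parallel, E_series, tau) from a staircase trace.

    Closed-form initial estimates are refined by a bounded least-squares fit
    of the exact piecewise staircase response to the whole trace. tau is
    flagged unidentifiable when the fitted value exceeds the trace duration
    (no complete relaxation is observed within the record); the moduli are
    still reported.
    """
    if windows is None:
        windows = segment_staircase(trace, protocol)
    if len(windows) < 1:
        raise ValueError("no staircase steps to fit")

    e_par0, e_ser0, tau0 = _initial_estimates(trace, windows, protocol)
    t = trace.t - trace.t[0]
    y = trace.stress_kpa

    def residuals(theta):
        e_par, e_ser, tau = theta
        p = SLSParams.from_tau(e_par, e_ser, tau)
        return sls_staircase_response(t, p, protocol) - y

    upper_tau = 1e4 * trace.duration_s
    res = optimize.least_squares(
        residuals,
        x0=[e_par0, e_ser0, min(tau0, upper_tau)],
        bounds=([1e-9, 1e-9, 1e-6], [np.inf, np.inf, upper_tau]),
        method="trf",
    )
    e_par, e_ser, tau = res.x
    params = SLSParams.from_tau(float(e_par), float(e_ser), float(tau))
    identifiable = bool(tau < trace.duration_s)
    if not identifiable:
        warnings.warn(
            "relaxation time constant exceeds the trace duration; "
            "tau is unidentifiable from this record",
            stacklevel=2,
        )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return SLSFit(
        params=params,
        tau_identifiable=identifiable,
        residual_rms_kpa=rms,
        diagnostics={
            "initial": {"e_parallel": e_par0, "e_series": e_ser0, "tau": tau0},
            "cost": float(res.cost),
            "success": bool(res.success),
        },
    )
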