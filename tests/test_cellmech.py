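"""Staircase segmentation, stress decomposition and SLS recovery."""

import warnings

import numpy as np
import pytest

from cardiomotion import cellmech, synthgen
from cardiomotion.cellmech import (
    CellGeometry,
    SLSParams,
    StepMechanicsConfig,
    StressTrace,
    StretchProtocol,
)


class TestProtocol:
    def test_default_step_is_five_percent_strain(self, default_protocol):
        assert default_protocol.strain_increment == pytest.approx(0.05)

    def test_cumulative_strain_bookkeeping_is_exact(self, default_protocol):
        for k in range(1, 6):
            assert default_protocol.cumulative_strain(k) == k * 6.0 / 120.0

    def test_ramp_must_fit_in_interval(self):
        with pytest.raises(ValueError, match="ramp"):
            StretchProtocol(step_size_um=100.0, ramp_velocity_um_s=5.0,
                            step_interval_s=10.0)


class TestSegmentation:
    def test_schedule_arithmetic(self, unit_sls):
        proto = StretchProtocol(n_steps=5)
        trace, _ = synthgen.generate_staircase_trace(unit_sls, proto, seed=0)
        windows = cellmech.segment_staircase(trace, proto)
        assert len(windows) == 5
        for a, b in zip(windows, windows[1:]):
            assert a.hold.stop <= b.ramp.start + 1

    def test_short_trace_rejected_with_step_count(self, unit_sls):
        proto = StretchProtocol(n_steps=5)
        trace, _ = synthgen.generate_staircase_trace(unit_sls, proto, seed=0)
        cut = StressTrace(t=trace.t[:2500], stress_kpa=trace.stress_kpa[:2500])
        with pytest.raises(ValueError, match="2 complete steps"):
            cellmech.segment_staircase(cut, proto)

    def test_windows_align_with_generator_holds(self, unit_sls):
        proto = StretchProtocol(n_steps=3)
        trace, _ = synthgen.generate_staircase_trace(
            unit_sls, proto, seed=0, sample_rate_hz=100.0
        )
        windows = cellmech.segment_staircase(trace, proto)
        for k, w in enumerate(windows):
            t_ramp_start = k * proto.step_interval_s
            assert trace.t[w.ramp.start] == pytest.approx(t_ramp_start, abs=0.011)
            assert trace.t[w.hold.start] == pytest.approx(
                t_ramp_start + proto.ramp_duration_s, abs=0.011
            )


class TestStepMechanics:
    def test_instant_ramp_closed_form_decomposition(self, unit_sls):
        proto = StretchProtocol(n_steps=1, ramp_velocity_um_s=6e6)
        trace, _ = synthgen.generate_staircase_trace(
            unit_sls, proto, seed=0, sample_rate_hz=1000.0
        )
        steps = cellmech.step_mechanics(
            trace, cellmech.segment_staircase(trace, proto)
        )
        s = steps[0]
        assert s.peak_stress_kpa == pytest.approx(0.10, abs=2e-3)
        assert s.steady_state_stress_kpa == pytest.approx(0.05, abs=1e-3)
        assert s.relaxation_stress_kpa == pytest.approx(0.05, abs=3e-3)

    def test_decomposition_identity_is_exact(self, unit_sls, default_protocol):
        trace, _ = synthgen.generate_staircase_trace(
            unit_sls, default_protocol, noise_sd_kpa=0.02, seed=3
        )
        steps = cellmech.step_mechanics(
            trace, cellmech.segment_staircase(trace, default_protocol)
        )
        for s in steps:
            assert s.relaxation_stress_kpa == (
                s.peak_stress_kpa - s.steady_state_stress_kpa
            )

    def test_pure_spring_has_zero_relaxation(self, default_protocol):
        # a near-instantaneous Maxwell arm relaxes within one sample:
        # only the parallel spring remains visible
        sls = SLSParams.from_tau(1.0, 1.0, 1e-4)
        trace, _ = synthgen.generate_staircase_trace(
            sls, default_protocol, seed=0
        )
        steps = cellmech.step_mechanics(
            trace, cellmech.segment_staircase(trace, default_protocol)
        )
        for s in steps:
            assert s.relaxation_stress_kpa == pytest.approx(0.0, abs=1e-6)

    def test_steady_estimate_error_scales_with_noise(self, unit_sls, default_protocol):
        sigma_n = 0.05
        cfg = StepMechanicsConfig()
        errors = []
        n_samples = int(cfg.steady_window_s * 100)
        for seed in range(30):
            trace, truth = synthgen.generate_staircase_trace(
                unit_sls, default_protocol, noise_sd_kpa=sigma_n, seed=seed
            )
            steps = cellmech.step_mechanics(
                trace, cellmech.segment_staircase(trace, default_protocol), cfg
            )
            errors.extend(
                abs(m.steady_state_stress_kpa - t.steady_state_stress_kpa)
                for m, t in zip(steps, truth)
            )
        bound = 3.0 * sigma_n / np.sqrt(n_samples)
        assert np.quantile(errors, 0.99) <= bound


class TestStressFromForce:
    def test_unit_arithmetic(self):
        geom = CellGeometry(thickness_um=10.0)  # area 300 um^2
        assert cellmech.stress_from_force(0.3, geom) == pytest.approx(1.0)
        assert cellmech.stress_from_force(0.0, geom) == 0.0

    def test_halving_area_doubles_stress(self):
        a = cellmech.stress_from_force(0.3, CellGeometry(thickness_um=10.0))
        b = cellmech.stress_from_force(0.3, CellGeometry(thickness_um=5.0))
        assert b == pytest.approx(2 * a)


class TestLengthTension:
    def test_sls_steady_stress_linear_in_strain(self, unit_sls, default_protocol):
        trace, _ = synthgen.generate_staircase_trace(
            unit_sls, default_protocol, seed=0
        )
        steps = cellmech.step_mechanics(
            trace, cellmech.segment_staircase(trace, default_protocol)
        )
        curve, rho = cellmech.length_tension(steps)
        assert rho == pytest.approx(1.0)
        coeffs = np.polyfit(
            curve["strain_pct"], curve["steady_state_stress_kpa"], 1
        )
        fit = np.polyval(coeffs, curve["strain_pct"])
        ss_res = np.sum((curve["steady_state_stress_kpa"] - fit) ** 2)
        ss_tot = np.sum(
            (curve["steady_state_stress_kpa"]
             - curve["steady_state_stress_kpa"].mean()) ** 2
        )
        assert 1 - ss_res / ss_tot > 0.999

    def test_order_invariance(self, unit_sls, default_protocol):
        trace, _ = synthgen.generate_staircase_trace(
            unit_sls, default_protocol, seed=0
        )
        steps = cellmech.step_mechanics(
            trace, cellmech.segment_staircase(trace, default_protocol)
        )
        a, _ = cellmech.length_tension(steps)
        b, _ = cellmech.length_tension(list(reversed(steps)))
        assert a.equals(b)

    def test_nonlinear_monotonic_data_still_positive(self):
        steps = [
            cellmech.StepMechanics(k, 5.0 * (k + 1), (0.05 * (k + 1)) ** 2 + 0.01,
                                   (0.05 * (k + 1)) ** 2)
            for k in range(5)
        ]
        _, rho = cellmech.length_tension(steps)
        assert rho == pytest.approx(1.0)


class TestFitSLS:
    def test_noiseless_recovery_below_one_percent(self, unit_sls, default_protocol):
        trace, _ = synthgen.generate_staircase_trace(
            unit_sls, default_protocol, seed=0
        )
        fit = cellmech.fit_sls(trace, default_protocol)
        assert fit.tau_identifiable
        assert fit.params.e_parallel_kpa == pytest.approx(1.0, rel=0.01)
        assert fit.params.e_series_kpa == pytest.approx(1.0, rel=0.01)
        assert fit.params.tau_s == pytest.approx(1.0, rel=0.01)

    def test_noisy_recovery_within_ten_percent_median(self, unit_sls, default_protocol):
        # noise sd = 5% of the final peak stress (~0.3 kPa)
        sigma = 0.05 * 0.30
        errs = []
        for seed in range(25):
            trace, _ = synthgen.generate_staircase_trace(
                unit_sls, default_protocol, noise_sd_kpa=sigma, seed=seed
            )
            fit = cellmech.fit_sls(trace, default_protocol)
            errs.append(
                max(
                    abs(fit.params.e_parallel_kpa - 1.0),
                    abs(fit.params.e_series_kpa - 1.0),
                    abs(fit.params.tau_s - 1.0),
                )
            )
        assert np.median(errs) < 0.10

    def test_long_tau_flagged_unidentifiable_moduli_recovered(self, default_protocol):
        sls = SLSParams.from_tau(1.0, 1.0, 500.0)
        trace, _ = synthgen.generate_staircase_trace(sls, default_protocol, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cellmech.fit_sls(trace, default_protocol)
        assert not fit.tau_identifiable
        assert fit.params.e_parallel_kpa == pytest.approx(1.0, rel=0.05)
        assert fit.params.e_series_kpa == pytest.approx(1.0, rel=0.05)
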