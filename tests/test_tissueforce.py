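"""Post tracking, cantilever force conversion and time-course normalization."""

import numpy as np
import pandas as pd
import pytest

from cardiomotion import synthgen, tissueforce
from cardiomotion.core import FrameSequence
from cardiomotion.synthgen import BeatWaveformParams, PostBlobSpec
from cardiomotion.tissueforce import PostGeometry, Roi


def _post_fixture(n_frames=300, noise_sd=0.0, seed=0, scale=1.0):
    tw = BeatWaveformParams(
        peak_contraction_velocity=30.0,
        peak_relaxation_velocity=20.0,
        contraction_duration_s=0.2,
        relaxation_duration_s=0.3,
        noise_sd=0.0,
        seed=seed,
    )
    seq, truth = synthgen.generate_post_track(
        tw, PostBlobSpec(), n_frames=n_frames, frame_interval_s=0.01,
        deflection_scale=scale, noise_sd=noise_sd,
    )
    rois = (Roi(4, 34, 60, 60), Roi(64, 34, 60, 60))
    return seq, truth, rois


class TestTrackPosts:
    def test_static_tips_give_zero_deflection(self):
        tw = BeatWaveformParams(
            peak_contraction_velocity=0.0, peak_relaxation_velocity=0.0, noise_sd=0.0
        )
        seq, _ = synthgen.generate_post_track(tw, PostBlobSpec(), n_frames=30)
        track = tissueforce.track_posts(
            seq, (Roi(4, 34, 60, 60), Roi(64, 34, 60, 60))
        )
        assert np.allclose(track.deflection_px, 0.0, atol=1e-6)

    def test_recovered_peak_to_peak_matches_truth(self):
        seq, truth, rois = _post_fixture()
        track = tissueforce.track_posts(seq, rois)
        assert track.deflection_px.max() == pytest.approx(
            truth["deflection_px"].max(), abs=0.1
        )

    def test_subpixel_centroid_accuracy(self):
        seq, truth, rois = _post_fixture()
        track = tissueforce.track_posts(seq, rois)
        err = track.deflection_px - truth["deflection_px"].to_numpy()
        assert np.sqrt(np.mean(err**2)) < 0.1

    def test_common_mode_drift_rejected(self):
        seq, truth, rois = _post_fixture(n_frames=120)
        # translate every frame by 2 px along x (stage drift)
        drifted = FrameSequence(
            frames=np.roll(seq.frames, 2, axis=2),
            frame_interval_s=seq.frame_interval_s,
        )
        rois_shifted = (Roi(6, 34, 60, 60), Roi(66, 34, 60, 60))
        a = tissueforce.track_posts(seq, rois)
        b = tissueforce.track_posts(drifted, rois_shifted)
        assert np.allclose(a.deflection_px, b.deflection_px, atol=0.05)


class TestDeflectionToForce:
    GEOM = PostGeometry(elastic_modulus_kpa=1700.0, length_mm=5.0, radius_mm=0.25)

    def test_zero_deflection_zero_force(self):
        f = tissueforce.deflection_to_force(np.zeros(5), self.GEOM, t=np.arange(5.0))
        assert np.all(f.force_un == 0.0)

    def test_hand_computed_cantilever_value(self):
        # F = 3 E I d / L^3 with E=1.7 MPa, r=0.25 mm, L=5 mm, d=10 um:
        # I = pi (0.25e-3)^4 / 4 = 3.06796e-15 m^4 -> F = 1.25173 uN
        f = tissueforce.deflection_to_force(np.array([10.0]), self.GEOM, t=[0.0])
        assert f.force_un[0] == pytest.approx(1.2517283, rel=1e-6)

    def test_linearity_in_deflection_and_modulus(self):
        d = np.array([5.0])
        f1 = tissueforce.deflection_to_force(d, self.GEOM, t=[0]).force_un[0]
        f2 = tissueforce.deflection_to_force(2 * d, self.GEOM, t=[0]).force_un[0]
        stiffer = PostGeometry(3400.0, 5.0, 0.25)
        f3 = tissueforce.deflection_to_force(d, stiffer, t=[0]).force_un[0]
        assert f2 == pytest.approx(2 * f1, rel=1e-12)
        assert f3 == pytest.approx(2 * f1, rel=1e-12)

    def test_geometry_must_be_positive(self):
        with pytest.raises(ValueError):
            PostGeometry(0.0, 5.0, 0.25)


class TestTwitchMetrics:
    def test_developed_force_on_synthetic_twitches(self):
        seq, truth, rois = _post_fixture(n_frames=400)
        track = tissueforce.track_posts(seq, rois)
        force = tissueforce.deflection_to_force(
            track.deflection_px, self_geom := TestDeflectionToForce.GEOM, t=track.t
        )
        per_beat, m = tissueforce.twitch_metrics(force, pacing_hz=1.0)
        assert m.n_twitches >= 2
        # truth: peak deflection -> peak force above the diastolic baseline
        peak_defl = truth["deflection_px"].max()
        expected = tissueforce.deflection_to_force(
            np.array([peak_defl]), self_geom, t=[0]
        ).force_un[0]
        assert m.developed_force_un == pytest.approx(expected, rel=0.1)
        assert m.beat_rate_bpm == pytest.approx(60.0, rel=0.05)

    def test_flat_force_trace_reports_no_twitches(self):
        force = tissueforce.ForceTrace(
            t=np.arange(100) * 0.01, force_un=np.zeros(100)
        )
        per_beat, m = tissueforce.twitch_metrics(force)
        assert m.n_twitches == 0
        assert per_beat.empty


class TestNormalizeTimecourse:
    def _records(self, values_by_tissue):
        rows = []
        for tid, (group, values) in values_by_tissue.items():
            for h, v in zip((0, 24, 48, 72), values):
                rows.append(
                    {
                        "tissue_id": tid,
                        "group": group,
                        "timepoint_h": h,
                        "value": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_constant_series_normalizes_to_one(self):
        rec = self._records({"T1": ("neg", [5.0] * 4), "T2": ("neg", [8.0] * 4)})
        out = tissueforce.normalize_timecourse(rec)
        post = out[out.timepoint_h > 0]
        assert np.allclose(post["normalized_ratio"], 1.0)

    def test_doubling_at_48h(self):
        rec = self._records({"T1": ("neg", [4.0, 4.0, 8.0, 4.0])})
        out = tissueforce.normalize_timecourse(rec)
        r48 = out[(out.tissue_id == "T1") & (out.timepoint_h == 48)]
        assert r48["normalized_ratio"].iloc[0] == pytest.approx(2.0)

    def test_baseline_expressed_relative_to_group_mean(self):
        rec = self._records(
            {"T1": ("neg", [4.0] * 4), "T2": ("neg", [12.0] * 4)}
        )
        out = tissueforce.normalize_timecourse(rec)
        h0 = out[out.timepoint_h == 0].set_index("tissue_id")["normalized_ratio"]
        assert h0["T1"] == pytest.approx(0.5)
        assert h0["T2"] == pytest.approx(1.5)

    def test_scale_invariance_per_tissue(self):
        rec = self._records({"T1": ("neg", [4.0, 5.0, 6.0, 7.0])})
        scaled = rec.assign(value=rec.value * 3.0)
        a = tissueforce.normalize_timecourse(rec)
        b = tissueforce.normalize_timecourse(scaled)
        post = a.timepoint_h > 0
        assert np.allclose(
            a.loc[post, "normalized_ratio"], b.loc[post, "normalized_ratio"]
        )

    def test_planted_group_trajectory_recovered(self):
        rng = np.random.default_rng(12)
        trajectory = np.array([1.0, 1.1, 1.3, 1.5])
        rows = {}
        for i in range(12):
            base = rng.uniform(3, 9)
            noise = rng.normal(1.0, 0.02, size=4)
            rows[f"T{i}"] = ("mir", base * trajectory * noise)
        out = tissueforce.normalize_timecourse(self._records(rows))
        for h, expected in zip((24, 48, 72), trajectory[1:]):
            got = out[out.timepoint_h == h]["normalized_ratio"].mean()
            assert got == pytest.approx(expected, rel=0.03)

    def test_missing_baseline_rejected(self):
        rec = self._records({"T1": ("neg", [4.0] * 4)})
        rec = rec[rec.timepoint_h != 0]
        with pytest.raises(ValueError, match="baseline"):
            tissueforce.normalize_timecourse(rec)

    def test_zero_baseline_excluded_with_diagnostic(self):
        rec = self._records(
            {"T1": ("neg", [0.0, 4.0, 4.0, 4.0]), "T2": ("neg", [2.0] * 4)}
        )
        with pytest.warns(UserWarning, match="zero"):
            out = tissueforce.normalize_timecourse(rec)
        assert "T1" not in set(out["tissue_id"])
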