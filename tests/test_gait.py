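"""Stride segmentation and gait parameters against closed-form generator values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import savgol_filter

import locoblink as lb
from locoblink.gait import (
    PAWS,
    PawTracks,
    StrideSet,
    align_trajectories,
    interlimb_params,
    limb_params,
    segment_strides,
    variability,
)

# generator config used throughout: belt 0.2 m/s, stride 0.3 s, duty 0.6
V, T, D = 0.2, 0.3, 0.6
FRAME = 1.0 / 400.0  # one frame period, s


class TestSegmentation:
    def test_round_trip_counts_and_durations(self, trot_tracks, trot_strides):
        for paw in PAWS:
            ss = trot_strides[paw]
            assert ss.n_strides == 10
            np.testing.assert_allclose(np.diff(ss.stance_onsets), T,
                                       atol=FRAME)
            np.testing.assert_allclose(np.diff(ss.swing_onsets), T,
                                       atol=FRAME)

    def test_constant_track_yields_no_strides(self):
        n = 400
        paws = {p: np.zeros((n, 3)) for p in PAWS}
        tracks = PawTracks(paws=paws, body_x=np.zeros(n), frame_rate=400.0)
        assert segment_strides(tracks, "FR").n_strides == 0

    def test_nan_rejected(self, trot_tracks):
        bad = PawTracks(
            paws={p: trot_tracks.paws[p].copy() for p in PAWS},
            body_x=trot_tracks.body_x.copy(), frame_rate=400.0,
            context="treadmill", belt_speed=0.2)
        bad.paws["FR"][10, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            segment_strides(bad, "FR")

    def test_noise_below_prominence_keeps_stride_count(self):
        clean = lb.gen_gait_session(lb.GaitSimConfig(seed=1))
        noisy = lb.gen_gait_session(lb.GaitSimConfig(noise_sd=1.0, seed=1))
        for paw in PAWS:
            assert (segment_strides(noisy, paw).n_strides
                    == segment_strides(clean, paw).n_strides)

    def test_alternation_enforced_by_constructor(self):
        with pytest.raises(ValueError, match="alternate"):
            StrideSet(np.array([0.0, 0.1]), np.array([0.3]))
        with pytest.raises(ValueError, match="increasing"):
            StrideSet(np.array([0.3, 0.1]), np.array([0.2]))


class TestLimbParams:
    def test_closed_form_values(self, trot_tracks, trot_strides):
        for paw in PAWS:
            p = limb_params(trot_strides[paw], trot_tracks, paw)
            assert len(p) == 9  # final stride has no closing touch-down
            assert p.attrs["n_dropped"] == 1
            np.testing.assert_allclose(p["stride_duration"], T, atol=FRAME)
            np.testing.assert_allclose(p["cadence"], 1 / T, rtol=0.01)
            np.testing.assert_allclose(p["duty_factor"], D, atol=0.02)
            np.testing.assert_allclose(p["stride_length"], V * T * 1000,
                                       atol=1.0)
            np.testing.assert_allclose(p["swing_velocity"], V / (1 - D),
                                       atol=0.02)

    def test_arithmetic_from_constructed_events(self):
        # stance 0.2 s + swing 0.1 s, swing displacement 60 mm
        fs = 1000.0
        n = 1500
        t = np.arange(n) / fs
        phase = (t / 0.3) % 1.0
        x = np.where(phase < 2 / 3,
                     30 - 90 * phase,  # stance: 30 -> -30 over 0.2 s
                     -30 + 180 * (phase - 2 / 3))  # swing: -30 -> 30 over 0.1 s
        paws = {p: np.column_stack([x, np.zeros(n), np.zeros(n)])
                for p in PAWS}
        tracks = PawTracks(paws=paws, body_x=np.zeros(n), frame_rate=fs,
                           context="overground")
        ss = segment_strides(tracks, "FR")
        p = limb_params(ss, tracks, "FR")
        assert p["stride_duration"].iloc[0] == pytest.approx(0.3, abs=2e-3)
        assert p["cadence"].iloc[0] == pytest.approx(3.333, abs=0.05)
        assert p["duty_factor"].iloc[0] == pytest.approx(2 / 3, abs=0.01)
        assert p["swing_velocity"].iloc[0] == pytest.approx(0.6, abs=0.02)

    def test_duty_factor_bounded(self, trot_tracks, trot_strides):
        p = limb_params(trot_strides["FR"], trot_tracks, "FR")
        assert p["duty_factor"].between(0, 1).all()

    def test_time_shift_invariance(self, trot_tracks):
        shifted = PawTracks(
            paws={p: trot_tracks.paws[p].copy() for p in PAWS},
            body_x=trot_tracks.body_x.copy(), frame_rate=400.0,
            context="treadmill", belt_speed=0.2)
        a = limb_params(segment_strides(trot_tracks, "FR"), trot_tracks, "FR")
        b = limb_params(segment_strides(shifted, "FR"), shifted, "FR")
        np.testing.assert_allclose(a["stride_duration"], b["stride_duration"])

    def test_x_translation_invariance(self, trot_tracks):
        moved = PawTracks(
            paws={p: trot_tracks.paws[p] + np.array([500.0, 0, 0])
                  for p in PAWS},
            body_x=trot_tracks.body_x.copy(), frame_rate=400.0,
            context="treadmill", belt_speed=0.2)
        a = limb_params(segment_strides(trot_tracks, "FR"), trot_tracks, "FR")
        b = limb_params(segment_strides(moved, "FR"), moved, "FR")
        np.testing.assert_allclose(a["stride_length"], b["stride_length"],
                                   atol=1e-6)


class TestInterlimbParams:
    def test_stance_phase_of_alternating_pair(self, trot_tracks, trot_strides):
        out = interlimb_params(trot_strides, trot_tracks)
        lr = out["stance_phase"].query("paw == 'FL'")["stance_phase"]
        np.testing.assert_allclose(lr, 0.5, atol=0.02)
        hl = out["stance_phase"].query("paw == 'HL'")["stance_phase"]
        np.testing.assert_allclose(hl, 0.0, atol=0.02)

    def test_symmetric_gait_has_equal_step_lengths(self, trot_tracks,
                                                   trot_strides):
        sl = interlimb_params(trot_strides, trot_tracks)["step_length"]
        fr = sl.query("paw == 'FR'")["step_length"].mean()
        fl = sl.query("paw == 'FL'")["step_length"].mean()
        assert fr == pytest.approx(fl, abs=0.5)

    def test_base_of_support_from_lateral_offsets(self, trot_tracks,
                                                  trot_strides):
        bos = interlimb_params(trot_strides, trot_tracks)["base_of_support"]
        np.testing.assert_allclose(bos["front"].dropna(), 20.0, atol=0.1)
        np.testing.assert_allclose(bos["hind"].dropna(), 20.0, atol=0.1)

    def test_double_support_trot(self, trot_tracks, trot_strides):
        # duty 0.6, phase 0.5: contralateral lift-off 10% into the cycle
        # (a record-boundary stride may miss the contralateral lift-off)
        ds = interlimb_params(trot_strides, trot_tracks)["double_support"]
        assert ds["double_support"].median() == pytest.approx(10.0, abs=1.0)
        close = np.isclose(ds["double_support"], 10.0, atol=1.0)
        assert close.mean() > 0.85

    def test_center_of_oscillation_symmetric(self, trot_tracks, trot_strides):
        co = interlimb_params(trot_strides, trot_tracks)[
            "center_of_oscillation"]
        np.testing.assert_allclose(co["center_of_oscillation"], 0.0, atol=0.5)

    def test_support_fractions_partition_stride(self, trot_tracks,
                                                trot_strides):
        sup = interlimb_params(trot_strides, trot_tracks)["supports"]
        cols = ["support_3paw", "support_2paw_diagonal", "support_2paw_other",
                "support_other"]
        totals = sup[cols].sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-9)
        assert ((sup[cols] >= 0) & (sup[cols] <= 1)).all().all()
        # trot: diagonal 2-paw support dominates (~80% of the cycle)
        assert sup["support_2paw_diagonal"].mean() == pytest.approx(0.8,
                                                                    abs=0.08)

    def test_missing_paw_strides_partial_output(self, trot_tracks,
                                                trot_strides):
        partial = dict(trot_strides)
        partial["HL"] = StrideSet(np.array([]), np.array([]))
        out = interlimb_params(partial, trot_tracks)
        assert not out["step_length"].query("paw == 'HL'").shape[0]
        assert out["step_length"].query("paw == 'FR'").shape[0] > 0


class TestTrajectories:
    def test_output_length_100(self, trot_tracks, trot_strides):
        out = align_trajectories(trot_strides["FR"], trot_tracks, "FR")
        assert out
        for traj in out.values():
            assert traj.shape == (100, 3)

    def test_resampling_preserves_swing_endpoints(self, trot_tracks,
                                                  trot_strides):
        # x is piecewise linear: the resampled swing must run trough-to-peak
        out = align_trajectories(trot_strides["FR"], trot_tracks, "FR",
                                 smooth=False)
        A = V * D * T * 1000.0  # stance excursion, mm
        for traj in out.values():
            assert traj[0, 0] == pytest.approx(-A / 2, abs=0.5)
            assert traj[-1, 0] == pytest.approx(A / 2, abs=0.5)

    def test_savgol_first_order_equals_moving_average(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        sg = savgol_filter(y, window_length=3, polyorder=1)
        ma = np.convolve(y, np.ones(3) / 3, mode="valid")
        np.testing.assert_allclose(sg[1:-1], ma, atol=1e-12)


class TestVariability:
    def test_constant_samples(self):
        assert variability([2.0, 2.0, 2.0]) == 0.0

    def test_two_sample_value(self):
        assert variability([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2.0)

    @given(st.lists(st.floats(1.0, 100.0), min_size=2, max_size=30),
           st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scale_invariance(self, xs, c):
        x = np.asarray(xs)
        assert variability(c * x) == pytest.approx(variability(x), abs=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            variability([-1.0, 1.0])
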