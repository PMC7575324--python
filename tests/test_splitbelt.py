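"""Split-belt protocols, asymmetries, phase metrics, and compliance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import locoblink as lb
from locoblink.splitbelt import (
    AdaptationProtocol,
    AdaptationSeries,
    PhaseMetrics,
    ProtocolTrial,
    asymmetry,
    genotype_phase_model,
    multi_session_protocol,
    percent_of_initial_error,
    phase_metrics,
    single_session_protocol,
    stance_speed_compliance,
)


class TestAsymmetry:
    def test_equal_sides_zero(self):
        assert asymmetry(0.05, 0.05) == 0.0

    def test_arithmetic(self):
        assert asymmetry(0.05, 0.02) == pytest.approx(0.03)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert asymmetry(a, b) == -asymmetry(b, a)

    def test_missing_side_propagates(self):
        assert np.isnan(asymmetry(np.nan, 0.1))


class TestProtocols:
    def test_single_session_structure(self):
        proto = single_session_protocol()
        assert len(proto) == 18
        assert list(proto.phases).count("baseline") == 2
        assert list(proto.phases).count("split") == 8
        assert list(proto.phases).count("washout") == 8
        assert proto.split_ratio == pytest.approx(0.375 / 0.175)

    def test_multi_session_structure(self):
        proto = multi_session_protocol()
        assert len(proto) == 50
        assert list(proto.phases).count("baseline") == 3
        assert list(proto.phases).count("split") == 30
        assert list(proto.phases).count("washout") == 17
        split = proto.trials[proto.indices("split")[0]]
        assert (split.slow_speed, split.fast_speed) == (0.125, 0.275)
        sessions = [tr.session for tr in proto.trials]
        assert sessions == sorted(sessions) and max(sessions) == 5

    def test_phase_order_enforced(self):
        with pytest.raises(ValueError, match="order"):
            AdaptationProtocol([
                ProtocolTrial("split", 0.1, 0.3),
                ProtocolTrial("baseline", 0.2, 0.2),
            ])

    def test_split_requires_fast_gt_slow(self):
        with pytest.raises(ValueError, match="fast"):
            ProtocolTrial("split", 0.3, 0.3)

    def test_series_length_must_match(self):
        with pytest.raises(ValueError, match="length"):
            AdaptationSeries(np.zeros(5), single_session_protocol())


class TestPhaseMetrics:
    def test_constructed_example(self):
        proto = single_session_protocol()
        values = np.concatenate([
            [0.0, 0.0],
            np.linspace(-0.30, -0.05, 8),
            [0.22] + [0.0] * 7,
        ])
        m = phase_metrics(AdaptationSeries(values, proto))
        assert m.initial_error == pytest.approx(-0.30)
        assert m.change_over_split == pytest.approx(0.25)
        assert m.aftereffect == pytest.approx(0.22)

    def test_zero_series(self):
        proto = single_session_protocol()
        m = phase_metrics(AdaptationSeries(np.zeros(18), proto))
        assert (m.initial_error, m.change_over_split, m.aftereffect) == (0, 0, 0)

    def test_aftereffect_baseline_subtraction_flag(self):
        proto = single_session_protocol()
        values = np.zeros(18)
        values[:2] = 0.05  # baseline offset
        values[10] = 0.25  # first washout trial
        m = phase_metrics(AdaptationSeries(values, proto))
        assert m.aftereffect == pytest.approx(0.20)
        m_raw = phase_metrics(AdaptationSeries(values, proto),
                              baseline_subtract_aftereffect=False)
        assert m_raw.aftereffect == pytest.approx(0.25)

    def test_missing_phase_named_in_error(self):
        proto = AdaptationProtocol([
            ProtocolTrial("baseline", 0.2, 0.2),
            ProtocolTrial("split", 0.1, 0.3),
            ProtocolTrial("split", 0.1, 0.3),
        ])
        with pytest.raises(ValueError, match="washout"):
            phase_metrics(AdaptationSeries(np.zeros(3), proto))

    def test_sign_relabeling_invariance(self):
        proto = single_session_protocol()
        s = lb.gen_splitbelt_series(
            lb.SplitbeltSimConfig(protocol=proto, noise_sd=0.02, seed=4))
        m = phase_metrics(AdaptationSeries(s.values, proto))
        m_flip = phase_metrics(AdaptationSeries(-s.values, proto))
        assert m_flip.initial_error == pytest.approx(-m.initial_error)
        assert m_flip.aftereffect == pytest.approx(-m.aftereffect)
        pct = percent_of_initial_error([m])
        pct_flip = percent_of_initial_error([m_flip])
        pd.testing.assert_frame_equal(
            pct.drop(columns="initial_error"),
            pct_flip.drop(columns="initial_error"))


class TestPercentOfInitialError:
    def test_arithmetic(self):
        m = PhaseMetrics(initial_error=-0.30, change_over_split=0.25,
                         aftereffect=0.10)
        out = percent_of_initial_error([m])
        assert out["change_over_split_pct"].iloc[0] == pytest.approx(83.333,
                                                                     abs=0.01)

    def test_complete_adaptation_is_100(self):
        m = PhaseMetrics(-0.30, 0.30, -0.30)
        out = percent_of_initial_error([m])
        assert out["change_over_split_pct"].iloc[0] == pytest.approx(100.0)

    def test_zero_change_is_0(self):
        m = PhaseMetrics(-0.30, 0.0, 0.0)
        out = percent_of_initial_error([m])
        assert out["change_over_split_pct"].iloc[0] == 0.0

    def test_zero_group_initial_error_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            percent_of_initial_error([PhaseMetrics(0.0, 0.1, 0.1)])


class TestCompliance:
    def test_generator_tracks_pass(self):
        proto = multi_session_protocol()
        tracks = lb.gen_splitbelt_trial_tracks(proto, trial_duration=2.0,
                                               seed=0)
        passed, table = stance_speed_compliance(tracks, proto)
        assert passed
        np.testing.assert_allclose(table["stance_speed_FL"], 0.125, atol=0.02)
        np.testing.assert_allclose(table["stance_speed_FR"], 0.275, atol=0.03)

    def test_wrong_belt_speed_fails(self):
        proto = multi_session_protocol()
        # animal walks at the fast-belt speed on both sides
        cfg = lb.GaitSimConfig(belt_speed=(0.275, 0.275), duration=2.0)
        tracks = [lb.gen_gait_session(cfg)
                  for _ in range(len(proto.indices("split")))]
        for tk in tracks:
            tk.belt_speed = {"left": 0.125, "right": 0.275}
        passed, _ = stance_speed_compliance(tracks, proto)
        assert not passed

    def test_infinite_tolerance_always_passes(self):
        proto = multi_session_protocol()
        cfg = lb.GaitSimConfig(belt_speed=(0.275, 0.275), duration=2.0)
        tracks = [lb.gen_gait_session(cfg)
                  for _ in range(len(proto.indices("split")))]
        for tk in tracks:
            tk.belt_speed = {"left": 0.125, "right": 0.275}
        passed, _ = stance_speed_compliance(tracks, proto,
                                            tolerance=np.inf)
        assert passed

    def test_no_split_trials_rejected(self):
        proto = multi_session_protocol()
        with pytest.raises(ValueError):
            stance_speed_compliance([], proto)


class TestGenotypePhaseModel:
    def test_zero_noise_identical_groups_contrast_zero(self):
        proto = single_session_protocol()
        df = lb.gen_adaptation_cohort(proto, {"WT": {}, "KO": {}},
                                      n_per_group=4, noise_sd=0.0, seed=0)
        res = genotype_phase_model(df)
        np.testing.assert_allclose(res.contrasts["estimate"], 0.0, atol=1e-9)

    def test_large_retention_difference_detected(self):
        proto = single_session_protocol()
        hits = 0
        for seed in range(20):
            df = lb.gen_adaptation_cohort(
                proto, {"WT": {"retention": 0.9}, "KO": {"retention": 0.1}},
                n_per_group=8, noise_sd=0.03, seed=seed)
            res = genotype_phase_model(df)
            row = res.contrasts.query("phase == 'aftereffect'").iloc[0]
            hits += row["pvalue_tukey"] < 0.05
        assert hits >= 19

    def test_single_group_rejected(self):
        proto = single_session_protocol()
        df = lb.gen_adaptation_cohort(proto, {"WT": {}}, n_per_group=4,
                                      seed=0)
        with pytest.raises(ValueError, match="2 genotype groups"):
            genotype_phase_model(df)

    def test_contrast_table_shape(self):
        proto = single_session_protocol()
        df = lb.gen_adaptation_cohort(proto, {"WT": {}, "KO": {}},
                                      n_per_group=4, noise_sd=0.02, seed=1)
        res = genotype_phase_model(df)
        assert len(res.contrasts) == 3  # one genotype contrast per phase
        assert set(res.contrasts["phase"]) == {"initial_error",
                                               "change_over_split",
                                               "aftereffect"}
        assert (res.contrasts["pvalue_tukey"]
                >= res.contrasts["pvalue"] - 1e-12).all()
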