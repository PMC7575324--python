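import numpy as np
import pytest

import locoblink as lb


@pytest.fixture(scope="session")
def trot_tracks():
    """Noise-free symmetric trot on a tied-belt treadmill (0.2 m/s)."""
    return lb.gen_gait_session(lb.GaitSimConfig(seed=0))


@pytest.fixture(scope="session")
def trot_strides(trot_tracks):
    return lb.segment_all(trot_tracks)


@pytest.fixture(scope="session")
def small_cohort():
    """Small two-group conditioning cohort with traces."""
    cfg = lb.EyeblinkSimConfig(
        n_mice_per_group=2, n_sessions=3, n_paired=20, n_cs_only=4, seed=7)
    return lb.gen_eyeblink_cohort(cfg, traces=True)


def make_trial(values, sampling_rate=1000.0, trial_type="paired",
               cs_onset=0.2, isi=0.3, mouse="m0", session=1, index=1):
    """Trial wrapper around an explicit closure trace."""
    return lb.Trial(
        mouse_id=mouse, group="WT", session=session, trial_index=index,
        trial_type=trial_type, cs_onset=cs_onset, isi=isi,
        eyelid=lb.EyelidTrace(values, sampling_rate),
    )


def trace_with_peak(peak_value, peak_time, n=1000, sampling_rate=1000.0,
                    width=0.02):
    """Closure trace: single narrow Gaussian bump at peak_time."""
    t = np.arange(n) / sampling_rate
    return peak_value * np.exp(-0.5 * ((t - peak_time) / width) ** 2)
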