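"""Synthetic inputs for the whole pipeline, with known ground truth.

Generates (a) eyeblink-conditioning cohorts in which acquisition speed
depends on locomotor activity and trial-level CR amplitude is coupled to
walking speed, (b) grayscale eye frames for the eyelid-extraction stage,
(c) periodic quadruped paw tracks with configurable phase/stance
structure, and (d) split-belt adaptation series with exponential learning
and aftereffects.  Every generator is fully reproducible from its seed,
and each downstream analysis operation recovers the configured parameters
(exactly at zero noise).

The default eyeblink-cohort conditions mirror the original acquisition
design: 20 sessions of 100 CS-US paired plus 10 CS-only trials, ITIs
drawn uniformly from 5-20 s, a 300 ms ISI with co-terminating stimuli
(50 ms US), eyelid video at 900 Hz, and hypoactive (0.04 m/s) vs control
(0.12 m/s) group activity levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from skimage import draw

from .eyelid import EyelidTrace
from .gait import PAWS, SIDE, PawTracks
from .splitbelt import (
    AdaptationProtocol,
    AdaptationSeries,
    phase_metrics,
)

# ==========================================================================
# Eyeblink cohorts
# ==========================================================================

@dataclass
class EyeblinkSimConfig:
    """Ground-truth parameters for a simulated conditioning cohort.

    Acquisition follows a latent learning state L in [0, 1], advanced after
    every paired trial by a saturating logistic step whose rate grows with
    the trial's walking speed:

        L <- L + acquisition_gain * (1 + w * speed) * L * (1 - L)

    with w = ``speed_learning_weight``.  The CR amplitude on each trial is
    ``L * (cr_baseline_amplitude + speed_amplitude_slope * speed)`` plus
    Gaussian noise, clipped to [0, 1].
    """

    n_mice_per_group: int = 12
    n_sessions: int = 20
    n_paired: int = 100
    n_cs_only: int = 10
    isi: float = 0.300  # s
    us_duration: float = 0.050  # s
    iti_range: tuple[float, float] = (5.0, 20.0)  # s
    sampling_rate: float = 900.0  # Hz (eyelid video)
    wheel_rate: float = 100.0  # Hz (wheel-speed trace)
    cs_onset: float = 0.200  # s within the trial recording
    activity_mean_per_group: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.12, "CB1KO": 0.04})  # m/s
    activity_sd: float = 0.03  # m/s
    acquisition_gain: float = 0.003
    speed_learning_weight: float = 20.0  # per (m/s)
    cr_baseline_amplitude: float = 0.3
    speed_amplitude_slope: float = 2.0  # closure units per (m/s)
    noise_sd: float = 0.05  # closure units
    initial_learning_state: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice_per_group <= 0 or self.n_sessions <= 0:
            raise ValueError("counts must be positive")
        if self.n_paired <= 0 or self.n_cs_only <= 0:
            raise ValueError("paired and cs_only trial counts must be positive")
        if self.isi <= 0 or self.us_duration <= 0:
            raise ValueError("stimulus timings must be positive")
        if self.sampling_rate <= 0 or self.wheel_rate <= 0:
            raise ValueError("rates must be positive")
        if not self.iti_range[0] < self.iti_range[1]:
            raise ValueError("iti_range must be (low, high) with low < high")
        if not np.isfinite(self.speed_amplitude_slope):
            raise ValueError("speed_amplitude_slope must be finite")
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an integer")

    @property
    def trials_per_session(self) -> int:
        return self.n_paired + self.n_cs_only

    @property
    def cs_duration(self) -> float:
        """CS duration implied by co-termination: ISI + US duration."""
        return self.isi + self.us_duration


@dataclass
class EyeblinkCohort:
    """Simulated cohort: trial table plus per-trial eyelid and wheel traces."""

    table: pd.DataFrame
    eyelid: dict[tuple, EyelidTrace]
    wheel: dict[tuple, np.ndarray]
    wheel_rate: float
    config: EyeblinkSimConfig


def _eyelid_trace(cfg: EyeblinkSimConfig, amplitude: float,
                  paired: bool) -> np.ndarray:
    """Render one trial's closure trace: CR ramp peaking at the (would-be)
    US time, plus a UR reaching full blink on paired trials."""
    duration = cfg.cs_onset + cfg.isi + cfg.us_duration + 0.300
    n = int(round(duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    us_onset = cfg.cs_onset + cfg.isi

    sigma = cfg.isi / 4.0
    cr = amplitude * np.exp(-0.5 * ((t - us_onset) / sigma) ** 2)
    # CRs begin after the CS: smooth gate opening ~50 ms post CS onset
    gate = 1.0 / (1.0 + np.exp(-(t - (cfg.cs_onset + 0.060)) / 0.008))
    cr = cr * gate

    trace = cr
    if paired:
        rise = 1.0 / (1.0 + np.exp(-(t - (us_onset + 0.008)) / 0.003))
        hold_end = us_onset + cfg.us_duration + 0.050
        decay = np.where(t > hold_end, np.exp(-(t - hold_end) / 0.050), 1.0)
        ur = rise * decay
        trace = np.maximum(cr, ur)
    return np.clip(trace, 0.0, 1.0)


def gen_eyeblink_cohort(config: EyeblinkSimConfig,
                        traces: bool = True) -> EyeblinkCohort:
    """Simulate a full conditioning cohort.

    Returns one trial record per trial (group, mouse, session, trial index,
    type, ITI, walking speed, latent learning state, CR amplitude) plus,
    when ``traces`` is true, per-trial eyelid-closure and wheel-speed
    traces.  Learning advances faster for more active mice, so groups with
    higher activity means reach the onset criterion in earlier sessions.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows = []
    eyelid: dict[tuple, EyelidTrace] = {}
    wheel: dict[tuple, np.ndarray] = {}
    wheel_n = int(round((cfg.cs_onset + cfg.isi + cfg.us_duration + 0.300)
                        * cfg.wheel_rate))

    for group, act_mean in cfg.activity_mean_per_group.items():
        for m in range(cfg.n_mice_per_group):
            mouse_id = f"{group}_{m:02d}"
            mouse_mean = max(float(rng.normal(act_mean, cfg.activity_sd)), 0.005)
            L = cfg.initial_learning_state
            for session in range(1, cfg.n_sessions + 1):
                types = np.array(
                    ["paired"] * cfg.n_paired + ["cs_only"] * cfg.n_cs_only)
                rng.shuffle(types)
                for idx, trial_type in enumerate(types, start=1):
                    speed = max(float(rng.normal(mouse_mean, cfg.activity_sd)),
                                0.0)
                    amp = L * (cfg.cr_baseline_amplitude
                               + cfg.speed_amplitude_slope * speed)
                    if cfg.noise_sd > 0:
                        amp += float(rng.normal(0.0, cfg.noise_sd))
                    amp = float(np.clip(amp, 0.0, 1.0))
                    paired = trial_type == "paired"
                    rows.append({
                        "mouse_id": mouse_id,
                        "group": group,
                        "session": session,
                        "trial_index": idx,
                        "trial_type": trial_type,
                        "cs_onset_s": cfg.cs_onset,
                        "isi_s": cfg.isi,
                        "us_present": paired,
                        "us_duration_s": cfg.us_duration if paired else 0.0,
                        "iti_s": float(rng.uniform(*cfg.iti_range)),
                        "speed_mps": speed,
                        "learning_state": L,
                        "cr_amplitude": amp,
                    })
                    if traces:
                        key = (mouse_id, session, idx)
                        eyelid[key] = EyelidTrace(
                            _eyelid_trace(cfg, amp, paired),
                            cfg.sampling_rate, trial_id=key)
                        wheel[key] = np.full(wheel_n, speed)
                    if paired:
                        L = float(np.clip(
                            L + cfg.acquisition_gain
                            * (1.0 + cfg.speed_learning_weight * speed)
                            * L * (1.0 - L), 0.0, 1.0))
    table = pd.DataFrame(rows)
    return EyeblinkCohort(table, eyelid, wheel, cfg.wheel_rate, cfg)


def gen_speed_amplitude_trials(
    n_mice: int = 10,
    n_trials: int = 200,
    slope: float = 0.5,
    intercept: float = 0.2,
    slope_sd: float = 0.1,
    intercept_sd: float = 0.05,
    noise_sd: float = 0.05,
    speed_mean: float = 0.10,
    speed_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial table from an explicit random-slopes model, for model validation.

    amplitude = (intercept + b0_i) + (slope + b1_i) * speed + noise, with
    per-mouse deviations b0, b1; amplitudes are left unclipped so the
    generating model is exactly the one the mixed fit assumes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_mice):
        b0 = rng.normal(0.0, intercept_sd)
        b1 = rng.normal(0.0, slope_sd)
        speeds = np.clip(rng.normal(speed_mean, speed_sd, n_trials), 0.0, None)
        amps = ((intercept + b0) + (slope + b1) * speeds
                + rng.normal(0.0, noise_sd, n_trials))
        for v, a in zip(speeds, amps):
            rows.append({"mouse_id": f"m{m:02d}", "speed_mps": float(v),
                         "cr_amplitude": float(a)})
    return pd.DataFrame(rows)


# ==========================================================================
# Eye frames
# ==========================================================================

@dataclass
class EyeGeometry:
    """Rendered eye geometry: bright ellipse on a darker background."""

    height: int = 160
    width: int = 172
    center: tuple[float, float] = (80.0, 86.0)  # (row, col)
    major_extent: float = 80.0  # full major-axis length, px (horizontal)
    open_minor_extent: float = 30.0  # full minor axis when fully open, px
    closed_minor_extent: float = 0.0  # full minor axis when fully closed, px
    foreground: float = 0.8
    background: float = 0.2

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("frame dimensions must be positive")


def gen_eye_frame(
    openness: float,
    geometry: EyeGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a grayscale eye frame at the given openness.

    The ellipse minor axis scales linearly between the configured closed
    and open extents with ``openness`` in [0, 1]; the major axis is fixed.
    """
    if not 0.0 <= openness <= 1.0:
        raise ValueError(f"openness must lie in [0, 1], got {openness}")
    geo = geometry or EyeGeometry()
    frame = np.full((geo.height, geo.width), geo.background)
    minor = (geo.closed_minor_extent
             + openness * (geo.open_minor_extent - geo.closed_minor_extent))
    if minor >= 1.0:
        rr, cc = draw.ellipse(geo.center[0], geo.center[1],
                              minor / 2.0, geo.major_extent / 2.0,
                              shape=frame.shape)
        frame[rr, cc] = geo.foreground
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frame = frame + rng.normal(0.0, noise_sd, frame.shape)
    return np.clip(frame, 0.0, 1.0)


# ==========================================================================
# Gait sessions
# ==========================================================================

@dataclass
class GaitSimConfig:
    """Periodic quadruped gait with configurable phase/stance structure."""

    belt_speed: float | tuple[float, float] = 0.2  # m/s; (left, right)
    stride_duration: float = 0.3  # s
    duty_factor: float = 0.6
    interlimb_phases: Mapping[str, float] = field(
        default_factory=lambda: {"FR": 0.0, "FL": 0.5, "HR": 0.5, "HL": 0.0})
    step_height: float = 10.0  # mm
    body_width: float = 20.0  # mm
    noise_sd: float = 0.0  # mm
    duration: float = 3.0  # s
    frame_rate: float = 400.0  # Hz
    context: str = "treadmill"  # "treadmill" | "overground"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must lie in (0, 1)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for paw, ph in self.interlimb_phases.items():
            if not 0.0 <= ph < 1.0:
                raise ValueError(f"phase for {paw} must lie in [0, 1)")

    def speed_for(self, paw: str) -> float:
        if isinstance(self.belt_speed, (tuple, list)):
            left, right = self.belt_speed
            return float(left if SIDE[paw] == "left" else right)
        return float(self.belt_speed)


# global phase offset: keeps touch-downs away from the record boundaries
_PHASE_OFFSET = 0.25


def gen_gait_session(config: GaitSimConfig) -> PawTracks:
    """Generate tracked paw trajectories for a periodic gait.

    Forward position alternates stance (moving backward at belt speed in
    the treadmill frame; stationary in the overground ground frame) and
    swing (moving forward), with the configured duty factor and interlimb
    phases; z is positive only during swing; y offsets realize the body
    width.  In the ground frame each stride advances the paw by
    belt speed x stride duration.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.frame_rate))
    t = np.arange(n) / cfg.frame_rate
    T = cfg.stride_duration
    d = cfg.duty_factor
    paws: dict[str, np.ndarray] = {}
    speeds = [cfg.speed_for(p) for p in PAWS]
    body_speed = float(np.mean(speeds))
    for paw in PAWS:
        v = cfg.speed_for(paw)
        A = v * d * T * 1000.0  # stance excursion, mm
        phase = (t / T + _PHASE_OFFSET + cfg.interlimb_phases.get(paw, 0.0)) % 1.0
        in_stance = phase < d
        x_rel = np.where(
            in_stance,
            A / 2.0 - (phase / d) * A,
            -A / 2.0 + ((phase - d) / (1.0 - d)) * A,
        )
        z = np.where(in_stance, 0.0,
                     cfg.step_height * np.sin(np.pi * (phase - d) / (1.0 - d)))
        y = np.full(n, cfg.body_width / 2.0
                    * (1.0 if SIDE[paw] == "left" else -1.0))
        if cfg.context == "overground":
            x = x_rel + v * 1000.0 * t
        else:
            x = x_rel
        xyz = np.column_stack([x, y, np.maximum(z, 0.0)])
        if cfg.noise_sd > 0:
            xyz = xyz + rng.normal(0.0, cfg.noise_sd, xyz.shape)
        paws[paw] = xyz
    body_x = (body_speed * 1000.0 * t if cfg.context == "overground"
              else np.zeros(n))
    belt = (cfg.belt_speed if not isinstance(cfg.belt_speed, (tuple, list))
            else {"left": cfg.belt_speed[0], "right": cfg.belt_speed[1]})
    return PawTracks(paws=paws, body_x=body_x, frame_rate=cfg.frame_rate,
                     context=cfg.context, belt_speed=belt)


# ==========================================================================
# Split-belt adaptation
# ==========================================================================

@dataclass
class SplitbeltSimConfig:
    """Exponential split-belt adaptation with retention-scaled aftereffects."""

    protocol: AdaptationProtocol
    initial_error: float = -0.30  # asymmetry units
    learning_rate: float = 0.3  # per-trial fraction of remaining error
    retention: float = 0.8  # fraction of the adapted amount carried to washout
    noise_sd: float = 0.0  # asymmetry units
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in [0, 1]")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must lie in [0, 1]")


def gen_splitbelt_series(config: SplitbeltSimConfig) -> AdaptationSeries:
    """Simulate a per-trial asymmetry series over a protocol.

    Baseline trials sit at 0; at split onset the asymmetry jumps to
    ``initial_error`` and decays exponentially (fraction ``learning_rate``
    of the remaining error removed per trial); the washout starts at the
    opposite-signed aftereffect, retention x the adapted amount, and
    decays back to 0 at the same rate.  Per-trial Gaussian noise is added
    on top.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    proto = cfg.protocol
    r = cfg.learning_rate
    values = np.zeros(len(proto))
    split_idx = proto.indices("split")
    wash_idx = proto.indices("washout")
    for j, idx in enumerate(split_idx):
        values[idx] = cfg.initial_error * (1.0 - r) ** j
    if split_idx.size:
        final = cfg.initial_error * (1.0 - r) ** (split_idx.size - 1)
        adapted = cfg.initial_error - final
        aftereffect = -adapted * cfg.retention
        for j, idx in enumerate(wash_idx):
            values[idx] = aftereffect * (1.0 - r) ** j
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, values.size)
    return AdaptationSeries(values, proto)


def gen_adaptation_cohort(
    protocol: AdaptationProtocol,
    group_params: Mapping[str, Mapping[str, float]],
    n_per_group: int = 8,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal phase metrics for several groups, as a tidy table.

    ``group_params`` maps group label -> dict with any of initial_error,
    learning_rate, retention.  Returns one row per animal per phase level
    (initial_error, change_over_split, aftereffect), ready for
    :func:`locoblink.splitbelt.genotype_phase_model`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, params in group_params.items():
        for a in range(n_per_group):
            cfg = SplitbeltSimConfig(
                protocol=protocol,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                **params,
            )
            m = phase_metrics(gen_splitbelt_series(cfg))
            animal = f"{group}_{a:02d}"
            for phase, value in (("initial_error", m.initial_error),
                                 ("change_over_split", m.change_over_split),
                                 ("aftereffect", m.aftereffect)):
                rows.append({"animal": animal, "group": group,
                             "phase": phase, "value": value})
    return pd.DataFrame(rows)


def gen_splitbelt_trial_tracks(
    protocol: AdaptationProtocol,
    trial_duration: float = 3.0,
    stride_duration: float = 0.3,
    noise_sd: float = 0.0,
    frame_rate: float = 400.0,
    seed: int = 0,
) -> list[PawTracks]:
    """Realize the split trials of a protocol as PawTracks (slow belt left).

    Trial durations are truncated to ``trial_duration`` to keep the tracks
    small; stance-speed compliance only needs a few strides per trial.
    """
    rng = np.random.default_rng(seed)
    out = []
    for idx in protocol.indices("split"):
        tr = protocol.trials[idx]
        cfg = GaitSimConfig(
            belt_speed=(tr.slow_speed, tr.fast_speed),
            stride_duration=stride_duration,
            duration=trial_duration,
            noise_sd=noise_sd,
            frame_rate=frame_rate,
            context="treadmill",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(gen_gait_session(cfg))
    return out
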