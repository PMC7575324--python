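"""Conditioned-response metrics for delay eyeblink conditioning.

Covers CR classification (closure >= 0.1 between 100 ms after CS onset and
US onset), per-session learning curves and onset detection, locomotor-state
quantification from wheel-speed traces, state-conditioned amplitude
analyses (speed-binned amplitudes, stationary-trial comparisons), CR
timing on CS-only trials, single-trial learning effects, and the
trial-level mixed-model and animal-level robust-fit statistical contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .eyelid import EyelidTrace
from .stats import (
    MixedSlopeResult,
    RobustLineResult,
    fit_random_slopes,
    robust_line,
)

#: CR threshold in normalized closure units.
CR_THRESHOLD = 0.1
#: CR window opens this long after CS onset (s).
CR_WINDOW_START = 0.100
#: Trials with mean speed below this are "stationary" (m/s).
STATIONARY_THRESHOLD = 0.05
#: Samples above this speed count as walking (m/s).
WALKING_THRESHOLD = 0.01
#: CS-only amplitude window extends this far past the would-be US onset (s).
CS_ONLY_WINDOW_EXTENSION = 0.050


@dataclass
class Trial:
    """One conditioning trial: stimulus timing plus its recorded traces."""

    mouse_id: str
    group: str
    session: int  # 1-based
    trial_index: int  # 1-based within session
    trial_type: str  # "paired" | "cs_only"
    cs_onset: float  # s, within the trial recording
    isi: float  # s, CS onset to US onset (0.300 or 0.500 typical)
    us_duration: float = 0.050
    eyelid: EyelidTrace | None = None
    wheel_speed: np.ndarray | None = None
    wheel_rate: float | None = None

    def __post_init__(self) -> None:
        if self.isi <= 0:
            raise ValueError("isi must be positive")
        if self.cs_onset < 0:
            raise ValueError("cs_onset must be non-negative")
        if self.trial_type not in ("paired", "cs_only"):
            raise ValueError(f"unknown trial_type {self.trial_type!r}")

    @property
    def us_onset(self) -> float:
        return self.cs_onset + self.isi


@dataclass
class CRResult:
    is_cr: bool
    amplitude: float
    window: tuple[float, float]
    peak_time: float | None = None  # s relative to CS onset (CS-only trials)


@dataclass
class LocomotorState:
    mean_speed: float  # m/s
    distance: float  # m
    fraction_time_walking: float
    is_stationary: bool
    is_ambulatory: bool


@dataclass
class LearningCurve:
    sessions: np.ndarray  # 1-based
    percent_cr: np.ndarray
    mean_amplitude: np.ndarray
    onset_session: int | None


# --------------------------------------------------------------------------
# CR classification
# --------------------------------------------------------------------------

def classify_cr(trial: Trial, threshold: float = CR_THRESHOLD) -> CRResult:
    """Classify one trial as CR / no-CR and measure its amplitude.

    A trial is a CR when the normalized eyelid closure reaches at least
    ``threshold`` within [CS onset + 100 ms, US onset); the lower bound is
    inclusive and the US-onset bound exclusive.  On CS-only trials the
    amplitude window extends through the would-be US (US onset + 50 ms)
    and the peak time relative to CS onset is reported.
    """
    if trial.eyelid is None:
        raise ValueError("trial has no eyelid trace")
    trace = trial.eyelid
    v = np.asarray(trace.values, float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("eyelid trace is not normalized to [0, 1]")
    t = trace.times
    lo = trial.cs_onset + CR_WINDOW_START
    eps = 0.5 / trace.sampling_rate  # boundary snap: half a sample period
    if trial.trial_type == "paired":
        hi = trial.us_onset
        in_window = (t >= lo - eps) & (t < hi - eps)
        window = (lo, hi)
    else:
        hi = trial.us_onset + CS_ONLY_WINDOW_EXTENSION
        in_window = (t >= lo - eps) & (t <= hi + eps)
        window = (lo, hi)
    if t[-1] < hi - 1.0 / trace.sampling_rate:
        raise ValueError(
            f"trace ends at {t[-1]:.3f}s but CR window extends to {hi:.3f}s"
        )
    if not in_window.any():
        raise ValueError("trace has no samples inside the CR window")
    vw = v[in_window]
    amplitude = float(vw.max())
    result = CRResult(
        is_cr=amplitude >= threshold,
        amplitude=amplitude,
        window=window,
    )
    if trial.trial_type == "cs_only":
        tw = t[in_window]
        result.peak_time = float(tw[np.argmax(vw)] - trial.cs_onset)
    return result


def percent_cr(trials: Sequence[Trial], threshold: float = CR_THRESHOLD,
               include_cs_only: bool = True) -> float:
    """%CR of one session: 100 x (# CR trials) / (# eligible trials).

    All CS-bearing trials are classifiable, so CS-only trials enter the
    denominator by default; set ``include_cs_only=False`` to restrict to
    paired trials.
    """
    eligible = [
        tr for tr in trials
        if include_cs_only or tr.trial_type == "paired"
    ]
    if not eligible:
        raise ValueError("no eligible trials in session")
    n_cr = sum(classify_cr(tr, threshold).is_cr for tr in eligible)
    return 100.0 * n_cr / len(eligible)


def learning_onset(session_mean_amplitudes: Sequence[float],
                   threshold: float = CR_THRESHOLD) -> int | None:
    """First session (1-based) whose mean CR amplitude strictly exceeds 0.1."""
    amps = np.asarray(list(session_mean_amplitudes), float)
    if amps.size == 0:
        raise ValueError("no sessions given")
    above = np.flatnonzero(amps > threshold)
    return int(above[0]) + 1 if above.size else None


def learning_curve(trials: Sequence[Trial],
                   threshold: float = CR_THRESHOLD) -> LearningCurve:
    """Per-session %CR and mean CR amplitude, with the learning-onset session."""
    if not trials:
        raise ValueError("no trials given")
    by_session: dict[int, list[Trial]] = {}
    for tr in trials:
        by_session.setdefault(tr.session, []).append(tr)
    sessions = np.array(sorted(by_session))
    pct = np.array([percent_cr(by_session[s], threshold) for s in sessions])
    amp = np.array([
        np.mean([classify_cr(tr, threshold).amplitude for tr in by_session[s]])
        for s in sessions
    ])
    return LearningCurve(sessions, pct, amp, learning_onset(amp, threshold))


# --------------------------------------------------------------------------
# Locomotor state
# --------------------------------------------------------------------------

def locomotor_state(
    speed: np.ndarray,
    sampling_rate: float,
    stationary_threshold: float = STATIONARY_THRESHOLD,
    walking_threshold: float = WALKING_THRESHOLD,
) -> LocomotorState:
    """Summarize a wheel-speed trace over a trial window.

    distance integrates speed over the window; a trial is stationary when
    its mean speed is below 0.05 m/s and ambulatory otherwise.
    """
    speed = np.asarray(speed, float)
    if speed.size == 0:
        raise ValueError("empty speed trace")
    if np.any(speed < 0):
        raise ValueError("speeds must be non-negative")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    duration = speed.size / sampling_rate
    mean_speed = float(speed.mean())
    distance = mean_speed * duration
    walking = float(np.mean(speed > walking_threshold))
    stationary = mean_speed < stationary_threshold
    return LocomotorState(
        mean_speed=mean_speed,
        distance=distance,
        fraction_time_walking=walking,
        is_stationary=stationary,
        is_ambulatory=not stationary,
    )


# --------------------------------------------------------------------------
# State-conditioned amplitude analyses
# --------------------------------------------------------------------------

def speed_binned_amplitude(
    trials: pd.DataFrame,
    bin_edges: Sequence[float],
    speed_col: str = "speed_mps",
    amplitude_col: str = "cr_amplitude",
    mouse_col: str = "mouse_id",
) -> pd.DataFrame:
    """Mean CR amplitude and trial fraction per walking-speed bin.

    Binned means are computed per animal and then averaged across animals;
    a bin with no trials for any animal is reported as missing (NaN), not
    zero.  Each animal's histogram of trial fractions sums to 100%.
    """
    edges = np.asarray(list(bin_edges), float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    if len(trials) == 0:
        raise ValueError("no trials given")
    df = trials[[mouse_col, speed_col, amplitude_col]].dropna().copy()
    df["bin"] = pd.cut(df[speed_col], edges, right=False)
    per_animal_amp = df.groupby([mouse_col, "bin"], observed=False)[amplitude_col].mean()
    per_animal_cnt = df.groupby([mouse_col, "bin"], observed=False)[amplitude_col].count()
    per_animal_pct = per_animal_cnt.groupby(level=0).transform(
        lambda c: 100.0 * c / c.sum()
    )
    amp_wide = per_animal_amp.unstack("bin")
    pct_wide = per_animal_pct.unstack("bin")
    out = pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "bin_center": 0.5 * (edges[:-1] + edges[1:]),
        "mean_amplitude": amp_wide.mean(axis=0, skipna=True).to_numpy(),
        "pct_trials": pct_wide.mean(axis=0, skipna=True).to_numpy(),
    })
    return out


def single_trial_modulation(
    session: pd.DataFrame,
    amplitude_col: str = "cr_amplitude",
    us_col: str = "us_present",
    mouse_col: str = "mouse_id",
    session_col: str = "session",
) -> pd.DataFrame:
    """Single-trial learning on 50%-US test sessions.

    Partitions trials by the presence of an air-puff US on the *previous*
    trial (the first trial of each session is excluded) and returns, per
    animal, the mean amplitude after-puff, after-no-puff, and their
    difference.
    """
    if len(session) < 2:
        raise ValueError("single-trial modulation needs at least 2 trials")
    rows = []
    for (mouse, sess), g in session.groupby([mouse_col, session_col]):
        if len(g) < 2:
            raise ValueError(
                f"session {sess} of {mouse} has a single trial; "
                "previous-trial partition is undefined"
            )
        g = g.sort_values("trial_index") if "trial_index" in g else g
        prev_us = g[us_col].to_numpy(bool)[:-1]
        amps = g[amplitude_col].to_numpy(float)[1:]
        rows.append({
            mouse_col: mouse,
            session_col: sess,
            "after_puff": amps[prev_us].mean() if prev_us.any() else np.nan,
            "after_no_puff": (amps[~prev_us].mean()
                              if (~prev_us).any() else np.nan),
        })
    out = pd.DataFrame(rows)
    out = out.groupby(mouse_col, as_index=False)[["after_puff", "after_no_puff"]].mean()
    out["difference"] = out["after_puff"] - out["after_no_puff"]
    return out


def stationary_trials(
    trials: pd.DataFrame,
    speed_col: str = "speed_mps",
    threshold: float = STATIONARY_THRESHOLD,
) -> pd.DataFrame:
    """Subset of trials on which the animal was stationary (< 0.05 m/s)."""
    return trials[trials[speed_col] < threshold]


# --------------------------------------------------------------------------
# CR timing
# --------------------------------------------------------------------------

def cr_timing(
    trials: Sequence[Trial],
    threshold: float = CR_THRESHOLD,
) -> pd.DataFrame:
    """Peak times of CRs on CS-only trials, relative to CS onset.

    Well-timed CRs peak near the time the US would have occurred (the ISI).
    Returns one row per CR trial; an empty frame when no trial has a CR.
    """
    rows = []
    for tr in trials:
        if tr.trial_type != "cs_only":
            continue
        res = classify_cr(tr, threshold)
        if res.is_cr:
            rows.append({
                "mouse_id": tr.mouse_id,
                "session": tr.session,
                "trial_index": tr.trial_index,
                "isi": tr.isi,
                "peak_time": res.peak_time,
                "amplitude": res.amplitude,
            })
    return pd.DataFrame(
        rows,
        columns=["mouse_id", "session", "trial_index", "isi", "peak_time",
                 "amplitude"],
    )


def cr_timing_summary(timing: pd.DataFrame) -> pd.DataFrame:
    """Per-animal mean and median CR peak time."""
    if timing.empty:
        return pd.DataFrame(columns=["mouse_id", "mean_peak_time",
                                     "median_peak_time", "n_crs"])
    g = timing.groupby("mouse_id")["peak_time"]
    return pd.DataFrame({
        "mouse_id": g.mean().index,
        "mean_peak_time": g.mean().to_numpy(),
        "median_peak_time": g.median().to_numpy(),
        "n_crs": g.count().to_numpy(),
    })


# --------------------------------------------------------------------------
# Statistical contracts
# --------------------------------------------------------------------------

def fit_speed_amplitude_mixed(
    trials: pd.DataFrame,
    amplitude_col: str = "cr_amplitude",
    speed_col: str = "speed_mps",
    mouse_col: str = "mouse_id",
) -> MixedSlopeResult:
    """Trial-level amplitude-on-speed mixed model.

    Random slopes and intercepts per mouse; the fixed-effect slope is
    tested with an F test using Satterthwaite-corrected denominator
    degrees of freedom.  A single-mouse table falls back to OLS with a
    warning.
    """
    return fit_random_slopes(trials, amplitude_col, speed_col, mouse_col)


def robust_onset_vs_activity(
    onset_sessions: Sequence[float],
    mean_distances: Sequence[float],
) -> RobustLineResult:
    """Robust linear fit of learning-onset session on mean per-session distance."""
    onset = np.asarray(list(onset_sessions), float)
    dist = np.asarray(list(mean_distances), float)
    mask = np.isfinite(onset) & np.isfinite(dist)
    if mask.sum() < 3:
        raise ValueError("need at least 3 animals with a defined onset")
    return robust_line(dist[mask], onset[mask])


def split_by_activity(
    mean_distances: Sequence[float],
    threshold_m: float = 150.0,
) -> np.ndarray:
    """Boolean mask of "top runners": mean distance above the 150 m/session cut."""
    return np.asarray(list(mean_distances), float) >= threshold_m
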