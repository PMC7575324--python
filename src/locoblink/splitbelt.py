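"""Split-belt locomotor adaptation: protocols, asymmetries, phase metrics.

A split-belt session exposes the mouse to unequal belt speeds after tied
(equal-speed) baseline trials and returns to tied belts during washout.
Interlimb parameters such as step length become asymmetric at the split
(initial error), regain symmetry gradually over the split period (change
over split = late - early), and show opposite-signed aftereffects upon
return to tied belts.  All asymmetries are fast-side minus slow-side.

Two protocols from the original experiments are built in: a single-session
protocol (2 tied + 8 split + 8 tied at 0.175/0.375 m/s) and a five-session
protocol at lower overall speeds (tied 0.2, split 0.125/0.275 m/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from . import gait
from .stats import satterthwaite_df, tukey_pvalue

PHASES = ("baseline", "split", "washout")


@dataclass
class ProtocolTrial:
    phase: str  # baseline | split | washout
    slow_speed: float  # m/s
    fast_speed: float  # m/s
    duration: float = 60.0  # s
    session: int = 1  # 1-based

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.slow_speed <= 0 or self.fast_speed <= 0:
            raise ValueError("belt speeds must be positive")
        if self.phase == "split" and not self.fast_speed > self.slow_speed:
            raise ValueError("split trials require fast > slow")


@dataclass
class AdaptationProtocol:
    """Ordered trial list; phases must run baseline -> split -> washout."""

    trials: list[ProtocolTrial]

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("protocol has no trials")
        order = {p: i for i, p in enumerate(PHASES)}
        last = -1
        for tr in self.trials:
            rank = order[tr.phase]
            if rank < last:
                raise ValueError(
                    "phases must appear in order baseline -> split -> washout"
                )
            last = rank

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def phases(self) -> np.ndarray:
        return np.array([tr.phase for tr in self.trials])

    def indices(self, phase: str) -> np.ndarray:
        return np.flatnonzero(self.phases == phase)

    @property
    def split_ratio(self) -> float:
        """Fast/slow belt-speed ratio of the split trials."""
        idx = self.indices("split")
        if idx.size == 0:
            raise ValueError("protocol has no split trials")
        tr = self.trials[idx[0]]
        return tr.fast_speed / tr.slow_speed


def single_session_protocol(
    tied_speed: float = 0.275,
    slow: float = 0.175,
    fast: float = 0.375,
    trial_duration: float = 60.0,
) -> AdaptationProtocol:
    """Single-session protocol: 2 tied, 8 split, 8 tied (split at 0.175/0.375 m/s)."""
    trials = (
        [ProtocolTrial("baseline", tied_speed, tied_speed, trial_duration)] * 2
        + [ProtocolTrial("split", slow, fast, trial_duration)] * 8
        + [ProtocolTrial("washout", tied_speed, tied_speed, trial_duration)] * 8
    )
    return AdaptationProtocol(list(trials))


def multi_session_protocol(
    tied_speed: float = 0.2,
    slow: float = 0.125,
    fast: float = 0.275,
    trial_duration: float = 60.0,
) -> AdaptationProtocol:
    """Five-session protocol, 10 trials per session.

    Session 1: three tied, seven split; sessions 2-3: 10 split;
    session 4: three split, seven tied; session 5: 10 tied.
    """
    def tied(phase, session):
        return ProtocolTrial(phase, tied_speed, tied_speed, trial_duration,
                             session)

    def split(session):
        return ProtocolTrial("split", slow, fast, trial_duration, session)

    trials = (
        [tied("baseline", 1)] * 3 + [split(1)] * 7
        + [split(2)] * 10 + [split(3)] * 10
        + [split(4)] * 3 + [tied("washout", 4)] * 7
        + [tied("washout", 5)] * 10
    )
    return AdaptationProtocol(trials)


@dataclass
class AdaptationSeries:
    """Per-trial asymmetry (fast - slow) of one gait parameter."""

    values: np.ndarray
    protocol: AdaptationProtocol
    parameter: str = "step_length"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.size != len(self.protocol):
            raise ValueError(
                f"series length {self.values.size} != protocol length "
                f"{len(self.protocol)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("asymmetry values must be finite")


@dataclass
class PhaseMetrics:
    initial_error: float
    change_over_split: float
    aftereffect: float


def asymmetry(param_fast, param_slow):
    """Fast-side minus slow-side value; NaN when a side is missing."""
    fast = np.asarray(param_fast, float)
    slow = np.asarray(param_slow, float)
    return fast - slow


def phase_metrics(
    series: AdaptationSeries,
    baseline_subtract_aftereffect: bool = True,
) -> PhaseMetrics:
    """Initial error, change over split, and aftereffect of one series.

    initial error = asymmetry on the first split trial; change over split
    = last split trial minus first split trial; aftereffect = first washout
    trial minus the baseline average (set
    ``baseline_subtract_aftereffect=False`` for the raw first washout
    trial).
    """
    proto = series.protocol
    for phase, minimum in (("baseline", 1), ("split", 2), ("washout", 1)):
        if proto.indices(phase).size < minimum:
            raise ValueError(
                f"protocol needs at least {minimum} {phase} trial(s)"
            )
    base = series.values[proto.indices("baseline")]
    split = series.values[proto.indices("split")]
    wash = series.values[proto.indices("washout")]
    aftereffect = wash[0] - base.mean() if baseline_subtract_aftereffect else wash[0]
    return PhaseMetrics(
        initial_error=float(split[0]),
        change_over_split=float(split[-1] - split[0]),
        aftereffect=float(aftereffect),
    )


def percent_of_initial_error(
    metrics: Sequence[PhaseMetrics],
) -> pd.DataFrame:
    """Learned changes as a percent of the group's average initial error.

    Per animal: 100 x |change over split| / |group mean initial error| and
    likewise for the aftereffect.  100% means complete adaptation.  The
    sign inversion that makes learned changes directly comparable to the
    initial error is implied by taking magnitudes.
    """
    metrics = list(metrics)
    if not metrics:
        raise ValueError("no metrics given")
    group_initial = float(np.mean([m.initial_error for m in metrics]))
    if group_initial == 0:
        raise ValueError("group mean initial error is zero")
    rows = [{
        "initial_error": m.initial_error,
        "change_over_split_pct": 100.0 * abs(m.change_over_split) / abs(group_initial),
        "aftereffect_pct": 100.0 * abs(m.aftereffect) / abs(group_initial),
    } for m in metrics]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Stance-speed compliance
# --------------------------------------------------------------------------

def stance_speed_compliance(
    split_tracks: Sequence[gait.PawTracks],
    protocol: AdaptationProtocol,
    tolerance: float = 0.2,
    min_fraction: float = 0.8,
) -> tuple[bool, pd.DataFrame]:
    """Check that the animal maintained split-belt walking.

    For each split trial and each side, the stance speed of the front paw
    (mean backward x velocity during stance, treadmill frame) must match
    that side's belt speed within ``tolerance`` (relative).  The animal
    passes when the fraction of compliant split trials is at least
    ``min_fraction``.  Returns (passed, per-trial table).
    """
    tracks_list = list(split_tracks)
    split_idx = protocol.indices("split")
    if not tracks_list or split_idx.size == 0:
        raise ValueError("no split-phase trials to check")
    rows = []
    for trial_no, (idx, tracks) in enumerate(zip(split_idx, tracks_list)):
        proto = protocol.trials[idx]
        row = {"trial": int(idx)}
        ok = True
        for paw in ("FR", "FL"):
            belt = tracks.belt_speed_for(paw)
            strides = gait.segment_strides(tracks, paw)
            if strides.n_strides == 0:
                ok = False
                row[f"stance_speed_{paw}"] = np.nan
                continue
            mask = gait._stance_mask(tracks, strides)
            x = tracks.paws[paw][:, 0]
            v = np.gradient(x, 1.0 / tracks.frame_rate) / 1000.0  # m/s
            stance_v = float(np.mean(np.abs(v[mask])))
            row[f"stance_speed_{paw}"] = stance_v
            if not np.isfinite(tolerance):
                continue
            if abs(stance_v - belt) > tolerance * belt:
                ok = False
        row["compliant"] = ok
        rows.append(row)
    table = pd.DataFrame(rows)
    passed = bool(table["compliant"].mean() >= min_fraction)
    return passed, table


# --------------------------------------------------------------------------
# Genotype x phase mixed model with Tukey post-hocs
# --------------------------------------------------------------------------

@dataclass
class PhaseModelResult:
    fixed_effects: pd.DataFrame
    contrasts: pd.DataFrame  # genotype contrast per phase


def genotype_phase_model(
    metrics: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    phase_col: str = "phase",
    animal_col: str = "animal",
) -> PhaseModelResult:
    """Mixed model of per-animal phase metrics with genotype x phase effects.

    One observation per animal per phase level (initial error, change over
    split, aftereffect); animal enters as a random intercept.  Genotype
    contrasts within each phase are reported with Satterthwaite-corrected
    t tests and Tukey-adjusted p-values over the genotype x phase cell
    means.
    """
    df = metrics[[value_col, group_col, phase_col, animal_col]].dropna().copy()
    groups_lv = sorted(df[group_col].unique())
    phases_lv = sorted(df[phase_col].unique())
    if len(groups_lv) < 2:
        raise ValueError("need at least 2 genotype groups")
    if df.groupby(group_col)[animal_col].nunique().min() < 2:
        raise ValueError("need at least 2 animals per group")

    # cell-means coding: one column per genotype x phase cell
    cells = [(g, p) for g in groups_lv for p in phases_lv]
    X = np.zeros((len(df), len(cells)))
    for j, (g, p) in enumerate(cells):
        X[:, j] = ((df[group_col] == g) & (df[phase_col] == p)).to_numpy(float)
    y = df[value_col].to_numpy(float)
    animals = df[animal_col].to_numpy()
    Z = np.ones((len(df), 1))

    model = sm.MixedLM(y, X, groups=animals, exog_re=Z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)

    fe = pd.DataFrame({
        "group": [g for g, _ in cells],
        "phase": [p for _, p in cells],
        "estimate": fit.fe_params,
        "se": fit.bse_fe,
    })

    cov_re = np.atleast_2d(np.asarray(fit.cov_re))
    cov_beta = np.asarray(fit.cov_params())[: len(cells), : len(cells)]
    rows = []
    n_means = len(cells)
    for p in phases_lv:
        for i, g1 in enumerate(groups_lv):
            for g2 in groups_lv[i + 1:]:
                L = np.zeros(len(cells))
                L[cells.index((g1, p))] = 1.0
                L[cells.index((g2, p))] = -1.0
                est = float(L @ fit.fe_params)
                se = float(np.sqrt(L @ cov_beta @ L))
                ddf = satterthwaite_df(y, X, Z, animals, cov_re,
                                       float(fit.scale), L)
                tstat = est / se if se > 0 else 0.0
                rows.append({
                    "phase": p,
                    "contrast": f"{g1} - {g2}",
                    "estimate": est,
                    "se": se,
                    "tstat": tstat,
                    "df": ddf,
                    "pvalue": float(2 * sps.t.sf(abs(tstat), ddf)),
                    "pvalue_tukey": tukey_pvalue(tstat, n_means, ddf),
                })
    return PhaseModelResult(fixed_effects=fe, contrasts=pd.DataFrame(rows))
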