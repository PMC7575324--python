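"""Stride segmentation and gait parameterization for quadruped locomotion.

Operates on tracked 3-D paw positions (FR/FL/HR/HL plus body center) from
overground corridor walking or a (split-belt) treadmill.  Tracks are broken
into strides by peak detection on the paw's forward excursion relative to
the body; per-stride individual-limb parameters (stride duration, cadence,
duty factor, stride length, swing velocity), interlimb and whole-body
coordination parameters (step length, base of support, stance phase,
double support, support patterns, center of oscillation), swing-trajectory
alignment, and coefficient-of-variation variability measures follow the
standard LocoMouse-style definitions.

Conventions: x is the animal's forward axis, y lateral, z vertical; all
positions in mm, times in seconds.  On the treadmill, per-paw displacement
over time is computed in the ground (belt-compensated) frame; instantaneous
between-paw distances are frame-independent and use raw positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

PAWS = ("FR", "FL", "HR", "HL")
FRONT = ("FR", "FL")
HIND = ("HR", "HL")
SIDE = {"FR": "right", "FL": "left", "HR": "right", "HL": "left"}
HOMOLOG = {"FR": "FL", "FL": "FR", "HR": "HL", "HL": "HR"}
DIAGONAL_PAIRS = (frozenset({"FR", "HL"}), frozenset({"FL", "HR"}))

#: Paw counts as in contact with the ground below this height (mm).
CONTACT_HEIGHT = 1.0
#: Peak prominence for stride events, as a fraction of the excursion range.
PEAK_PROMINENCE_FRAC = 0.2
#: Minimum event separation, as a fraction of the estimated stride period.
MIN_SEPARATION_FRAC = 0.5


@dataclass
class PawTracks:
    """Tracked (x, y, z) paw positions plus body center for one session/trial."""

    paws: dict[str, np.ndarray]  # paw -> (n, 3) array, mm
    body_x: np.ndarray  # (n,), mm
    frame_rate: float  # Hz
    context: str = "overground"  # "overground" | "treadmill"
    belt_speed: float | Mapping[str, float] = 0.0  # m/s; per-side mapping ok

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.context not in ("overground", "treadmill"):
            raise ValueError(f"unknown context {self.context!r}")
        n = len(self.body_x)
        for paw in PAWS:
            if paw not in self.paws:
                raise ValueError(f"missing paw {paw}")
            arr = np.asarray(self.paws[paw], float)
            if arr.shape != (n, 3):
                raise ValueError(f"paw {paw} has shape {arr.shape}, expected ({n}, 3)")
            self.paws[paw] = arr
        self.body_x = np.asarray(self.body_x, float)

    @property
    def n_frames(self) -> int:
        return len(self.body_x)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def belt_speed_for(self, paw: str) -> float:
        if isinstance(self.belt_speed, Mapping):
            return float(self.belt_speed[SIDE[paw]])
        return float(self.belt_speed)

    def ground_x(self, paw: str, belt_compensate: bool = True) -> np.ndarray:
        """Forward position in the ground frame (belt-compensated on treadmill)."""
        x = self.paws[paw][:, 0]
        if self.context == "treadmill" and belt_compensate:
            return x + self.belt_speed_for(paw) * 1000.0 * self.times
        return x


@dataclass
class StrideSet:
    """Ordered stance (touch-down) and swing (lift-off) onset times of one limb."""

    stance_onsets: np.ndarray  # s
    swing_onsets: np.ndarray  # s

    def __post_init__(self) -> None:
        self.stance_onsets = np.asarray(self.stance_onsets, float)
        self.swing_onsets = np.asarray(self.swing_onsets, float)
        for arr in (self.stance_onsets, self.swing_onsets):
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError("event times must be strictly increasing")
        # events must alternate stance -> swing -> stance ...
        merged = sorted(
            [(t, "stance") for t in self.stance_onsets]
            + [(t, "swing") for t in self.swing_onsets]
        )
        for (t0, k0), (t1, k1) in zip(merged, merged[1:]):
            if k0 == k1:
                raise ValueError("stance and swing onsets must alternate")

    @property
    def n_strides(self) -> int:
        return len(self.stance_onsets)


# --------------------------------------------------------------------------
# Stride segmentation
# --------------------------------------------------------------------------

def _dominant_period(x: np.ndarray, fs: float) -> float | None:
    """Stride period estimate from the dominant non-DC Fourier component."""
    x = x - x.mean()
    n = x.size
    if n < 8:
        return None
    spec = np.abs(np.fft.rfft(x * np.hanning(n)))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if freqs[k] <= 0 or spec[k] == 0:
        return None
    return 1.0 / freqs[k]


def segment_strides(
    tracks: PawTracks,
    paw: str,
    prominence_frac: float = PEAK_PROMINENCE_FRAC,
    min_separation_frac: float = MIN_SEPARATION_FRAC,
) -> StrideSet:
    """Break one paw's track into strides by peak detection.

    Stance onset (touch-down) is a local maximum of the paw's forward
    excursion relative to the body; swing onset (lift-off) a local minimum.
    Peak prominence and minimum separation (fractions of the excursion
    range and of the estimated stride period) guard against noise.  A
    constant track yields an empty stride set.
    """
    if paw not in PAWS:
        raise ValueError(f"unknown paw {paw!r}")
    x_rel = tracks.paws[paw][:, 0] - tracks.body_x
    if np.any(~np.isfinite(x_rel)):
        raise ValueError("track contains NaN/inf")
    excursion = float(np.ptp(x_rel))
    if excursion <= 1e-9:
        return StrideSet(np.array([]), np.array([]))
    period = _dominant_period(x_rel, tracks.frame_rate)
    if period is None:
        return StrideSet(np.array([]), np.array([]))
    distance = max(1, int(round(min_separation_frac * period * tracks.frame_rate)))
    prominence = prominence_frac * excursion
    peaks, _ = signal.find_peaks(x_rel, prominence=prominence, distance=distance)
    troughs, _ = signal.find_peaks(-x_rel, prominence=prominence, distance=distance)
    t = tracks.times
    events = sorted(
        [(t[i], "stance", x_rel[i]) for i in peaks]
        + [(t[i], "swing", x_rel[i]) for i in troughs]
    )
    # enforce alternation starting at the first touch-down
    stance, swing = [], []
    expect = "stance"
    for when, kind, _ in events:
        if kind != expect:
            continue
        (stance if kind == "stance" else swing).append(when)
        expect = "swing" if kind == "stance" else "stance"
    return StrideSet(np.array(stance), np.array(swing))


def segment_all(tracks: PawTracks, **kwargs) -> dict[str, StrideSet]:
    return {paw: segment_strides(tracks, paw, **kwargs) for paw in PAWS}


def _interp_at(times: np.ndarray, values: np.ndarray, at: np.ndarray) -> np.ndarray:
    return np.interp(at, times, values)


def _stance_mask(tracks: PawTracks, strides: StrideSet) -> np.ndarray:
    """Boolean per-frame mask: paw in stance (between touch-down and lift-off)."""
    t = tracks.times
    mask = np.zeros(t.size, bool)
    for t_on in strides.stance_onsets:
        later = strides.swing_onsets[strides.swing_onsets > t_on]
        t_off = later[0] if later.size else t[-1] + 1
        mask |= (t >= t_on) & (t < t_off)
    return mask


# --------------------------------------------------------------------------
# Individual limb parameters
# --------------------------------------------------------------------------

def limb_params(
    strides: StrideSet,
    tracks: PawTracks,
    paw: str,
    belt_compensate: bool = True,
) -> pd.DataFrame:
    """Per-stride individual-limb parameters.

    stride duration = time between consecutive stance onsets; cadence its
    inverse; duty factor = stance duration / stride duration; stride
    length = forward displacement touch-down to touch-down; swing velocity
    = forward displacement during swing / swing duration.  The final
    incomplete stride (no closing touch-down) is dropped; the number of
    dropped strides is recorded in ``DataFrame.attrs["n_dropped"]``.
    """
    t = tracks.times
    xg = tracks.ground_x(paw, belt_compensate)
    rows = []
    n_dropped = 0
    for k, t0 in enumerate(strides.stance_onsets):
        nxt = strides.stance_onsets[strides.stance_onsets > t0]
        if nxt.size == 0:
            n_dropped += 1
            continue
        t1 = nxt[0]
        sw = strides.swing_onsets[(strides.swing_onsets > t0)
                                  & (strides.swing_onsets < t1)]
        if sw.size == 0:
            n_dropped += 1
            continue
        t_sw = sw[0]
        duration = t1 - t0
        stance_dur = t_sw - t0
        swing_dur = t1 - t_sw
        x0, x_sw, x1 = _interp_at(t, xg, np.array([t0, t_sw, t1]))
        stride_length = x1 - x0
        rows.append({
            "stride_index": k,
            "stance_onset": t0,
            "swing_onset": t_sw,
            "stride_duration": duration,
            "cadence": 1.0 / duration,
            "stance_duration": stance_dur,
            "swing_duration": swing_dur,
            "duty_factor": stance_dur / duration,
            "stride_length": stride_length,
            "swing_velocity": (x1 - x_sw) / 1000.0 / swing_dur,
            "stride_speed": stride_length / 1000.0 / duration,
        })
    df = pd.DataFrame(rows, columns=[
        "stride_index", "stance_onset", "swing_onset", "stride_duration",
        "cadence", "stance_duration", "swing_duration", "duty_factor",
        "stride_length", "swing_velocity", "stride_speed",
    ])
    df.attrs["n_dropped"] = n_dropped
    df.attrs["paw"] = paw
    return df


# --------------------------------------------------------------------------
# Interlimb and whole-body coordination parameters
# --------------------------------------------------------------------------

def _support_category(contact: dict[str, bool]) -> str:
    on = frozenset(p for p, c in contact.items() if c)
    if len(on) == 3:
        return "support_3paw"
    if len(on) == 2:
        return ("support_2paw_diagonal" if on in DIAGONAL_PAIRS
                else "support_2paw_other")
    return "support_other"


def interlimb_params(
    stride_sets: Mapping[str, StrideSet],
    tracks: PawTracks,
    reference_paw: str = "FR",
    contact_height: float = CONTACT_HEIGHT,
) -> dict[str, pd.DataFrame]:
    """Interlimb and whole-body coordination parameters.

    Returns a dict of tidy per-stride tables:

    - ``step_length``: displacement of each paw relative to its contralateral
      homolog at the paw's stance onset (raw lab-frame positions).
    - ``base_of_support``: lateral width between the two front and the two
      hind paws during stance, per reference stride.
    - ``stance_phase``: relative timing of each paw's touch-down within the
      reference paw's stride cycle, (t_on - t_on_ref) / stride duration,
      wrapped to [0, 1).
    - ``double_support``: per limb, % of the stride cycle from its
      touch-down to the lift-off of its contralateral homolog.
    - ``center_of_oscillation``: midpoint of each stride's swing- and
      stance-onset forward positions, relative to the body center.
    - ``supports``: per reference stride, fractions of stride time spent in
      3-paw, 2-paw diagonal, 2-paw other, and remaining support patterns
      (paw contact = z below ``contact_height``).

    Paws without segmented strides simply contribute no rows to the tables
    that need them; the remaining parameters are still computed.
    """
    t = tracks.times
    ref = stride_sets.get(reference_paw, StrideSet(np.array([]), np.array([])))

    # --- step length (per paw, at its own stance onsets)
    sl_rows = []
    for paw in PAWS:
        ss = stride_sets.get(paw)
        if ss is None or ss.n_strides == 0:
            continue
        other = HOMOLOG[paw]
        x_p = tracks.paws[paw][:, 0]
        x_o = tracks.paws[other][:, 0]
        for k, t_on in enumerate(ss.stance_onsets):
            sl_rows.append({
                "paw": paw,
                "stride_index": k,
                "stance_onset": t_on,
                "step_length": float(_interp_at(t, x_p, np.array([t_on]))[0]
                                     - _interp_at(t, x_o, np.array([t_on]))[0]),
            })
    step_length = pd.DataFrame(
        sl_rows, columns=["paw", "stride_index", "stance_onset", "step_length"])

    # --- per-frame stance masks (from stride events)
    stance_masks = {
        paw: _stance_mask(tracks, stride_sets[paw])
        if paw in stride_sets and stride_sets[paw].n_strides else
        np.zeros(t.size, bool)
        for paw in PAWS
    }

    # --- base of support, stance phase, supports: per reference stride
    bos_rows, phase_rows, support_rows = [], [], []
    for k, t0 in enumerate(ref.stance_onsets):
        nxt = ref.stance_onsets[ref.stance_onsets > t0]
        if nxt.size == 0:
            continue
        t1 = nxt[0]
        duration = t1 - t0
        in_stride = (t >= t0) & (t < t1)

        widths = {}
        for label, (p_r, p_l) in (("front", ("FR", "FL")), ("hind", ("HR", "HL"))):
            m_r = in_stride & stance_masks[p_r]
            m_l = in_stride & stance_masks[p_l]
            if m_r.any() and m_l.any():
                widths[label] = abs(
                    float(tracks.paws[p_r][m_r, 1].mean())
                    - float(tracks.paws[p_l][m_l, 1].mean())
                )
            else:
                widths[label] = np.nan
        bos_rows.append({"stride_index": k, "front": widths["front"],
                         "hind": widths["hind"]})

        for paw in PAWS:
            if paw == reference_paw:
                continue
            ss = stride_sets.get(paw)
            if ss is None or ss.n_strides == 0:
                continue
            ons = ss.stance_onsets[(ss.stance_onsets >= t0)
                                   & (ss.stance_onsets < t1)]
            if ons.size == 0:
                continue
            phase_rows.append({
                "stride_index": k,
                "paw": paw,
                "pair": "LR" if paw == HOMOLOG[reference_paw]
                        else ("FH" if SIDE[paw] == SIDE[reference_paw] else "diagonal"),
                "stance_phase": ((ons[0] - t0) / duration) % 1.0,
            })

        frac = {"support_3paw": 0.0, "support_2paw_diagonal": 0.0,
                "support_2paw_other": 0.0, "support_other": 0.0}
        idx = np.flatnonzero(in_stride)
        for i in idx:
            contact = {p: tracks.paws[p][i, 2] < contact_height for p in PAWS}
            frac[_support_category(contact)] += 1.0
        if idx.size:
            for key in frac:
                frac[key] /= idx.size
        support_rows.append({"stride_index": k, **frac})

    base_of_support = pd.DataFrame(
        bos_rows, columns=["stride_index", "front", "hind"])
    stance_phase = pd.DataFrame(
        phase_rows, columns=["stride_index", "paw", "pair", "stance_phase"])
    supports = pd.DataFrame(
        support_rows, columns=["stride_index", "support_3paw",
                               "support_2paw_diagonal", "support_2paw_other",
                               "support_other"])

    # --- double support (each limb is its own reference)
    ds_rows = []
    for paw in PAWS:
        ss = stride_sets.get(paw)
        contra = stride_sets.get(HOMOLOG[paw])
        if ss is None or contra is None or ss.n_strides == 0:
            continue
        for k, t0 in enumerate(ss.stance_onsets):
            nxt = ss.stance_onsets[ss.stance_onsets > t0]
            if nxt.size == 0:
                continue
            t1 = nxt[0]
            liftoffs = contra.swing_onsets[(contra.swing_onsets >= t0)
                                           & (contra.swing_onsets < t1)]
            pct = 100.0 * (liftoffs[0] - t0) / (t1 - t0) if liftoffs.size else 0.0
            ds_rows.append({"paw": paw, "stride_index": k,
                            "double_support": pct})
    double_support = pd.DataFrame(
        ds_rows, columns=["paw", "stride_index", "double_support"])

    # --- center of oscillation
    co_rows = []
    for paw in PAWS:
        ss = stride_sets.get(paw)
        if ss is None or ss.n_strides == 0:
            continue
        x_rel = tracks.paws[paw][:, 0] - tracks.body_x
        for k, t0 in enumerate(ss.stance_onsets):
            sw = ss.swing_onsets[ss.swing_onsets > t0]
            if sw.size == 0:
                continue
            x_on = float(_interp_at(t, x_rel, np.array([t0]))[0])
            x_sw = float(_interp_at(t, x_rel, np.array([sw[0]]))[0])
            co_rows.append({"paw": paw, "stride_index": k,
                            "center_of_oscillation": 0.5 * (x_on + x_sw)})
    center_of_oscillation = pd.DataFrame(
        co_rows, columns=["paw", "stride_index", "center_of_oscillation"])

    return {
        "step_length": step_length,
        "base_of_support": base_of_support,
        "stance_phase": stance_phase,
        "double_support": double_support,
        "center_of_oscillation": center_of_oscillation,
        "supports": supports,
    }


# --------------------------------------------------------------------------
# Swing-trajectory alignment
# --------------------------------------------------------------------------

def align_trajectories(
    strides: StrideSet,
    tracks: PawTracks,
    paw: str,
    speed_bin_width: float = 0.05,
    n_points: int = 100,
    smooth: bool = True,
) -> dict[tuple[float, float], np.ndarray]:
    """Speed-binned mean swing trajectories, resampled to 100 points.

    Each swing (lift-off to next touch-down) is linearly interpolated onto
    ``n_points`` equidistant points per axis, averaged within speed bins
    (stride speed = stride length / stride duration), and smoothed with a
    first-order Savitzky-Golay filter with a 3-point window.  Returns a
    mapping (bin_low, bin_high) -> (n_points, 3) array; bins with no
    swings are simply absent.
    """
    params = limb_params(strides, tracks, paw)
    if params.empty:
        return {}
    t = tracks.times
    xyz = tracks.paws[paw]
    binned: dict[tuple[float, float], list[np.ndarray]] = {}
    for _, row in params.iterrows():
        t_sw, t1 = row["swing_onset"], row["stance_onset"] + row["stride_duration"]
        u = np.linspace(t_sw, t1, n_points)
        traj = np.column_stack([_interp_at(t, xyz[:, j], u) for j in range(3)])
        b = int(np.floor(row["stride_speed"] / speed_bin_width + 1e-9))
        key = (b * speed_bin_width, (b + 1) * speed_bin_width)
        binned.setdefault(key, []).append(traj)
    out = {}
    for key, trajs in binned.items():
        mean = np.mean(trajs, axis=0)
        if smooth:
            mean = signal.savgol_filter(mean, window_length=3, polyorder=1, axis=0)
        out[key] = mean
    return out


# --------------------------------------------------------------------------
# Variability
# --------------------------------------------------------------------------

def variability(samples: Sequence[float]) -> float:
    """Coefficient of variation, CV = sd / mean (sample sd, ddof=1)."""
    x = np.asarray(list(samples), float)
    if x.size < 2:
        raise ValueError("CV requires at least 2 samples")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)
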