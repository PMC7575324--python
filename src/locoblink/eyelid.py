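"""Eyelid-distance extraction from eye video frames and session normalization.

The eye appears as a bright elliptical region in a pre-cropped grayscale
frame (acquired as a 172 x 160 px window in the original setup).  The
eyelid distance is the full minor-axis length of the ellipse delineating
the eye, obtained frame by frame by thresholding and a second-moments
ellipse fit of the largest connected component.  Per session, raw distances
are mapped to a closure scale from 0 (eye fully open) to 1 (full blink)
using robust session-wide anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from skimage import filters, measure


@dataclass
class RawEyelidTrace:
    """Per-trial eyelid distance in pixels, one value per frame."""

    values: np.ndarray
    sampling_rate: float
    trial_id: str | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("eyelid distances must be finite")
        if np.any(self.values < 0):
            raise ValueError("eyelid distances must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate


@dataclass
class EyelidTrace:
    """Per-trial normalized eyelid closure: 1 = full blink, 0 = fully open."""

    values: np.ndarray
    sampling_rate: float
    trial_id: str | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("normalized closure must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate


class ExtractionResult(NamedTuple):
    distance_px: float
    eye_closed: bool


def extract_eyelid_distance(frame, threshold: float | None = None) -> ExtractionResult:
    """Eyelid distance (px) from one grayscale frame.

    The frame is binarized at ``threshold`` (Otsu's method when omitted),
    the largest connected foreground component is kept, and the full
    minor-axis length of its second-moments ellipse is returned.  A frame
    with no foreground yields distance 0 with ``eye_closed=True``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale frame, got ndim={frame.ndim}")
    frame = frame.astype(float)
    if threshold is None:
        if np.ptp(frame) == 0:
            return ExtractionResult(0.0, True)
        threshold = filters.threshold_otsu(frame)
    mask = frame > threshold
    if not mask.any():
        return ExtractionResult(0.0, True)
    labels = measure.label(mask)
    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    if largest.area < 2:
        return ExtractionResult(0.0, True)
    return ExtractionResult(float(largest.axis_minor_length), False)


def extract_trace(
    frames: Sequence[np.ndarray] | np.ndarray,
    sampling_rate: float,
    threshold: float | None = None,
    trial_id=None,
) -> RawEyelidTrace:
    """Apply :func:`extract_eyelid_distance` to a stack of frames."""
    values = [extract_eyelid_distance(f, threshold).distance_px for f in frames]
    return RawEyelidTrace(np.asarray(values), sampling_rate, trial_id)


def normalize_session(
    raw_traces: Sequence[RawEyelidTrace],
    baseline_end_s: float | None = None,
    open_percentile: float = 97.5,
    closed_percentile: float = 1.0,
    anchors: tuple[float, float] | None = None,
) -> list[EyelidTrace]:
    """Map raw eyelid distances of one session onto the [0, 1] closure scale.

    closure = (d_open - d) / (d_open - d_closed), clipped to [0, 1].

    Anchors are session-wide robust statistics: d_closed is the
    ``closed_percentile`` of all frame distances (blinks bring the eyelids
    together, so the low tail is the full-blink distance) and d_open is the
    ``open_percentile`` of pre-CS baseline distances (frames with
    time < ``baseline_end_s``; all frames when no baseline window is
    given).  Pass ``anchors=(d_open, d_closed)`` to override.
    """
    traces = list(raw_traces)
    if not traces:
        raise ValueError("normalize_session requires at least one trace")
    if anchors is not None:
        d_open, d_closed = map(float, anchors)
    else:
        all_vals = np.concatenate([t.values for t in traces])
        if baseline_end_s is None:
            base_vals = all_vals
        else:
            base_vals = np.concatenate(
                [t.values[t.times < baseline_end_s] for t in traces]
            )
            if base_vals.size == 0:
                raise ValueError("baseline window contains no frames")
        d_closed = float(np.percentile(all_vals, closed_percentile))
        d_open = float(np.percentile(base_vals, open_percentile))
    if d_open == d_closed:
        raise ValueError(
            "session anchors coincide (constant session?); cannot normalize"
        )
    span = d_open - d_closed
    out = []
    for t in traces:
        closure = np.clip((d_open - t.values) / span, 0.0, 1.0)
        out.append(EyelidTrace(closure, t.sampling_rate, t.trial_id))
    return out
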