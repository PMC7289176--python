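"""Foot-strike detection from ankle vertical velocity, step timing, stance.

Foot strikes are located from the vertical velocity of each ankle keypoint.
During swing the ankle rises then descends; the landing shows a peak of
downward velocity that decays back toward zero as the foot meets the ground.
The strike is placed, per step cycle, at the first sample after the peak
downward velocity where the downward speed decays through 35% of that
cycle's peak — a relative threshold, so detection is invariant to global
pixel scaling and to any constant offset of the position signal.

All velocities in this module are *up-positive*: image rows grow downward,
so the vertical position is negated before differencing.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

FOOT_LEFT = "left"
FOOT_RIGHT = "right"


@dataclass
class FootStrikeEvents:
    """Ordered foot-strike times for each foot, with a merged labelled view."""

    left: np.ndarray  # strictly increasing strike times (s)
    right: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        for arr, foot in ((self.left, "left"), (self.right, "right")):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{foot} strike times not strictly increasing")

    @property
    def merged(self) -> List[Tuple[float, str]]:
        """All strikes ordered in time as ``(time_s, foot)`` pairs."""
        pairs = [(t, FOOT_LEFT) for t in self.left] + [(t, FOOT_RIGHT) for t in self.right]
        return sorted(pairs)

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.merged])

    @property
    def feet(self) -> List[str]:
        return [f for _, f in self.merged]

    @property
    def n_strikes(self) -> int:
        return self.left.size + self.right.size


@dataclass
class StepSequence:
    """Durations between consecutive strikes and per-foot attributed time.

    A *step* ends at a strike; its duration is attributed to the foot that
    struck, so ``per_foot_time`` is the "time spent on each foot" entering the
    symmetry index.
    """

    step_times: np.ndarray  # (n_strikes - 1,) durations, s
    step_feet: List[str]  # foot terminating each step
    per_foot_time: Dict[str, float]


def vertical_velocity(ankle_y_px: np.ndarray, fs: float) -> np.ndarray:
    """Up-positive vertical velocity (px/s) by central differences.

    Image ``y`` grows downward, so the series is negated: a keypoint moving
    up the image yields positive velocity.  One-sided differences at the
    boundaries keep the output the same length as the input.
    """
    y = np.asarray(ankle_y_px, dtype=float)
    return -np.gradient(y) * fs


def detect_foot_strikes(
    velocity: np.ndarray,
    fs: float,
    threshold_frac: float = 0.35,
    min_step_interval_s: float = 0.25,
    peak_height_frac: float = 0.25,
) -> np.ndarray:
    """Strike times (s) for one ankle from its up-positive vertical velocity.

    Per step cycle: (i) candidate landings are prominent peaks of the
    *downward* velocity (at least ``peak_height_frac`` of the global downward
    maximum, separated by ``min_step_interval_s``); (ii) the cycle maximum is
    the velocity magnitude at that peak; (iii) the strike is the first sample
    after the peak where the downward velocity decays through
    ``threshold_frac`` x the cycle maximum; (iv) strikes closer than
    ``min_step_interval_s`` to the previous retained strike are dropped.
    """
    v = np.asarray(velocity, dtype=float)
    down = -v  # downward speed, positive while the foot is descending
    if down.size == 0 or not np.any(down > 0):
        return np.array([])
    dmax = float(down.max())
    min_dist = max(1, int(round(min_step_interval_s * fs)))
    peaks, _ = find_peaks(down, height=peak_height_frac * dmax, distance=min_dist)
    strikes: List[int] = []
    for i, p in enumerate(peaks):
        end = peaks[i + 1] if i + 1 < len(peaks) else down.size
        thr = threshold_frac * down[p]
        below = np.flatnonzero(down[p + 1 : end] <= thr)
        if below.size == 0:
            continue
        strikes.append(p + 1 + int(below[0]))
    # enforce the refractory interval between retained strikes
    kept: List[int] = []
    for s in strikes:
        if not kept or (s - kept[-1]) >= min_dist:
            kept.append(s)
    return np.asarray(kept, dtype=float) / fs


def step_times(events: FootStrikeEvents) -> StepSequence:
    """Durations between consecutive merged strikes and per-foot totals."""
    merged = events.merged
    if len(merged) < 2:
        return StepSequence(np.array([]), [], {FOOT_LEFT: 0.0, FOOT_RIGHT: 0.0})
    times = np.array([t for t, _ in merged])
    feet = [f for _, f in merged]
    durations = np.diff(times)
    step_feet = feet[1:]  # a step ends at (and is attributed to) its strike's foot
    per_foot = {FOOT_LEFT: 0.0, FOOT_RIGHT: 0.0}
    for d, f in zip(durations, step_feet):
        per_foot[f] += float(d)
    return StepSequence(durations, step_feet, per_foot)


def stance_foot(time_s: float, events: FootStrikeEvents) -> str:
    """Stance foot at a time: the foot of the most recent strike at/before it.

    Times before the first strike are assigned the first strike's foot.
    """
    merged = events.merged
    if not merged:
        raise ValueError("no strikes in bout; stance undefined")
    times = [t for t, _ in merged]
    i = bisect_right(times, time_s) - 1
    return merged[max(i, 0)][1]


def stance_series(n_frames: int, fs: float, events: FootStrikeEvents) -> np.ndarray:
    """Per-frame stance-foot labels (vectorised :func:`stance_foot`)."""
    merged = events.merged
    if not merged:
        raise ValueError("no strikes in bout; stance undefined")
    strike_t = np.array([t for t, _ in merged])
    feet = np.array([f for _, f in merged])
    t = np.arange(n_frames) / fs
    idx = np.clip(np.searchsorted(strike_t, t, side="right") - 1, 0, len(merged) - 1)
    return feet[idx]


def events_to_rows(events: FootStrikeEvents, bout_id: str, fs: float) -> List[dict]:
    """Tidy rows (bout_id, foot, time_s, frame_index) for CSV export."""
    return [
        {"bout_id": bout_id, "foot": foot, "time_s": t, "frame_index": int(round(t * fs))}
        for t, foot in events.merged
    ]
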