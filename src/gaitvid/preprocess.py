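"""Confidence gating, linear imputation, low-pass filtering, normalization.

Detector keypoints below a confidence threshold (default 0.4) are discarded
and re-filled by linear interpolation from temporally adjacent accepted
frames.  Trajectories are then smoothed with a zero-phase 2nd-order
Butterworth low-pass filter (4 Hz cutoff at 30 fps).  All pixel distances are
made scale-free by dividing by the mediolateral hip span — the pixel distance
between the left and right hip keypoints — which removes the perspective
growth of a walker approaching the camera.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy import signal

from .pose_io import REQUIRED_KEYPOINTS, WalkingBout

logger = logging.getLogger(__name__)


class BoutRejectedError(ValueError):
    """A bout cannot be preprocessed (too sparse / too short); carries a reason."""

    def __init__(self, bout_id: str, reason: str):
        self.bout_id = bout_id
        self.reason = reason
        super().__init__(f"bout {bout_id!r} rejected: {reason}")


@dataclass
class FilteredTrajectory:
    """Per-keypoint (x, y) time series after imputation (and filtering).

    ``imputed`` marks exactly the samples that were confidence-gated or
    missing and therefore re-filled.
    """

    data: Dict[str, np.ndarray]  # name -> (n, 2) float array
    imputed: Dict[str, np.ndarray]  # name -> (n,) bool array
    fs: float
    n_frames: int

    def get(self, name: str) -> np.ndarray:
        return self.data[name]

    @property
    def imputed_fraction(self) -> float:
        masks = np.concatenate([m for m in self.imputed.values()])
        return float(masks.mean()) if masks.size else 0.0


def _impute_series(values: np.ndarray, accepted: np.ndarray) -> np.ndarray:
    """Linear interpolation at rejected samples; constant fill at the edges."""
    idx = np.arange(values.shape[0], dtype=float)
    good = np.flatnonzero(accepted)
    out = values.copy()
    for col in range(values.shape[1]):
        out[:, col] = np.interp(idx, idx[good], values[good, col])
    return out


def threshold_and_impute(bout: WalkingBout, conf_threshold: float = 0.4) -> FilteredTrajectory:
    """Gate keypoints with confidence strictly below threshold and impute.

    Accepted samples are passed through unchanged; gated samples are replaced
    by linear interpolation between the nearest accepted neighbours (constant
    extrapolation at the bout edges).  A required keypoint with fewer than two
    accepted samples makes the bout unusable.
    """
    n = bout.n_frames
    data: Dict[str, np.ndarray] = {}
    imputed: Dict[str, np.ndarray] = {}
    for name in bout.schema.names:
        arr = bout.keypoint_series(name)
        accepted = (arr[:, 2] >= conf_threshold) & np.isfinite(arr[:, 0]) & np.isfinite(arr[:, 1])
        n_ok = int(accepted.sum())
        if n_ok < 2:
            if name in REQUIRED_KEYPOINTS:
                raise BoutRejectedError(
                    bout.bout_id, f"required keypoint {name!r} has {n_ok} accepted samples (<2)"
                )
            logger.warning("bout %s: keypoint %r unusable (%d accepted), dropped", bout.bout_id, name, n_ok)
            continue
        data[name] = _impute_series(arr[:, :2], accepted)
        imputed[name] = ~accepted
    return FilteredTrajectory(data=data, imputed=imputed, fs=bout.fps, n_frames=n)


def lowpass(
    series: np.ndarray,
    fs: float,
    cutoff_hz: float = 4.0,
    order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth low-pass along axis 0; zero-phase (filtfilt) by default.

    Zero-phase application preserves event timing at the cost of doubling the
    effective order.  Unit DC gain: a constant series passes unchanged.
    """
    series = np.asarray(series, dtype=float)
    if fs <= 2 * cutoff_hz:
        raise ValueError(f"fs={fs} must exceed twice the cutoff ({cutoff_hz} Hz)")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values; impute first")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if series.shape[0] <= padlen:
        raise ValueError(f"series length {series.shape[0]} below filter warm-up ({padlen + 1})")
    if zero_phase:
        return signal.filtfilt(b, a, series, axis=0)
    return signal.lfilter(b, a, series, axis=0)


def filter_trajectory(
    traj: FilteredTrajectory,
    cutoff_hz: float = 4.0,
    order: int = 2,
    zero_phase: bool = True,
) -> FilteredTrajectory:
    """Apply the low-pass filter to every keypoint trajectory."""
    try:
        data = {
            name: lowpass(xy, traj.fs, cutoff_hz=cutoff_hz, order=order, zero_phase=zero_phase)
            for name, xy in traj.data.items()
        }
    except ValueError as exc:
        raise BoutRejectedError("<trajectory>", str(exc)) from exc
    return FilteredTrajectory(data=data, imputed=dict(traj.imputed), fs=traj.fs, n_frames=traj.n_frames)


@dataclass
class NormalizationContext:
    """Per-frame hip span (px) used as the scale-free normalization unit."""

    hip_span: np.ndarray  # (n,) pixel distance left_hip -> right_hip
    policy: str = "per_frame"  # or "bout_median"
    floor_px: float = 1.0
    _median: float = field(init=False, default=np.nan)

    def __post_init__(self) -> None:
        usable = self.hip_span[self.hip_span > self.floor_px]
        self._median = float(np.median(usable)) if usable.size else np.nan

    @classmethod
    def from_trajectory(
        cls, traj: FilteredTrajectory, policy: str = "per_frame", floor_px: float = 1.0
    ) -> "NormalizationContext":
        lh, rh = traj.get("left_hip"), traj.get("right_hip")
        span = np.hypot(lh[:, 0] - rh[:, 0], lh[:, 1] - rh[:, 1])
        return cls(hip_span=span, policy=policy, floor_px=floor_px)

    def valid(self) -> np.ndarray:
        """Frames whose hip span is above the floor (usable for per-frame stats)."""
        return self.hip_span > self.floor_px

    def reference(self, frame_index: Optional[np.ndarray | int] = None) -> np.ndarray | float:
        """The normalization length for given frame(s) under the active policy."""
        if self.policy == "bout_median":
            if frame_index is None:
                return np.full_like(self.hip_span, self._median)
            return self._median if np.isscalar(frame_index) else np.full(np.shape(frame_index), self._median)
        if frame_index is None:
            return self.hip_span
        return self.hip_span[frame_index]

    def normalize(self, distance_px: np.ndarray | float, frame_index: Optional[np.ndarray | int] = None):
        """Dimensionless ratio ``distance_px / hip_span`` (per active policy)."""
        return np.asarray(distance_px, dtype=float) / self.reference(frame_index)
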