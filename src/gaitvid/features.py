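"""The seven per-bout gait variables and participant baseline aggregation.

Variables (all scale-free; pixel distances are divided by the mediolateral
hip span, positions enter only as differences so nothing depends on where
the walker is in the image):

* **cadence** — foot strikes per minute of bout duration.
* **SI of step time** — |T_left − T_right| / ((T_left + T_right)/2), where
  T_f is the time attributed to foot f's steps; 0 = perfectly symmetric.
* **CV of step time** — sd/mean of the inter-strike step durations.
* **average step width** — per-frame horizontal (image-x) ankle separation in
  hip-span units, averaged over frames.
* **CV of step width** — sd/mean of the width sampled once per step, at each
  strike frame.
* **average / minimum eMOS** — margin-of-stability construct: the estimated
  centre of mass (eCOM) is the hip midpoint; the extrapolated centre of mass
  (eXCOM) adds the eCOM's normalized horizontal velocity divided by
  sqrt(g / leg length) (inverted-pendulum scaling); eMOS is the signed
  normalized horizontal distance from the eXCOM to the stance-foot ankle,
  positive when the ankle is lateral of the eXCOM.  avg eMOS averages over
  frames, min eMOS averages each step's minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from datetime import datetime, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import events as ev
from .pose_io import WalkingBout, qc_bout
from .preprocess import (
    BoutRejectedError,
    FilteredTrajectory,
    NormalizationContext,
    filter_trajectory,
    threshold_and_impute,
)

logger = logging.getLogger(__name__)

GRAVITY_M_S2 = 9.81

FEATURE_NAMES = (
    "cadence",
    "si_step_time",
    "cv_step_time",
    "avg_step_width",
    "cv_step_width",
    "avg_emos",
    "min_emos",
)


class FeatureUndefined(ValueError):
    """A feature cannot be computed on this bout (recorded as absent)."""


@dataclass
class FeatureConfig:
    """All tunable parameters of the bout-level feature pipeline."""

    conf_threshold: float = 0.4  # confidence gate before imputation
    cutoff_hz: float = 4.0  # Butterworth low-pass cutoff
    filter_order: int = 2
    zero_phase: bool = True
    hip_span_floor_px: float = 1.0
    normalization_policy: str = "per_frame"
    threshold_frac: float = 0.35  # foot-strike crossing threshold
    min_step_interval_s: float = 0.25
    min_strikes: int = 3  # bouts with fewer steps are discarded
    g: float = GRAVITY_M_S2
    step_width_sampling: str = "per_step"  # or "per_frame" for the width CV


@dataclass
class GaitFeatureVector:
    """The seven gait variables for one walking bout (None = undefined)."""

    bout_id: str
    participant_id: str
    cadence: Optional[float] = None
    si_step_time: Optional[float] = None
    cv_step_time: Optional[float] = None
    avg_step_width: Optional[float] = None
    cv_step_width: Optional[float] = None
    avg_emos: Optional[float] = None
    min_emos: Optional[float] = None
    n_steps: int = 0
    duration_s: float = 0.0
    recorded_at: Optional[datetime] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class ComTrajectory:
    """eCOM path (hip midpoint, px) with what the eXCOM construction needs."""

    ecom: np.ndarray  # (n, 2) px
    ecom_velocity_px: np.ndarray  # (n, 2) px/s, central differences
    hip_span: np.ndarray  # (n,) px
    leg_length: float  # hip-span units
    fs: float


@dataclass
class ParticipantBaseline:
    """Per-feature mean over retained bouts within the enrollment window."""

    participant_id: str
    features: Dict[str, float]
    n_bouts: int
    window_days: int = 14


# -- elementary statistics ---------------------------------------------------


def cadence(events: ev.FootStrikeEvents, duration_s: float) -> float:
    """Steps per minute: merged foot strikes over bout duration in minutes."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return events.n_strikes / (duration_s / 60.0)


def symmetry_index(steps: ev.StepSequence) -> float:
    """|T_left − T_right| / (total attributed time / 2); range [0, 2]."""
    t_l, t_r = steps.per_foot_time[ev.FOOT_LEFT], steps.per_foot_time[ev.FOOT_RIGHT]
    if t_l <= 0 or t_r <= 0:
        raise FeatureUndefined("symmetry index needs at least one step per foot")
    return abs(t_l - t_r) / ((t_l + t_r) / 2.0)


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample (n−1) standard deviation over mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise FeatureUndefined("CV needs at least 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise FeatureUndefined("CV undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean)


# -- width -------------------------------------------------------------------


def _width_series(traj: FilteredTrajectory, context: NormalizationContext) -> np.ndarray:
    la, ra = traj.get("left_ankle"), traj.get("right_ankle")
    width_px = np.abs(la[:, 0] - ra[:, 0])
    out = np.asarray(context.normalize(width_px), dtype=float)
    out[~context.valid()] = np.nan  # hip span below floor: frame dropped
    return out


def avg_step_width(traj: FilteredTrajectory, context: NormalizationContext) -> float:
    """Mean over frames of normalized horizontal ankle separation."""
    w = _width_series(traj, context)
    if np.all(np.isnan(w)):
        raise FeatureUndefined("hip span below floor in every frame")
    return float(np.nanmean(w))


def step_widths_per_step(
    traj: FilteredTrajectory, events: ev.FootStrikeEvents, context: NormalizationContext
) -> np.ndarray:
    """Normalized ankle separation sampled once per step, at strike frames."""
    if events.n_strikes < 2:
        raise FeatureUndefined("need >=2 strikes for per-step widths")
    w = _width_series(traj, context)
    idx = np.clip(np.round(events.times * traj.fs).astype(int), 0, traj.n_frames - 1)
    vals = w[idx]
    return vals[np.isfinite(vals)]


# -- eCOM / eXCOM / eMOS -----------------------------------------------------


def com_trajectory(
    traj: FilteredTrajectory,
    events: ev.FootStrikeEvents,
    context: NormalizationContext,
) -> ComTrajectory:
    """eCOM (hip midpoint) path with velocity and the leg-length estimate."""
    lh, rh = traj.get("left_hip"), traj.get("right_hip")
    ecom = (lh + rh) / 2.0
    vel = np.gradient(ecom, axis=0) * traj.fs
    leg = leg_length_estimate(traj, events, context)
    return ComTrajectory(ecom=ecom, ecom_velocity_px=vel, hip_span=context.hip_span, leg_length=leg, fs=traj.fs)


def leg_length_estimate(
    traj: FilteredTrajectory, events: ev.FootStrikeEvents, context: NormalizationContext
) -> float:
    """Normalized hip→ankle length at strike frames, averaged per foot then
    between feet.  A foot with no strikes falls back to the other foot's mean."""
    ref = context.reference()
    per_foot: Dict[str, float] = {}
    for foot, times in ((ev.FOOT_LEFT, events.left), (ev.FOOT_RIGHT, events.right)):
        if times.size == 0:
            continue
        hip, ankle = traj.get(f"{foot}_hip"), traj.get(f"{foot}_ankle")
        idx = np.clip(np.round(times * traj.fs).astype(int), 0, traj.n_frames - 1)
        d = np.hypot(hip[idx, 0] - ankle[idx, 0], hip[idx, 1] - ankle[idx, 1]) / np.asarray(ref)[idx]
        d = d[np.isfinite(d)]
        if d.size:
            per_foot[foot] = float(d.mean())
    if not per_foot:
        raise FeatureUndefined("no strike frames with usable hip span for leg length")
    if len(per_foot) == 1:
        only = next(iter(per_foot))
        logger.warning("one foot has no strikes; using %s leg length for both", only)
        return per_foot[only]
    return float(np.mean(list(per_foot.values())))


def excom_series(com: ComTrajectory, g: float = GRAVITY_M_S2) -> np.ndarray:
    """eXCOM horizontal coordinate, hip-span units, per frame.

    eXCOM(t) = eCOM_norm(t) + v_norm(t) / sqrt(g / leg_length), with the
    velocity normalized *after* differencing so a constant image offset
    cannot leak into the extrapolation term.
    """
    if com.leg_length <= 0:
        raise ValueError("leg length must be positive")
    omega = np.sqrt(g / com.leg_length)
    ecom_norm = com.ecom[:, 0] / com.hip_span
    v_norm = com.ecom_velocity_px[:, 0] / com.hip_span
    return ecom_norm + v_norm / omega


def emos_series(
    traj: FilteredTrajectory,
    events: ev.FootStrikeEvents,
    com: ComTrajectory,
    g: float = GRAVITY_M_S2,
) -> np.ndarray:
    """Signed normalized eMOS per frame (nan before the first strike).

    m(t) = s(t) · (ankle_x − eXCOM_x) / hip_span with s(t) = ±1 choosing the
    lateral direction of the stance foot relative to the eCOM, so the margin
    is positive while the stance ankle lies lateral (outside) of the eXCOM.
    """
    n = traj.n_frames
    stance = ev.stance_series(n, traj.fs, events)
    excom = excom_series(com, g=g)
    la, ra = traj.get("left_ankle"), traj.get("right_ankle")
    ankle_x = np.where(stance == ev.FOOT_LEFT, la[:, 0], ra[:, 0])
    ankle_norm = ankle_x / com.hip_span
    ecom_norm = com.ecom[:, 0] / com.hip_span
    side = np.sign(ankle_norm - ecom_norm)
    side[side == 0] = 1.0
    m = side * (ankle_norm - excom)
    first_idx = int(np.ceil(events.times[0] * traj.fs))
    m[: max(first_idx, 0)] = np.nan  # no stance assignment before the first strike
    return m


def emos(
    traj: FilteredTrajectory,
    events: ev.FootStrikeEvents,
    com: ComTrajectory,
    g: float = GRAVITY_M_S2,
) -> Tuple[float, float]:
    """(avg eMOS over frames, mean over steps of each step's minimum eMOS)."""
    m = emos_series(traj, events, com, g=g)
    if np.all(np.isnan(m)):
        raise FeatureUndefined("no frames with stance assignment")
    avg = float(np.nanmean(m))
    times = events.times
    if times.size < 2:
        raise FeatureUndefined("min eMOS needs >=2 strikes")
    mins: List[float] = []
    for t0, t1 in zip(times[:-1], times[1:]):
        i0, i1 = int(np.ceil(t0 * traj.fs)), int(np.ceil(t1 * traj.fs))
        seg = m[i0 : max(i1, i0 + 1)]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            mins.append(float(seg.min()))
    if not mins:
        raise FeatureUndefined("no step segments with defined eMOS")
    return avg, float(np.mean(mins))


# -- per-bout orchestration --------------------------------------------------


def detect_events(traj: FilteredTrajectory, config: FeatureConfig = FeatureConfig()) -> ev.FootStrikeEvents:
    """Per-foot strike detection on the filtered ankle trajectories."""
    strikes = {}
    for foot in (ev.FOOT_LEFT, ev.FOOT_RIGHT):
        v = ev.vertical_velocity(traj.get(f"{foot}_ankle")[:, 1], traj.fs)
        strikes[foot] = ev.detect_foot_strikes(
            v,
            traj.fs,
            threshold_frac=config.threshold_frac,
            min_step_interval_s=config.min_step_interval_s,
        )
    return ev.FootStrikeEvents(left=strikes[ev.FOOT_LEFT], right=strikes[ev.FOOT_RIGHT])


def extract_features(bout: WalkingBout, config: FeatureConfig = FeatureConfig()) -> GaitFeatureVector:
    """Run the full per-bout pipeline: gate → impute → filter → events → features.

    Bouts with fewer than ``config.min_strikes`` detected strikes are flagged
    ``too_few_steps`` and rejected.  Individual features that are undefined on
    a bout are recorded as absent (None), never as zero.
    """
    traj = threshold_and_impute(bout, conf_threshold=config.conf_threshold)
    traj = filter_trajectory(
        traj, cutoff_hz=config.cutoff_hz, order=config.filter_order, zero_phase=config.zero_phase
    )
    context = NormalizationContext.from_trajectory(
        traj, policy=config.normalization_policy, floor_px=config.hip_span_floor_px
    )
    events = detect_events(traj, config)
    qc_bout(bout, events.n_strikes, min_strikes=config.min_strikes)
    if "too_few_steps" in bout.exclusion_flags:
        raise BoutRejectedError(bout.bout_id, f"too_few_steps ({events.n_strikes} strikes)")

    vec = GaitFeatureVector(
        bout_id=bout.bout_id,
        participant_id=bout.participant_id,
        n_steps=events.n_strikes,
        duration_s=bout.duration_s,
        recorded_at=bout.recorded_at,
    )
    steps = ev.step_times(events)
    vec.cadence = cadence(events, bout.duration_s)

    def _try(name, fn):
        try:
            setattr(vec, name, fn())
        except FeatureUndefined as exc:
            logger.info("bout %s: %s undefined (%s)", bout.bout_id, name, exc)

    _try("si_step_time", lambda: symmetry_index(steps))
    _try("cv_step_time", lambda: cv(steps.step_times))
    _try("avg_step_width", lambda: avg_step_width(traj, context))
    if config.step_width_sampling == "per_frame":
        _try("cv_step_width", lambda: cv(_finite(_width_series(traj, context))))
    else:
        _try("cv_step_width", lambda: cv(step_widths_per_step(traj, events, context)))

    def _emos_pair():
        com = com_trajectory(traj, events, context)
        return emos(traj, events, com, g=config.g)

    try:
        vec.avg_emos, vec.min_emos = _emos_pair()
    except FeatureUndefined as exc:
        logger.info("bout %s: eMOS undefined (%s)", bout.bout_id, exc)
    return vec


def _finite(arr: np.ndarray) -> np.ndarray:
    return arr[np.isfinite(arr)]


def baseline_aggregate(
    vectors: Sequence[GaitFeatureVector],
    enrollment_date: datetime,
    window_days: int = 14,
) -> ParticipantBaseline:
    """Average features over retained bouts recorded within the first
    ``window_days`` of enrollment (the participant's baseline gait)."""
    cutoff = enrollment_date + timedelta(days=window_days)
    in_window = [
        v for v in vectors if v.recorded_at is not None and enrollment_date <= v.recorded_at <= cutoff
    ]
    if not in_window:
        raise ValueError("no retained bouts within the baseline window")
    means: Dict[str, float] = {}
    for name in FEATURE_NAMES:
        vals = [getattr(v, name) for v in in_window if getattr(v, name) is not None]
        means[name] = float(np.mean(vals)) if vals else np.nan
    pid = in_window[0].participant_id
    return ParticipantBaseline(
        participant_id=pid, features=means, n_bouts=len(in_window), window_days=window_days
    )
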