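"""Synthetic walking bouts, annotation fixtures and cohorts with ground truth.

The bout generator emulates the study geometry: a walker approaching a
ceiling-mounted hallway camera, so the skeleton's pixel size grows over the
bout (modelled as isotropic scale growth — adequate for probing the hip-span
normalization, no full pinhole projection).  Kinematics: hips sway
laterally; feet alternate, the stance ankle quasi-static while the swing
ankle traces a half-sine-squared vertical arc per step at the programmed
cadence, landing at a programmed step width (in hip-span units) with
optional per-step jitter and step-time asymmetry.  Gaussian pixel noise and
low-confidence dropouts emulate detector error.  Every generated quantity
(contact times, stance intervals, per-step widths, realized cadence/SI/CV,
leg length, eCOM path) is recorded as ground truth.

Generated cohorts mirror the magnitudes of a small dementia-unit study:
~31 participants observed for ~44 +/- 19 days, fall counts from a log-link
Poisson rate model with exposure, POMA scores linear in designated features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pose_io import (
    DEFAULT_SCHEMA,
    Keypoint,
    KeypointSchema,
    PoseFrame,
    WalkingBout,
    write_bout,
    write_manifest,
)
from .validation import AnnotationSet, Predictions

PARTICIPANT_TRACK = "0"
ASSISTANT_TRACK = "1"


@dataclass
class GaitSimParams:
    """Parameters of one synthetic walking bout (defaults = study-like)."""

    fps: float = 30.0
    duration_s: float = 10.0
    cadence_spm: float = 100.0  # programmed steps per minute
    step_width_ratio: float = 0.5  # ankle separation in hip-span units
    stance_time_split: float = 0.5  # share of a stride attributed to the left foot
    hip_span_start_px: float = 100.0
    perspective_scale_end: float = 1.5  # size multiplier at bout end (>= 1)
    sway_amplitude: float = 0.08  # lateral eCOM sway, hip-span units
    leg_length_ratio: float = 3.0  # hip->ankle length, hip-span units
    swing_fraction: float = 0.7  # share of a step spent in swing
    arc_height: float = 0.35  # swing foot lift, hip-span units
    width_jitter_cv: float = 0.0  # per-step landing-width jitter (CV)
    pixel_noise_sd: float = 1.0
    dropout_rate: float = 0.05
    dropout_confidence: Tuple[float, float] = (0.0, 0.35)
    good_confidence: Tuple[float, float] = (0.6, 1.0)
    dropout_displacement_px: float = 40.0
    assistant_track: bool = False
    image_center: Tuple[float, float] = (960.0, 540.0)
    bout_id: str = "sim"
    participant_id: str = "p0"
    recorded_at: Optional[datetime] = None
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything the generator knows about the bout it emitted."""

    contact_times_left: np.ndarray
    contact_times_right: np.ndarray
    stance_intervals: List[Tuple[float, float, str]]  # single-support (start, end, stance foot)
    per_step_widths: np.ndarray  # normalized width at each merged contact
    ecom_x: np.ndarray  # clean lateral eCOM path, hip-span units
    features: Dict[str, float]  # realized cadence/si/cv/width/leg length
    cadence_programmed: float
    track_id: str = PARTICIPANT_TRACK

    @property
    def contact_times(self) -> np.ndarray:
        return np.sort(np.concatenate([self.contact_times_left, self.contact_times_right]))

    @property
    def n_contacts(self) -> int:
        return self.contact_times_left.size + self.contact_times_right.size


def _contact_schedule(p: GaitSimParams) -> Tuple[List[float], List[str]]:
    t_step = 60.0 / p.cadence_spm
    asym = 2.0 * p.stance_time_split - 1.0
    dur = {"left": t_step * (1.0 + asym), "right": t_step * (1.0 - asym)}
    t0 = max(0.5, p.swing_fraction * max(dur.values())) + 0.1
    times, feet = [], []
    t, foot = t0, "left"
    while t <= p.duration_s - 0.15:
        times.append(t)
        feet.append(foot)
        foot = "right" if foot == "left" else "left"
        t += dur[foot]
    return times, feet


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _body_pose(p: GaitSimParams, rng: np.random.Generator):
    """Clean per-frame unit-coordinate skeleton plus ground truth.

    Units: nominal hip span = 1; origin at the body midline, hip height 0,
    y growing downward (image convention).
    """
    n = int(round(p.duration_s * p.fps))
    t = np.arange(n) / p.fps
    contact_times, contact_feet = _contact_schedule(p)
    t_step = 60.0 / p.cadence_spm
    asym = 2.0 * p.stance_time_split - 1.0
    dur = {"left": t_step * (1.0 + asym), "right": t_step * (1.0 - asym)}

    w = p.step_width_ratio
    dx_hip_ankle = abs(0.5 - w / 2.0)
    y_ground = math.sqrt(max(p.leg_length_ratio**2 - dx_hip_ankle**2, 1e-6))

    stride_hz = p.cadence_spm / 120.0
    t0 = contact_times[0] if contact_times else 0.0
    ecom_x = p.sway_amplitude * np.sin(2.0 * math.pi * stride_hz * (t - t0))

    sign = {"left": -1.0, "right": 1.0}
    foot_x = {f: np.full(n, sign[f] * w / 2.0) for f in ("left", "right")}
    foot_y = {f: np.full(n, y_ground) for f in ("left", "right")}

    stance_intervals: List[Tuple[float, float, str]] = []
    per_step_widths: List[float] = []
    landing_x = {"left": -w / 2.0, "right": w / 2.0}
    for tc, foot in zip(contact_times, contact_feet):
        jitter = rng.normal(0.0, p.width_jitter_cv) if p.width_jitter_cv > 0 else 0.0
        w_target = w * max(0.05, 1.0 + jitter)
        new_x = sign[foot] * w_target / 2.0
        # swing time is a share of the *average* step: timing asymmetry loads
        # onto stance, as in real asymmetric gait
        dsw = min(p.swing_fraction * t_step, 0.95 * dur[foot])
        swing = (t >= tc - dsw) & (t < tc)
        tau = (t - (tc - dsw)) / dsw
        foot_y[foot] = np.where(swing, y_ground - p.arc_height * np.sin(np.pi * np.clip(tau, 0, 1)) ** 2, foot_y[foot])
        old_x = landing_x[foot]
        foot_x[foot] = np.where(swing, old_x + (new_x - old_x) * _smoothstep(tau), foot_x[foot])
        foot_x[foot][t >= tc] = new_x
        landing_x[foot] = new_x
        other = "right" if foot == "left" else "left"
        stance_intervals.append((tc - dsw, tc, other))
        per_step_widths.append(abs(new_x - landing_x[other]))

    width_series = np.abs(foot_x["left"] - foot_x["right"])

    pose: Dict[str, Tuple[np.ndarray, np.ndarray]] = {
        "left_hip": (ecom_x - 0.5, np.zeros(n)),
        "right_hip": (ecom_x + 0.5, np.zeros(n)),
        "pelvis": (ecom_x, np.full(n, 0.05)),
        "neck": (ecom_x, np.full(n, -1.8)),
        "head_top": (ecom_x, np.full(n, -2.2)),
        "left_shoulder": (ecom_x - 0.45, np.full(n, -1.6)),
        "right_shoulder": (ecom_x + 0.45, np.full(n, -1.6)),
        "left_elbow": (ecom_x - 0.55, np.full(n, -1.0)),
        "right_elbow": (ecom_x + 0.55, np.full(n, -1.0)),
        "left_ankle": (foot_x["left"], foot_y["left"]),
        "right_ankle": (foot_x["right"], foot_y["right"]),
        "left_knee": ((ecom_x - 0.5 + foot_x["left"]) / 2.0, (foot_y["left"]) * 0.55),
        "right_knee": ((ecom_x + 0.5 + foot_x["right"]) / 2.0, (foot_y["right"]) * 0.55),
    }

    # realized ground-truth features from the emitted schedule
    merged = np.asarray(contact_times)
    features: Dict[str, float] = {"leg_length": np.nan, "cadence": 0.0}
    features["cadence"] = merged.size / (p.duration_s / 60.0)
    if merged.size >= 2:
        durations = np.diff(merged)
        features["cv_step_time"] = float(durations.std(ddof=1) / durations.mean()) if durations.size >= 2 else np.nan
        per_foot = {"left": 0.0, "right": 0.0}
        for d, f in zip(durations, contact_feet[1:]):
            per_foot[f] += float(d)
        if per_foot["left"] > 0 and per_foot["right"] > 0:
            total = per_foot["left"] + per_foot["right"]
            features["si_step_time"] = abs(per_foot["left"] - per_foot["right"]) / (total / 2.0)
    features["avg_step_width"] = float(width_series.mean())
    # leg length at contacts, per foot, from the clean geometry
    leg_means = []
    for foot in ("left", "right"):
        ds = []
        for tc, f in zip(contact_times, contact_feet):
            if f != foot:
                continue
            i = min(int(round(tc * p.fps)), n - 1)
            hip_x = ecom_x[i] + sign[foot] * 0.5
            ds.append(math.hypot(hip_x - foot_x[foot][i], foot_y[foot][i]))
        if ds:
            leg_means.append(float(np.mean(ds)))
    if leg_means:
        features["leg_length"] = float(np.mean(leg_means))

    truth = GroundTruth(
        contact_times_left=np.array([tc for tc, f in zip(contact_times, contact_feet) if f == "left"]),
        contact_times_right=np.array([tc for tc, f in zip(contact_times, contact_feet) if f == "right"]),
        stance_intervals=stance_intervals,
        per_step_widths=np.asarray(per_step_widths),
        ecom_x=ecom_x,
        features=features,
        cadence_programmed=p.cadence_spm,
    )
    return t, pose, truth


def simulate_pose_frames(
    params: GaitSimParams, schema: KeypointSchema = DEFAULT_SCHEMA
) -> Tuple[List[PoseFrame], GroundTruth]:
    """Raw multi-person pose frames (participant plus optional assistant)."""
    rng = np.random.default_rng(params.seed)
    t, pose, truth = _body_pose(params, rng)
    n = t.size
    cx, cy = params.image_center
    scale = params.hip_span_start_px * (
        1.0 + (params.perspective_scale_end - 1.0) * t / max(params.duration_s, 1e-9)
    )

    frames: List[PoseFrame] = []
    tracks_px: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
    tracks_px[PARTICIPANT_TRACK] = {
        name: (cx + scale * ux, cy + scale * uy) for name, (ux, uy) in pose.items()
    }
    if params.assistant_track:
        a_scale = 0.5 * params.hip_span_start_px
        jx = rng.normal(0.0, 0.02, size=n)
        tracks_px[ASSISTANT_TRACK] = {
            name: (cx + 350.0 + a_scale * (ux[:1].repeat(n) + jx), cy - 80.0 + a_scale * uy[:1].repeat(n))
            for name, (ux, uy) in pose.items()
        }

    noise = {
        tid: rng.normal(0.0, params.pixel_noise_sd, size=(n, len(schema), 2))
        for tid in tracks_px
    }
    dropout = {tid: rng.random(size=(n, len(schema))) < params.dropout_rate for tid in tracks_px}
    conf_good = {
        tid: rng.uniform(*params.good_confidence, size=(n, len(schema))) for tid in tracks_px
    }
    conf_bad = {
        tid: rng.uniform(*params.dropout_confidence, size=(n, len(schema))) for tid in tracks_px
    }
    displace = {
        tid: rng.uniform(-params.dropout_displacement_px, params.dropout_displacement_px, size=(n, len(schema), 2))
        for tid in tracks_px
    }

    names = list(schema.names)
    for i in range(n):
        people: Dict[str, Dict[str, Keypoint]] = {}
        for tid, kp_map in tracks_px.items():
            kps: Dict[str, Keypoint] = {}
            for j, name in enumerate(names):
                if name not in kp_map:
                    continue
                x = kp_map[name][0][i] + noise[tid][i, j, 0]
                y = kp_map[name][1][i] + noise[tid][i, j, 1]
                if dropout[tid][i, j]:
                    kps[name] = Keypoint(
                        x + displace[tid][i, j, 0], y + displace[tid][i, j, 1], float(conf_bad[tid][i, j])
                    )
                else:
                    kps[name] = Keypoint(x, y, float(conf_good[tid][i, j]))
            people[tid] = kps
        frames.append(PoseFrame(i, i / params.fps, people))
    return frames, truth


def simulate_bout(
    params: GaitSimParams, schema: KeypointSchema = DEFAULT_SCHEMA
) -> Tuple[WalkingBout, GroundTruth]:
    """One synthetic walking bout restricted to the participant track.

    Deterministic given ``params.seed``.  Parameter combinations yielding
    fewer than 3 steps are generated but pre-flagged ``too_few_steps``.
    """
    frames, truth = simulate_pose_frames(params, schema=schema)
    participant_frames = [
        PoseFrame(f.frame_index, f.time_s, {PARTICIPANT_TRACK: f.person_tracks[PARTICIPANT_TRACK]})
        for f in frames
    ]
    bout = WalkingBout(
        bout_id=params.bout_id,
        participant_id=params.participant_id,
        fps=params.fps,
        frames=participant_frames,
        track_id=PARTICIPANT_TRACK,
        recorded_at=params.recorded_at,
        schema=schema,
    )
    if truth.n_contacts < 3:
        bout.exclusion_flags.add("too_few_steps")
    return bout, truth


# -- annotation fixtures -----------------------------------------------------


def make_annotation_fixture(
    bout: WalkingBout,
    jitter_sd_px: float = 2.0,
    inaccurate_fraction: float = 0.2,
    n_images: int = 6,
    seed: int = 0,
) -> Tuple[Predictions, AnnotationSet]:
    """Prediction/annotation pairs with a *known* fraction of gross errors.

    Annotations are the bout's keypoints; an exact ``inaccurate_fraction`` of
    predictions is displaced beyond the PCKh@0.5 threshold (1.5-2.5 head
    lengths) with low confidence, the rest jittered within 0.45 head lengths
    with high confidence — so PCKh equals 1 − inaccurate_fraction by count,
    and a confidence sweep is monotone by construction.
    """
    rng = np.random.default_rng(seed)
    frame_ids = np.linspace(0, bout.n_frames - 1, num=min(n_images, bout.n_frames), dtype=int)
    ann_points: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for fi in frame_ids:
        kps = bout.frames[fi].person_tracks.get(bout.track_id, {})
        img = f"{bout.bout_id}_f{fi}"
        for name, kp in kps.items():
            if not kp.is_missing:
                ann_points[(img, name)] = (kp.x, kp.y)
    annotations = AnnotationSet.from_points(ann_points)

    keys = sorted(ann_points)
    n_bad = int(round(inaccurate_fraction * len(keys)))
    bad = set(int(i) for i in rng.permutation(len(keys))[:n_bad])
    predictions: Predictions = {}
    for i, (img, name) in enumerate(keys):
        x, y = ann_points[(img, name)]
        h = annotations.head_lengths[img]
        angle = rng.uniform(0.0, 2.0 * math.pi)
        if i in bad:
            r = rng.uniform(1.5 * h, 2.5 * h)
            conf = rng.uniform(0.02, 0.38)
        else:
            r = min(abs(rng.normal(0.0, jitter_sd_px)), 0.45 * h)
            conf = rng.uniform(0.62, 1.0)
        predictions[(img, name)] = (x + r * math.cos(angle), y + r * math.sin(angle), float(conf))
    return predictions, annotations


# -- cohorts -----------------------------------------------------------------

_DEF_MEANS = {
    "cadence": 95.0,
    "si_step_time": 0.15,
    "cv_step_time": 0.12,
    "avg_step_width": 0.45,
    "cv_step_width": 0.15,
    "avg_emos": 0.35,
    "min_emos": 0.15,
}
_DEF_SDS = {
    "cadence": 15.0,
    "si_step_time": 0.08,
    "cv_step_time": 0.05,
    "avg_step_width": 0.12,
    "cv_step_width": 0.06,
    "avg_emos": 0.10,
    "min_emos": 0.08,
}


@dataclass
class CohortSimParams:
    """Parameters of a synthetic participant cohort.

    ``betas`` are log fall-rate coefficients per unit of each (mean-centered)
    feature; ``base_rate_per_day`` anchors the average faller profile
    (~1.4 falls over ~44 observed days).  The eMOS pair is generated with a
    high mutual correlation, matching its construction (one is a per-step
    minimum of the other's signal).
    """

    n_participants: int = 31
    feature_means: Dict[str, float] = field(default_factory=lambda: dict(_DEF_MEANS))
    feature_sds: Dict[str, float] = field(default_factory=lambda: dict(_DEF_SDS))
    emos_correlation: float = 0.9
    betas: Dict[str, float] = field(
        default_factory=lambda: {"cadence": 0.06, "avg_emos": -9.0, "avg_step_width": -1.5}
    )
    base_rate_per_day: float = 1.4 / 44.0
    exposure_mean_days: float = 44.0
    exposure_sd_days: float = 19.0
    exposure_range_days: Tuple[float, float] = (14.0, 90.0)
    poma_gait_coefs: Dict[str, float] = field(default_factory=lambda: {"cadence": -0.06})
    poma_gait_intercept: float = 8.2  # at the feature means
    poma_gait_noise_sd: float = 1.5
    poma_gait_range: Tuple[int, int] = (0, 12)
    poma_balance_coefs: Dict[str, float] = field(
        default_factory=lambda: {"cadence": -0.05, "avg_step_width": 7.0}
    )
    poma_balance_intercept: float = 8.8
    poma_balance_noise_sd: float = 1.8
    poma_balance_range: Tuple[int, int] = (0, 16)
    seed: int = 0


def _cohort_correlation(names: Sequence[str], emos_r: float) -> np.ndarray:
    corr = np.eye(len(names))
    i, j = names.index("avg_emos"), names.index("min_emos")
    corr[i, j] = corr[j, i] = emos_r
    return corr


def simulate_cohort(params: CohortSimParams) -> Tuple[pd.DataFrame, Dict]:
    """Participant records (features, POMA scores, falls, exposure) + truth."""
    rng = np.random.default_rng(params.seed)
    names = list(params.feature_means)
    corr = _cohort_correlation(names, params.emos_correlation)
    z = rng.multivariate_normal(np.zeros(len(names)), corr, size=params.n_participants)
    sds = np.array([params.feature_sds[n] for n in names])
    means = np.array([params.feature_means[n] for n in names])
    X = means + z * sds

    exposure = np.clip(
        rng.normal(params.exposure_mean_days, params.exposure_sd_days, size=params.n_participants),
        *params.exposure_range_days,
    )
    centered = X - means
    eta = math.log(params.base_rate_per_day) + centered @ np.array(
        [params.betas.get(n, 0.0) for n in names]
    )
    n_falls = rng.poisson(exposure * np.exp(eta))

    def _poma(coefs: Dict[str, float], intercept: float, noise_sd: float, lo_hi: Tuple[int, int]) -> np.ndarray:
        lin = intercept + centered @ np.array([coefs.get(n, 0.0) for n in names])
        raw = lin + rng.normal(0.0, noise_sd, size=params.n_participants)
        return np.clip(np.round(raw), *lo_hi).astype(int)

    records = pd.DataFrame(X, columns=names)
    records.insert(0, "participant_id", [f"p{i:03d}" for i in range(params.n_participants)])
    records["poma_gait"] = _poma(
        params.poma_gait_coefs, params.poma_gait_intercept, params.poma_gait_noise_sd, params.poma_gait_range
    )
    records["poma_balance"] = _poma(
        params.poma_balance_coefs,
        params.poma_balance_intercept,
        params.poma_balance_noise_sd,
        params.poma_balance_range,
    )
    records["n_falls"] = n_falls
    records["exposure_days"] = exposure
    truth = {
        "betas": {n: params.betas.get(n, 0.0) for n in names},
        "base_rate_per_day": params.base_rate_per_day,
        "feature_means": dict(params.feature_means),
        "emos_correlation": params.emos_correlation,
    }
    return records, truth


# -- bout manifests (for end-to-end pipeline runs) ---------------------------


def simulate_manifest(
    out_dir: str | Path,
    n_bouts: int = 100,
    flagged_fraction: float = 0.2,
    n_participants: int = 5,
    seed: int = 0,
    duration_s: float = 8.0,
    enrollment: datetime = datetime(2018, 1, 1),
) -> Tuple[Path, Dict]:
    """Write synthetic bout files plus a manifest CSV; returns (path, truth).

    Exactly ``round(flagged_fraction * n_bouts)`` bouts carry a manual
    exclusion flag (handrail / turned_around / occluded), emulating the
    visual-preprocessing discards of the source study.  Bout timestamps fall
    within each participant's first two weeks.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_flagged = int(round(flagged_fraction * n_bouts))
    flagged = set(int(i) for i in rng.permutation(n_bouts)[:n_flagged])
    flag_names = ["handrail", "turned_around", "occluded"]

    per_participant_cadence = rng.uniform(70.0, 120.0, size=n_participants)
    per_participant_width = rng.uniform(0.3, 0.8, size=n_participants)
    rows = []
    truth: Dict = {"flagged_bout_ids": [], "bout_truth": {}}
    for i in range(n_bouts):
        pi = i % n_participants
        bout_id = f"b{i:04d}"
        recorded_at = enrollment + timedelta(days=float(rng.uniform(0.0, 13.0)))
        params = GaitSimParams(
            duration_s=duration_s,
            cadence_spm=float(per_participant_cadence[pi] + rng.normal(0.0, 3.0)),
            step_width_ratio=float(np.clip(per_participant_width[pi] + rng.normal(0.0, 0.03), 0.2, 1.0)),
            pixel_noise_sd=1.0,
            dropout_rate=0.05,
            bout_id=bout_id,
            participant_id=f"p{pi}",
            recorded_at=recorded_at,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bout, bout_truth = simulate_bout(params)
        path = out_dir / f"{bout_id}.json"
        write_bout(bout, path)
        flags = ""
        if i in flagged:
            flags = flag_names[i % len(flag_names)]
            truth["flagged_bout_ids"].append(bout_id)
        truth["bout_truth"][bout_id] = bout_truth.features
        rows.append(
            {
                "bout_id": bout_id,
                "participant_id": f"p{pi}",
                "recorded_at": recorded_at.isoformat(),
                "fps": params.fps,
                "path": str(path),
                "flags": flags,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    write_manifest(rows, manifest_path)
    truth["flagged_fraction"] = n_flagged / n_bouts
    return manifest_path, truth
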