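"""Reading, writing and assembling 2D pose-keypoint walking bouts.

The input contract mirrors the per-frame JSON emitted by common 2D human pose
estimators: each frame maps person-track ids to keypoint labels, each keypoint
being an ``[x, y, confidence]`` triple in image coordinates (``x`` = column,
``y`` = row, increasing *downward*; confidence in ``[0, 1]``).  A *walking
bout* is one continuous recorded walk of a single participant past the
camera; bouts are assembled by selecting exactly one person track from the
raw multi-person frames.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Keypoints the downstream gait math cannot do without.
REQUIRED_KEYPOINTS = frozenset(
    {"left_hip", "right_hip", "left_ankle", "right_ankle", "head_top", "neck"}
)

#: Default 13-keypoint schema (required six plus an MPII-style limb set).
DEFAULT_KEYPOINT_NAMES: Tuple[str, ...] = (
    "head_top",
    "neck",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "pelvis",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: Manual bout-level exclusion reasons plus the automated step-count rule.
EXCLUSION_FLAGS = ("handrail", "turned_around", "occluded", "too_few_steps")
MANUAL_FLAGS = frozenset({"handrail", "turned_around", "occluded"})


class PoseFormatError(ValueError):
    """Raised when a pose file does not parse as the documented dialect."""


class EmptyBoutError(ValueError):
    """Raised when a bout contains no person tracks at all."""


@dataclass(frozen=True)
class Keypoint:
    """A single 2D keypoint detection: image coords (px) and confidence."""

    x: float
    y: float
    confidence: float

    @property
    def is_missing(self) -> bool:
        return not (math.isfinite(self.x) and math.isfinite(self.y))


#: Sentinel for a keypoint the detector did not produce.
MISSING_KEYPOINT = Keypoint(float("nan"), float("nan"), 0.0)


@dataclass(frozen=True)
class KeypointSchema:
    """Ordered keypoint label set; the six required labels must be present."""

    names: Tuple[str, ...] = DEFAULT_KEYPOINT_NAMES

    def __post_init__(self) -> None:
        missing = REQUIRED_KEYPOINTS - set(self.names)
        if missing:
            raise ValueError(f"schema missing required keypoints: {sorted(missing)}")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)


DEFAULT_SCHEMA = KeypointSchema()


@dataclass
class PoseFrame:
    """All person detections in one video frame."""

    frame_index: int
    time_s: float
    person_tracks: Dict[str, Dict[str, Keypoint]] = field(default_factory=dict)


@dataclass
class WalkingBout:
    """One recorded walk, restricted to a single selected person track."""

    bout_id: str
    participant_id: str
    fps: float
    frames: List[PoseFrame]
    track_id: str = "0"
    recorded_at: Optional[datetime] = None
    schema: KeypointSchema = DEFAULT_SCHEMA
    exclusion_flags: Set[str] = field(default_factory=set)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def is_excluded(self) -> bool:
        return bool(self.exclusion_flags)

    def keypoint_series(self, name: str) -> np.ndarray:
        """Per-frame ``(x, y, confidence)`` array for one keypoint, shape (n, 3).

        Frames where the selected track (or the keypoint) is absent appear as
        ``(nan, nan, 0)``.
        """
        out = np.full((self.n_frames, 3), np.nan)
        out[:, 2] = 0.0
        for i, frame in enumerate(self.frames):
            kps = frame.person_tracks.get(self.track_id)
            if kps is None:
                continue
            kp = kps.get(name, MISSING_KEYPOINT)
            out[i] = (kp.x, kp.y, kp.confidence)
        return out

    def transformed(self, scale: float = 1.0, offset: Tuple[float, float] = (0.0, 0.0)) -> "WalkingBout":
        """Copy of the bout with every coordinate mapped to ``scale*p + offset``.

        Confidences are untouched.  Used to probe scale/translation invariance
        of downstream features.
        """
        ox, oy = offset
        new_frames = []
        for frame in self.frames:
            tracks: Dict[str, Dict[str, Keypoint]] = {}
            for tid, kps in frame.person_tracks.items():
                tracks[tid] = {
                    name: Keypoint(scale * kp.x + ox, scale * kp.y + oy, kp.confidence)
                    for name, kp in kps.items()
                }
            new_frames.append(PoseFrame(frame.frame_index, frame.time_s, tracks))
        return replace(self, frames=new_frames, exclusion_flags=set(self.exclusion_flags))


def _parse_triple(label: str, value: object, where: str) -> Keypoint:
    if (
        not isinstance(value, (list, tuple))
        or len(value) != 3
        or not all(isinstance(v, (int, float)) for v in value)
    ):
        raise PoseFormatError(f"{where}: keypoint {label!r} is not an [x, y, confidence] triple")
    x, y, c = (float(v) for v in value)
    if not (0.0 <= c <= 1.0) or math.isnan(c):
        raise PoseFormatError(f"{where}: keypoint {label!r} confidence {c} outside [0, 1]")
    return Keypoint(x, y, c)


def _parse_frame(obj: Mapping, index: int, fps: float, schema: KeypointSchema, where: str) -> PoseFrame:
    if not isinstance(obj, Mapping) or "people" not in obj:
        raise PoseFormatError(f"{where}, frame {index}: expected an object with a 'people' map")
    frame_index = int(obj.get("frame_index", index))
    tracks: Dict[str, Dict[str, Keypoint]] = {}
    for tid, kp_map in obj["people"].items():
        if not isinstance(kp_map, Mapping):
            raise PoseFormatError(f"{where}, frame {index}: track {tid!r} is not a keypoint map")
        kps: Dict[str, Keypoint] = {}
        for label, triple in kp_map.items():
            if label not in schema:
                logger.warning("%s, frame %d: dropping unknown keypoint %r", where, index, label)
                continue
            kps[label] = _parse_triple(label, triple, f"{where}, frame {index}")
        for label in schema.names:
            kps.setdefault(label, MISSING_KEYPOINT)
        tracks[str(tid)] = kps
    return PoseFrame(frame_index, frame_index / fps, tracks)


def read_pose_json(
    path: str | Path,
    schema: KeypointSchema = DEFAULT_SCHEMA,
    fps: Optional[float] = None,
) -> Tuple[List[PoseFrame], dict]:
    """Read a pose file (bout object or bare frame array) into PoseFrames.

    Returns ``(frames, metadata)`` where metadata carries any bout-level keys
    present in the file (``bout_id``, ``participant_id``, ``recorded_at``,
    ``fps``).  ``fps`` must come from the file or the argument.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PoseFormatError(f"{path}: malformed JSON ({exc})") from exc

    meta: dict = {}
    if isinstance(payload, Mapping):
        frame_objs = payload.get("frames")
        if frame_objs is None:
            raise PoseFormatError(f"{path}: bout object has no 'frames' array")
        for key in ("bout_id", "participant_id", "recorded_at", "fps"):
            if key in payload:
                meta[key] = payload[key]
    elif isinstance(payload, list):
        frame_objs = payload
    else:
        raise PoseFormatError(f"{path}: top level must be a bout object or a frame array")

    effective_fps = float(meta.get("fps", fps) or 0.0)
    if effective_fps <= 0:
        raise ValueError(f"{path}: fps absent from file and not supplied")
    meta["fps"] = effective_fps

    frames = [_parse_frame(obj, i, effective_fps, schema, str(path)) for i, obj in enumerate(frame_objs)]
    return frames, meta


def write_bout(bout: WalkingBout, path: str | Path) -> None:
    """Write a bout in the canonical JSON dialect (round-trips with read_bout)."""
    frames = []
    for frame in bout.frames:
        people = {
            tid: {name: [kp.x, kp.y, kp.confidence] for name, kp in kps.items() if not kp.is_missing}
            for tid, kps in frame.person_tracks.items()
        }
        frames.append({"frame_index": frame.frame_index, "people": people})
    payload = {
        "bout_id": bout.bout_id,
        "participant_id": bout.participant_id,
        "fps": bout.fps,
        "recorded_at": bout.recorded_at.isoformat() if bout.recorded_at else None,
        "schema": list(bout.schema.names),
        "frames": frames,
    }
    Path(path).write_text(json.dumps(payload))


def read_bout(path: str | Path, schema: KeypointSchema = DEFAULT_SCHEMA, fps: Optional[float] = None) -> WalkingBout:
    """Read a single-track bout file written by :func:`write_bout`."""
    frames, meta = read_pose_json(path, schema=schema, fps=fps)
    recorded_at = meta.get("recorded_at")
    if isinstance(recorded_at, str):
        recorded_at = datetime.fromisoformat(recorded_at)
    return select_participant_track(
        frames,
        fps=meta["fps"],
        policy="most_frames",
        bout_id=str(meta.get("bout_id", Path(path).stem)),
        participant_id=str(meta.get("participant_id", "unknown")),
        recorded_at=recorded_at,
        schema=schema,
    )


def _median_hip_span(frames: Sequence[PoseFrame], tid: str) -> float:
    spans = []
    for frame in frames:
        kps = frame.person_tracks.get(tid)
        if kps is None:
            continue
        lh, rh = kps.get("left_hip", MISSING_KEYPOINT), kps.get("right_hip", MISSING_KEYPOINT)
        if lh.is_missing or rh.is_missing:
            continue
        spans.append(math.hypot(lh.x - rh.x, lh.y - rh.y))
    return float(np.median(spans)) if spans else 0.0


def select_participant_track(
    frames: Sequence[PoseFrame],
    fps: float,
    policy: str = "largest_hip_span",
    explicit_id: Optional[str] = None,
    bout_id: str = "bout",
    participant_id: str = "unknown",
    recorded_at: Optional[datetime] = None,
    schema: KeypointSchema = DEFAULT_SCHEMA,
) -> WalkingBout:
    """Keep exactly one person track per bout, discarding all others.

    The study setting guarantees the participant is the person walking the
    hallway toward the camera, hence the foreground (largest) figure; the
    default policy keeps the track with the largest *median* pixel hip span.
    ``most_frames`` keeps the most persistent track; ``explicit_id`` trusts
    the caller.  Frames where the selected track is absent keep all-missing
    placeholders so frame indexing stays dense.
    """
    track_ids = sorted({tid for f in frames for tid in f.person_tracks})
    if not track_ids:
        raise EmptyBoutError(f"bout {bout_id!r}: no person tracks in any frame")

    if policy == "explicit_id":
        if explicit_id is None or explicit_id not in track_ids:
            raise ValueError(f"bout {bout_id!r}: explicit track id {explicit_id!r} not present")
        chosen = explicit_id
    elif policy == "most_frames":
        counts = {tid: sum(tid in f.person_tracks for f in frames) for tid in track_ids}
        chosen = max(track_ids, key=lambda t: (counts[t], t))
    elif policy == "largest_hip_span":
        spans = {tid: _median_hip_span(frames, tid) for tid in track_ids}
        chosen = max(track_ids, key=lambda t: (spans[t], t))
    else:
        raise ValueError(f"unknown track-selection policy {policy!r}")

    placeholder = {name: MISSING_KEYPOINT for name in schema.names}
    new_frames = []
    for frame in frames:
        kps = frame.person_tracks.get(chosen, placeholder)
        new_frames.append(PoseFrame(frame.frame_index, frame.frame_index / fps, {chosen: dict(kps)}))
    return WalkingBout(
        bout_id=bout_id,
        participant_id=participant_id,
        fps=fps,
        frames=new_frames,
        track_id=chosen,
        recorded_at=recorded_at,
        schema=schema,
    )


def qc_bout(bout: WalkingBout, n_strikes: int, min_strikes: int = 3) -> WalkingBout:
    """Flag a bout whose walk is too short to analyse (< ``min_strikes`` steps).

    Only flags are touched; keypoint data is never mutated.  Manual flags
    (handrail, turned_around, occluded) always exclude a bout regardless of
    step count.
    """
    if n_strikes < min_strikes:
        bout.exclusion_flags.add("too_few_steps")
    else:
        bout.exclusion_flags.discard("too_few_steps")
    return bout


# -- bout manifest -----------------------------------------------------------

MANIFEST_COLUMNS = ["bout_id", "participant_id", "recorded_at", "fps", "path", "flags"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a bout manifest CSV; ``flags`` is a semicolon-joined string."""
    df = pd.read_csv(path, dtype={"bout_id": str, "participant_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    df["flags"] = df["flags"].fillna("")
    df["recorded_at"] = pd.to_datetime(df["recorded_at"])
    return df


def write_manifest(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return df


def parse_flags(flags_str: str) -> Set[str]:
    return {f for f in str(flags_str).split(";") if f}
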