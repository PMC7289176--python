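"""PCKh keypoint-accuracy evaluation against manual annotations.

A predicted keypoint is *correct* when its Euclidean distance to the manual
annotation is at most ``alpha`` times the head-segment length of that image
(distance between the annotated ``head_top`` and ``neck``); ``alpha = 0.5``
gives the standard PCKh@0.5.  A confidence-cutoff sweep reports, per cutoff,
the PCKh of the surviving predictions and the fraction discarded — the
trade-off used to pick an imputation threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

#: prediction: (image_id, keypoint) -> (x, y, confidence)
Predictions = Dict[Tuple[str, str], Tuple[float, float, float]]


@dataclass
class AnnotationSet:
    """Manual keypoint annotations plus per-image head-segment lengths."""

    points: Dict[Tuple[str, str], Tuple[float, float]]
    head_lengths: Dict[str, float]

    def __post_init__(self) -> None:
        for image_id, h in self.head_lengths.items():
            if not h > 0:
                raise ValueError(f"image {image_id!r}: head segment length must be positive")

    @classmethod
    def from_points(cls, points: Dict[Tuple[str, str], Tuple[float, float]]) -> "AnnotationSet":
        """Derive head lengths from the annotated head_top/neck of each image."""
        heads: Dict[str, float] = {}
        images = {img for img, _ in points}
        for img in images:
            top, neck = points.get((img, "head_top")), points.get((img, "neck"))
            if top is None or neck is None:
                raise ValueError(f"image {img!r}: head_top/neck annotation required for PCKh")
            heads[img] = math.hypot(top[0] - neck[0], top[1] - neck[1])
        return cls(points=points, head_lengths=heads)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnnotationSet":
        df = pd.read_csv(path, dtype={"image_id": str, "keypoint": str})
        points = {
            (r.image_id, r.keypoint): (float(r.x), float(r.y)) for r in df.itertuples()
        }
        return cls.from_points(points)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"image_id": img, "keypoint": kp, "x": x, "y": y}
            for (img, kp), (x, y) in sorted(self.points.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class PckReport:
    """PCK outcome for one keypoint subset at one confidence cutoff."""

    pck: Optional[float]  # fraction correct in [0, 1]; None if nothing evaluated
    n_evaluated: int
    n_discarded: int  # predictions below the confidence cutoff
    n_skipped: int  # predictions without a matching annotation
    cutoff: float
    alpha: float
    subset: Optional[Tuple[str, ...]] = None

    @property
    def discarded_fraction(self) -> float:
        total = self.n_evaluated + self.n_discarded
        return self.n_discarded / total if total else 0.0


def pckh(
    predictions: Predictions,
    annotations: AnnotationSet,
    alpha: float = 0.5,
    subset: Optional[Iterable[str]] = None,
    cutoff: float = 0.0,
) -> PckReport:
    """Fraction of predictions within ``alpha`` x head length of annotation.

    ``subset`` restricts scoring to the given keypoint names (e.g. ankles
    only).  Predictions with confidence strictly below ``cutoff`` are
    discarded before scoring; ties at the distance threshold count correct.
    """
    subset_t = tuple(sorted(subset)) if subset is not None else None
    keep = set(subset_t) if subset_t is not None else None
    n_eval = n_correct = n_disc = n_skip = 0
    for (img, kp), (x, y, conf) in predictions.items():
        if keep is not None and kp not in keep:
            continue
        if conf < cutoff:
            n_disc += 1
            continue
        ann = annotations.points.get((img, kp))
        if ann is None or img not in annotations.head_lengths:
            n_skip += 1
            continue
        n_eval += 1
        if math.hypot(x - ann[0], y - ann[1]) <= alpha * annotations.head_lengths[img]:
            n_correct += 1
    pck = n_correct / n_eval if n_eval else None
    return PckReport(
        pck=pck,
        n_evaluated=n_eval,
        n_discarded=n_disc,
        n_skipped=n_skip,
        cutoff=cutoff,
        alpha=alpha,
        subset=subset_t,
    )


def confidence_sweep(
    predictions: Predictions,
    annotations: AnnotationSet,
    cutoffs: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    alpha: float = 0.5,
    subset: Optional[Iterable[str]] = None,
) -> List[PckReport]:
    """PCKh after discarding predictions below each confidence cutoff."""
    return [pckh(predictions, annotations, alpha=alpha, subset=subset, cutoff=c) for c in cutoffs]


def sweep_table(
    predictions: Predictions,
    annotations: AnnotationSet,
    cutoffs: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    subsets: Optional[Dict[str, Optional[Iterable[str]]]] = None,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Cutoff-sweep table: rows = cutoffs, columns = PCKh per subset and the
    discarded fraction (the layout used to choose the confidence threshold)."""
    if subsets is None:
        subsets = {"all": None, "ankles": ("left_ankle", "right_ankle"), "hips": ("left_hip", "right_hip")}
    rows = []
    for c in cutoffs:
        row: dict = {"cutoff": c}
        for label, sub in subsets.items():
            rep = pckh(predictions, annotations, alpha=alpha, subset=sub, cutoff=c)
            row[f"pckh_{label}"] = rep.pck
            if label == "all":
                row["discarded_fraction"] = rep.discarded_fraction
        rows.append(row)
    return pd.DataFrame(rows)
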