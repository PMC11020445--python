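"""Radiographic segmental height and the binary cage-subsidence call.

Segmental height spans the fused level: the Euclidean distance between the
midpoint of the superior endplate of the upper vertebral body and the
midpoint of the inferior endplate of the lower vertebral body, on a
calibrated lateral radiograph (mm coordinates).  Subsidence is a loss of
segmental height strictly exceeding 2 mm between the week-1 postoperative
film and the final follow-up, or reader-adjudicated migration of the
interbody cage into either endplate, regardless of the height change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RadiographLandmarks",
    "SubsidenceRecord",
    "segmental_height",
    "classify",
    "classify_cohort",
]

TIMEPOINTS = ("postop_week1", "final_followup")
DEFAULT_THRESHOLD_MM = 2.0


@dataclass(frozen=True)
class RadiographLandmarks:
    """The two endplate midpoints defining segmental height at one timepoint."""

    timepoint: str
    sup_midpoint_mm: tuple
    inf_midpoint_mm: tuple

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        sup = tuple(float(v) for v in self.sup_midpoint_mm)
        inf = tuple(float(v) for v in self.inf_midpoint_mm)
        if len(sup) != 2 or len(inf) != 2:
            raise ValueError("landmarks must be 2-D points in mm")
        if sup == inf:
            raise ValueError("superior and inferior midpoints coincide")
        object.__setattr__(self, "sup_midpoint_mm", sup)
        object.__setattr__(self, "inf_midpoint_mm", inf)


@dataclass(frozen=True)
class SubsidenceRecord:
    """Pre/post heights, height loss, migration flag and the binary call.

    ``loss_mm`` may be negative (apparent height gain under measurement
    noise); it is retained unclamped so it flows into means and CIs, and in
    that case the record is subsided iff migration was adjudicated.
    """

    h_postop_mm: float
    h_final_mm: float
    loss_mm: float
    migration: bool
    subsided: bool
    threshold_mm: float = DEFAULT_THRESHOLD_MM
    patient_id: Optional[str] = None
    level: Optional[str] = None


def segmental_height(lm: RadiographLandmarks) -> float:
    """Euclidean distance between the two endplate midpoints, in mm."""
    dx = lm.sup_midpoint_mm[0] - lm.inf_midpoint_mm[0]
    dy = lm.sup_midpoint_mm[1] - lm.inf_midpoint_mm[1]
    return float(np.hypot(dx, dy))


def classify(
    h_postop_mm: float,
    h_final_mm: float,
    migration: bool = False,
    threshold_mm: float = DEFAULT_THRESHOLD_MM,
    patient_id: Optional[str] = None,
    level: Optional[str] = None,
) -> SubsidenceRecord:
    """Apply the subsidence rule: loss strictly > threshold, OR migration.

    The inequality is strict ("exceeding 2 mm"): a loss of exactly the
    threshold without migration is not subsidence.
    """
    if h_postop_mm <= 0 or h_final_mm <= 0:
        raise ValueError("segmental heights must be positive")
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    loss = h_postop_mm - h_final_mm
    subsided = bool(loss > threshold_mm or migration)
    return SubsidenceRecord(
        h_postop_mm=float(h_postop_mm),
        h_final_mm=float(h_final_mm),
        loss_mm=float(loss),
        migration=bool(migration),
        subsided=subsided,
        threshold_mm=float(threshold_mm),
        patient_id=patient_id,
        level=level,
    )


def classify_cohort(
    cohort: pd.DataFrame, threshold_mm: float = DEFAULT_THRESHOLD_MM
) -> pd.DataFrame:
    """Apply the subsidence rule row-wise to a cohort table.

    Uses ``preop_height_mm`` as the baseline (week-1 postoperative) height
    and ``final_height_mm`` at follow-up; returns a copy with ``loss_mm``
    and ``subsided_call`` columns appended.
    """
    required = {"preop_height_mm", "final_height_mm", "migration"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    out = cohort.copy()
    loss = out["preop_height_mm"] - out["final_height_mm"]
    out["loss_mm"] = loss
    out["subsided_call"] = ((loss > threshold_mm) | out["migration"].astype(bool)).astype(int)
    return out
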