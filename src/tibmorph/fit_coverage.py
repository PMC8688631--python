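"""Bone–component fit scoring.

A knee is a point (ML, AP) in millimetres; a component table is a per-gender
list of (AP, ML) sizes.  Fit is point-based: the knee is assigned to the
nearest size by Euclidean distance in the (ML, AP) plane, the signed per-axis
mismatches are classified with the 2 mm / 5 mm overhang–underhang thresholds,
and population coverage counts knees within the 2.5 mm circle criterion.
Boundary values fall in the less-severe class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FitCriteria",
    "FitDelta",
    "classify_dimension",
    "assign_size",
    "coverage_percent",
    "aspect_ratio_curve",
    "fit_report",
]

#: mismatch classes from most overhanging to most underhanging
CLASSES = (
    "absolute_overhang",
    "relative_overhang",
    "acceptable",
    "relative_underhang",
    "absolute_underhang",
)


@dataclass(frozen=True)
class FitCriteria:
    """Coverage circle radius and the overhang/underhang thresholds (mm)."""

    circle_radius_mm: float = 2.5
    overhang_threshold_mm: float = 2.0
    underhang_absolute_mm: float = 5.0

    def __post_init__(self) -> None:
        if min(self.circle_radius_mm, self.overhang_threshold_mm,
               self.underhang_absolute_mm) <= 0:
            raise ValueError("all fit criteria must be positive")
        if self.underhang_absolute_mm <= self.overhang_threshold_mm:
            raise ValueError("absolute-underhang bound must exceed the "
                             "overhang threshold")


@dataclass
class FitDelta:
    """Component-minus-bone mismatch for one knee against one size."""

    d_ml: float
    d_ap: float
    euclidean: float
    ml_class: str
    ap_class: str


def classify_dimension(delta_mm: float, criteria: FitCriteria = FitCriteria()) -> str:
    """Classify a signed component-minus-bone mismatch on one axis.

    Positive deltas are overhang (component past the bone edge), negative
    underhang; deltas in [-2, 0] mm are acceptable.
    """
    if not np.isfinite(delta_mm):
        raise ValueError("delta must be finite")
    t, u = criteria.overhang_threshold_mm, criteria.underhang_absolute_mm
    if delta_mm > t:
        return "absolute_overhang"
    if delta_mm > 0:
        return "relative_overhang"
    if delta_mm >= -t:
        return "acceptable"
    if delta_mm >= -u:
        return "relative_underhang"
    return "absolute_underhang"


def _gender_sizes(table: pd.DataFrame, gender: str) -> pd.DataFrame:
    rows = table[table["gender"] == gender]
    if len(rows) == 0:
        raise ValueError(f"component table has no rows for gender '{gender}'")
    return rows


def assign_size(
    bone: tuple[float, float],
    table: pd.DataFrame,
    gender: str,
    criteria: FitCriteria = FitCriteria(),
) -> tuple[int, FitDelta]:
    """Nearest component size for a (ml, ap) bone point.

    Distance is Euclidean in (ML, AP) mm; ties go to the smaller size index.
    """
    ml, ap = float(bone[0]), float(bone[1])
    rows = _gender_sizes(table, gender).sort_values("size", kind="stable")
    d_ml = rows["ml_mm"].to_numpy() - ml
    d_ap = rows["ap_mm"].to_numpy() - ap
    dist = np.hypot(d_ml, d_ap)
    i = int(np.flatnonzero(dist <= dist.min() + 1e-12)[0])
    delta = FitDelta(
        d_ml=float(d_ml[i]),
        d_ap=float(d_ap[i]),
        euclidean=float(dist[i]),
        ml_class=classify_dimension(float(d_ml[i]), criteria),
        ap_class=classify_dimension(float(d_ap[i]), criteria),
    )
    return int(rows["size"].iloc[i]), delta


def coverage_percent(
    bones,
    table: pd.DataFrame,
    gender: str,
    criteria: FitCriteria = FitCriteria(),
) -> float:
    """Percent of knees whose nearest-size distance is within the circle."""
    pts = np.asarray(bones, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("bones must be a nonempty (n, 2) array of (ml, ap)")
    rows = _gender_sizes(table, gender)
    centers = rows[["ml_mm", "ap_mm"]].to_numpy()
    d = np.sqrt(
        ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    return float(100.0 * np.mean(d <= criteria.circle_radius_mm))


def aspect_ratio_curve(table: pd.DataFrame) -> pd.DataFrame:
    """(AP, AR) rows sorted by AP; AR = ML/AP per row.

    Accepts either a SizeTable (``ap_mm``/``ml_mm``) or a record table
    (``ap``/``ml``).
    """
    if "ap_mm" in table.columns:
        ap, ml = table["ap_mm"].to_numpy(), table["ml_mm"].to_numpy()
    else:
        ap, ml = table["ap"].to_numpy(), table["ml"].to_numpy()
    if np.any(ap <= 0) or np.any(ml <= 0):
        raise ValueError("AP and ML must be positive")
    out = pd.DataFrame({"ap": ap, "ar": ml / ap}).sort_values(
        "ap", kind="stable", ignore_index=True
    )
    return out


def fit_report(
    records: pd.DataFrame,
    table: pd.DataFrame,
    criteria: FitCriteria = FitCriteria(),
) -> pd.DataFrame:
    """Per-knee fit report against a component table.

    Columns: subject_id, gender, size, d_ml, d_ap, euclidean, ml_class,
    ap_class, covered.
    """
    rows = []
    for _, rec in records.iterrows():
        size, delta = assign_size(
            (rec["ml"], rec["ap"]), table, rec["gender"], criteria
        )
        rows.append(
            dict(
                subject_id=rec.get("subject_id"),
                gender=rec["gender"],
                size=size,
                d_ml=delta.d_ml,
                d_ap=delta.d_ap,
                euclidean=delta.euclidean,
                ml_class=delta.ml_class,
                ap_class=delta.ap_class,
                covered=delta.euclidean <= criteria.circle_radius_mm,
            )
        )
    return pd.DataFrame(rows)
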