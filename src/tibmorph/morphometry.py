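"""The nine morphometric parameters of the resected proximal tibial surface.

All measurements act on a :class:`~tibmorph.mesh_resection.PlanarContour` in
the canonical frame (+x medial→lateral, +y posterior→anterior):

========  ==========================================================
ML        longest mediolateral extent of the cut surface
AP        vertical chord length at the ML midpoint
MAP/LAP   anteroposterior width of the medial / lateral condyle,
          measured on the vertical line through the posterior-most
          point of that half-contour
CM/CL     distance of the MAP / LAP line from the AP line
MAR/LAR   radius of the least-squares circle fitted to the anterior
          contour arc of the outer medial / lateral quarter
AR        ML / AP (dimensionless)
========  ==========================================================

A note on MAP/LAP: the defining line "passes through the extreme posterior
point ... of the condyle".  The width is therefore taken as the full vertical
chord at the posterior extreme of the half-contour.  A max-chord rule would
be inconsistent with real tibiae, where the chord at the ML midpoint (= AP)
exceeds the lateral condylar width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AmbiguousSectionError,
    DegenerateContourError,
    InsufficientArcError,
    NoCircleError,
)
from .mesh_resection import PlanarContour

__all__ = [
    "MorphometricRecord",
    "CircleFit",
    "PARAMETER_NAMES",
    "chord_at",
    "measure_ml",
    "measure_ap",
    "measure_condyle",
    "measure_cm_cl",
    "fit_circle",
    "measure_anterior_radius",
    "measure_all",
]

#: the nine parameters in canonical order
PARAMETER_NAMES = ("ml", "ap", "map", "lap", "cm", "cl", "mar", "lar", "ar")

#: crossings closer than this are merged before counting intersections (mm)
TANGENCY_TOL = 1e-6


@dataclass
class MorphometricRecord:
    """The nine measured parameters for one tibia (lengths in mm)."""

    ml: float
    ap: float
    map: float
    lap: float
    cm: float
    cl: float
    mar: float
    lar: float
    ar: float
    subject_id: str | None = None
    gender: str | None = None
    side: str | None = None

    def __post_init__(self) -> None:
        for name in ("ml", "ap", "map", "lap", "mar", "lar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cm < 0 or self.cl < 0:
            raise ValueError("cm and cl must be non-negative")
        if self.cm >= self.ml / 2 or self.cl >= self.ml / 2:
            raise ValueError("condylar offsets must be less than ML/2")
        if abs(self.ar - self.ml / self.ap) > 1e-9 * self.ar:
            raise ValueError("ar must equal ml/ap")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAMETER_NAMES}


@dataclass
class CircleFit:
    """Least-squares circle: Kåsa algebraic seed + Gauss–Newton refinement."""

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise NoCircleError("fitted radius must be positive")
        if self.n_points < 3:
            raise NoCircleError("circle fit needs at least 3 points")


def chord_at(contour: PlanarContour, x: float) -> np.ndarray:
    """Sorted y-coordinates where the vertical line at ``x`` meets the contour.

    Crossings closer than :data:`TANGENCY_TOL` are merged (tangency handling);
    a vertical edge lying exactly on the line contributes both endpoints.
    """
    pts = contour.points
    a = pts
    b = np.roll(pts, -1, axis=0)
    ys: list[float] = []
    dx = b[:, 0] - a[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x - a[:, 0]) / dx
    spans = ((a[:, 0] - x) * (b[:, 0] - x)) <= 0
    for i in np.flatnonzero(spans):
        if abs(dx[i]) < 1e-15:
            if abs(a[i, 0] - x) < TANGENCY_TOL:
                ys.extend([a[i, 1], b[i, 1]])
            continue
        ti = min(max(t[i], 0.0), 1.0)
        ys.append(a[i, 1] + ti * (b[i, 1] - a[i, 1]))
    if not ys:
        return np.empty(0)
    ys_arr = np.sort(np.asarray(ys))
    merged = [ys_arr[0]]
    for y in ys_arr[1:]:
        if y - merged[-1] > TANGENCY_TOL:
            merged.append(y)
    return np.asarray(merged)


def measure_ml(contour: PlanarContour) -> tuple[float, float, float]:
    """Longest mediolateral extent: (ml, x_min, x_max)."""
    x = contour.points[:, 0]
    x_min, x_max = float(x.min()), float(x.max())
    return x_max - x_min, x_min, x_max


def measure_ap(contour: PlanarContour) -> tuple[float, float]:
    """AP width: vertical chord length at the ML midpoint; returns (ap, x_mid)."""
    _, x_min, x_max = measure_ml(contour)
    x_mid = 0.5 * (x_min + x_max)
    ys = chord_at(contour, x_mid)
    if len(ys) != 2:
        raise AmbiguousSectionError(
            f"AP line at x={x_mid:.3f} crosses the contour {len(ys)} times"
        )
    return float(ys[1] - ys[0]), x_mid


def measure_condyle(
    contour: PlanarContour, side: str, x_mid: float
) -> tuple[float, float]:
    """Condylar AP width and the x position of its line.

    The line runs through the posterior-most vertex of the half-contour on
    the requested side of the AP line; the width is the full vertical chord
    (anterior minus posterior crossing) at that x.
    Returns ``(width, x_line)``.
    """
    pts = contour.points
    if side == "medial":
        mask = pts[:, 0] <= x_mid
    elif side == "lateral":
        mask = pts[:, 0] >= x_mid
    else:
        raise ValueError("side must be 'medial' or 'lateral'")
    if not np.any(mask):
        raise DegenerateContourError(f"no contour points on the {side} half")
    half = pts[mask]
    x_line = float(half[np.argmin(half[:, 1]), 0])
    ys = chord_at(contour, x_line)
    if len(ys) < 2:
        raise DegenerateContourError(
            f"{side} condylar line at x={x_line:.3f} has no chord"
        )
    return float(ys[-1] - ys[0]), x_line


def measure_cm_cl(
    x_mid: float, x_line_medial: float, x_line_lateral: float
) -> tuple[float, float]:
    """Distances of the condylar AP lines from the central AP line."""
    return abs(x_line_medial - x_mid), abs(x_line_lateral - x_mid)


def fit_circle(points: np.ndarray, max_iter: int = 50, tol: float = 1e-10) -> CircleFit:
    """Least-squares best-fit circle.

    Algebraic (Kåsa) seed minimizing ``sum (x^2+y^2+Dx+Ey+F)^2``, then at most
    ``max_iter`` Gauss–Newton steps on the geometric residual ``dist - r``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise NoCircleError("circle fit needs >= 3 planar points")
    # collinearity: rank of centered coordinates
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise NoCircleError("points are collinear; no circle fits")
    A = np.column_stack([pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        raise NoCircleError("degenerate algebraic circle fit")
    r = float(np.sqrt(r2))
    p = np.array([cx, cy, r])
    for _ in range(max_iter):
        d = np.linalg.norm(pts - p[:2], axis=1)
        if np.any(d < 1e-12):
            break
        res = d - p[2]
        J = np.column_stack(
            [-(pts[:, 0] - p[0]) / d, -(pts[:, 1] - p[1]) / d, -np.ones(len(pts))]
        )
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        p = p + step
        if np.linalg.norm(step) < tol:
            break
    d = np.linalg.norm(pts - p[:2], axis=1)
    rms = float(np.sqrt(np.mean((d - p[2]) ** 2)))
    return CircleFit(center=p[:2], radius=float(p[2]), rms_residual=rms,
                     n_points=len(pts))


def measure_anterior_radius(
    contour: PlanarContour,
    side: str,
    ml: float,
    x_mid: float,
    condyle_width: float,
    x_line: float,
) -> float:
    """Anterior radius (MAR or LAR) on one side.

    Contour points in the outer quarter of the given side that lie anterior of
    the condylar chord's vertical midpoint are fitted with a least-squares
    circle; its radius is returned.
    """
    pts = contour.points
    x_min = x_mid - ml / 2.0
    x_max = x_mid + ml / 2.0
    if side == "medial":
        in_quarter = pts[:, 0] <= x_min + ml / 4.0
    elif side == "lateral":
        in_quarter = pts[:, 0] >= x_max - ml / 4.0
    else:
        raise ValueError("side must be 'medial' or 'lateral'")
    ys = chord_at(contour, x_line)
    if len(ys) < 2:
        raise DegenerateContourError(f"no chord at condylar line x={x_line:.3f}")
    y_mid = 0.5 * (ys[0] + ys[-1])
    sel = pts[in_quarter & (pts[:, 1] > y_mid)]
    if len(sel) < 3:
        raise InsufficientArcError(
            f"only {len(sel)} points selected for the {side} anterior arc"
        )
    return fit_circle(sel).radius


def measure_all(
    contour: PlanarContour,
    subject_id: str | None = None,
    gender: str | None = None,
    side: str | None = None,
) -> MorphometricRecord:
    """Measure all nine parameters on a canonical-frame closed contour."""
    ml, _, _ = measure_ml(contour)
    ap, x_mid = measure_ap(contour)
    map_, x_med = measure_condyle(contour, "medial", x_mid)
    lap, x_lat = measure_condyle(contour, "lateral", x_mid)
    cm, cl = measure_cm_cl(x_mid, x_med, x_lat)
    mar = measure_anterior_radius(contour, "medial", ml, x_mid, map_, x_med)
    lar = measure_anterior_radius(contour, "lateral", ml, x_mid, lap, x_lat)
    return MorphometricRecord(
        ml=ml, ap=ap, map=map_, lap=lap, cm=cm, cl=cl, mar=mar, lar=lar,
        ar=ml / ap, subject_id=subject_id, gender=gender, side=side,
    )
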