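"""Synthetic tibial resection contours and gender-stratified populations.

A :class:`ParameterVector` prescribes the eight directly measured parameters;
:func:`make_contour` realizes it as a simple closed contour on which
:func:`~tibmorph.morphometry.measure_all` recovers every parameter to well
within 1%.  The contour is built from an anterior (top) and posterior
(bottom) boundary over the mediolateral span:

* the anterior boundary over each outer mediolateral quarter is an exact
  circular arc of the prescribed anterior radius (MAR / LAR), whose westmost
  (eastmost) pole forms the medial (lateral) tip of the contour, so the arc
  also rounds the tip;
* the posterior boundary has its per-half minima exactly at x = −CM and
  x = +CL (condylar posterior extremes) with vertical chords MAP and LAP
  there, and a small posterior notch bump at the midline emulating the
  intercondylar fossa;
* the remaining boundary is shape-preserving monotone (PCHIP) interpolation,
  so no segment overshoots its control values.

Populations are drawn per gender from a multivariate normal with the
published per-gender means/SDs and a within-gender correlation matrix
calibrated from the published *pooled* correlations (a pooled r is inflated
by the gender mean gap; sampling each gender with the pooled r would
overshoot it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from shapely import constrained_delaunay_triangles
from shapely.geometry import Polygon

from . import reference
from .errors import GeneratorInfeasibleError, GeometryError, SpecInfeasibleError
from .mesh_resection import PlanarContour, TriangleMesh
from .morphometry import measure_all

__all__ = [
    "ParameterVector",
    "PopulationSpec",
    "make_contour",
    "calibrate_within_correlation",
    "within_correlation_matrix",
    "nearest_correlation_matrix",
    "sample_population",
    "extrude_contour",
    "default_population_spec",
]

GENERATOR_PARAMS = ("ml", "ap", "map", "lap", "cm", "cl", "mar", "lar")

# contour shape constants (mm): depth of the midline posterior notch, drop of
# the anterior boundary from the condylar peak to the quarter line, and how
# far below the condylar mid-height the tip arc is extended so that every
# near-tip point lies on the fitted circle.
NOTCH_MM = 3.0
TOP_DROP_MM = 2.0
ARC_DIP_MM = 1.0
#: feasibility margin (mm) for the geometric constraints below
MARGIN_MM = 0.5


@dataclass(frozen=True)
class ParameterVector:
    """Ground-truth generator parameters (mm); AR is derived as ML/AP."""

    ml: float
    ap: float
    map: float
    lap: float
    cm: float
    cl: float
    mar: float
    lar: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in GENERATOR_PARAMS])

    @classmethod
    def from_array(cls, values) -> "ParameterVector":
        return cls(**dict(zip(GENERATOR_PARAMS, map(float, values))))

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in GENERATOR_PARAMS}


def feasibility_violation(p: ParameterVector) -> str | None:
    """Reason the generator cannot realize ``p``, or None if it can.

    Beyond positivity and the basic shape invariants (condylar widths larger
    than half of AP, condylar offsets inside the central half), the tip arcs
    must span their quarter (radius > ML/4) without lifting the tip above the
    condylar mid-height.
    """
    arr = p.as_array()
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        return "parameters must be positive and finite"
    quarter = p.ml / 4.0
    if p.map <= p.ap / 2 or p.lap <= p.ap / 2:
        return "condylar widths must exceed AP/2"
    if not (MARGIN_MM < p.cm < quarter - MARGIN_MM):
        return "cm must lie strictly inside the medial quarter span"
    if not (MARGIN_MM < p.cl < quarter - MARGIN_MM):
        return "cl must lie strictly inside the lateral quarter span"
    if p.mar < quarter + MARGIN_MM or p.lar < quarter + MARGIN_MM:
        return "anterior radii must exceed ML/4 so the arc spans the quarter"
    h_m = np.sqrt(p.mar**2 - (p.mar - quarter) ** 2)
    h_l = np.sqrt(p.lar**2 - (p.lar - quarter) ** 2)
    tip_m = p.map - TOP_DROP_MM - h_m
    tip_l = p.lap - TOP_DROP_MM - h_l
    if tip_m < MARGIN_MM or tip_l < MARGIN_MM:
        return "tip would fall below the posterior baseline"
    top_min = min(p.map, p.lap) - TOP_DROP_MM
    bottom_max = max(tip_m, tip_l, NOTCH_MM,
                     p.map / 2 - ARC_DIP_MM, p.lap / 2 - ARC_DIP_MM)
    if top_min <= bottom_max + MARGIN_MM:
        return "anterior and posterior boundaries would cross"
    return None


def _arc_points(xc, yc, r, theta0, theta1, n) -> np.ndarray:
    th = np.linspace(theta0, theta1, max(int(n), 2))
    return np.column_stack([xc + r * np.cos(th), yc + r * np.sin(th)])


def make_contour(params: ParameterVector, n_points: int = 720) -> PlanarContour:
    """Realize a parameter vector as a simple closed counterclockwise contour."""
    reason = feasibility_violation(params)
    if reason is not None:
        raise GeneratorInfeasibleError(reason)
    if n_points < 64:
        raise GeneratorInfeasibleError("n_points must be at least 64")
    p = params
    quarter = p.ml / 4.0
    x_tip_m, x_tip_l = -p.ml / 2.0, p.ml / 2.0
    xq_m, xq_l = -quarter, quarter

    # medial tip circle: west pole at the tip
    xc_m = x_tip_m + p.mar
    h_m = float(np.sqrt(p.mar**2 - (p.mar - quarter) ** 2))
    tip_m = p.map - TOP_DROP_MM - h_m  # y of the medial tip (= circle center y)
    # lateral tip circle: east pole at the tip
    xc_l = x_tip_l - p.lar
    h_l = float(np.sqrt(p.lar**2 - (p.lar - quarter) ** 2))
    tip_l = p.lap - TOP_DROP_MM - h_l

    # anterior (top) boundary knots over the central half
    top_x = np.array([xq_m, -p.cm, 0.0, p.cl, xq_l])
    top_y = np.array(
        [p.map - TOP_DROP_MM, p.map, NOTCH_MM + p.ap, p.lap, p.lap - TOP_DROP_MM]
    )
    top_mid = PchipInterpolator(top_x, top_y)

    # posterior (bottom) boundary: optional on-circle dips at the tips keep
    # every point that could enter the anterior-arc selection on the circle
    y_dip_m = min(tip_m, p.map / 2.0 - ARC_DIP_MM)
    y_dip_l = min(tip_l, p.lap / 2.0 - ARC_DIP_MM)
    phi_m = float(np.arcsin(max(tip_m - y_dip_m, 0.0) / p.mar))
    phi_l = float(np.arcsin(max(tip_l - y_dip_l, 0.0) / p.lar))
    x_dip_m = xc_m - p.mar * np.cos(phi_m)
    x_dip_l = xc_l + p.lar * np.cos(phi_l)
    bot_x = np.array([x_dip_m, -p.cm, 0.0, p.cl, x_dip_l])
    bot_y = np.array([tip_m - p.mar * np.sin(phi_m), 0.0, NOTCH_MM, 0.0,
                      tip_l - p.lar * np.sin(phi_l)])
    bot_mid = PchipInterpolator(bot_x, bot_y)

    # angle spans of the four circle pieces
    th_qm = float(np.arccos((xq_m - xc_m) / p.mar))  # top medial arc end
    th_ql = float(np.arccos((xq_l - xc_l) / p.lar))  # top lateral arc end

    # distribute points by approximate length of the six pieces
    lengths = np.array(
        [
            p.mar * (np.pi - th_qm),          # top medial arc
            2.2 * quarter,                    # top middle (pchip)
            p.lar * th_ql,                    # top lateral arc
            p.mar * phi_m,                    # bottom medial dip arc
            float(bot_x[-1] - bot_x[0]) * 1.1,  # bottom middle
            p.lar * phi_l,                    # bottom lateral dip arc
        ]
    )
    counts = np.maximum((n_points * lengths / lengths.sum()).astype(int), 4)

    def pchip_xgrid(x0, x1, knots, n):
        grid = np.linspace(x0, x1, max(int(n), 4))
        inner = [k for k in knots if x0 < k < x1]
        return np.unique(np.concatenate([grid, np.asarray(inner)]))

    # --- bottom, medial tip -> lateral tip (interior above => CCW) ---
    pieces = []
    if phi_m > 0:
        pieces.append(
            _arc_points(xc_m, tip_m, p.mar, np.pi, np.pi + phi_m, counts[3])
        )
    else:
        pieces.append(np.array([[x_tip_m, tip_m]]))
    gx = pchip_xgrid(float(bot_x[0]), float(bot_x[-1]),
                     [-p.cm, 0.0, p.cl], counts[4])
    pieces.append(np.column_stack([gx, bot_mid(gx)]))
    if phi_l > 0:
        pieces.append(
            _arc_points(xc_l, tip_l, p.lar, -phi_l, 0.0, counts[5])
        )
    else:
        pieces.append(np.array([[x_tip_l, tip_l]]))
    # --- top, lateral tip -> medial tip ---
    pieces.append(_arc_points(xc_l, tip_l, p.lar, 0.0, th_ql, counts[2]))
    gx = pchip_xgrid(xq_m, xq_l, [-p.cm, 0.0, p.cl], counts[1])[::-1]
    pieces.append(np.column_stack([gx, top_mid(gx)]))
    pieces.append(_arc_points(xc_m, tip_m, p.mar, th_qm, np.pi, counts[0]))

    pts = np.vstack(pieces)
    # drop consecutive duplicates (piece endpoints coincide) and closing point
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    pts = pts[keep]
    if np.linalg.norm(pts[0] - pts[-1]) < 1e-9:
        pts = pts[:-1]
    contour = PlanarContour(points=pts, closed=True)
    if not contour.is_simple():
        raise GeneratorInfeasibleError(
            "interpolated boundary self-intersects for these parameters"
        )
    return contour


def calibrate_within_correlation(
    pooled_r: float,
    pooled_sd_a: float,
    pooled_sd_b: float,
    within_sd_a: float,
    within_sd_b: float,
    half_gap_a: float,
    half_gap_b: float,
) -> float:
    """Within-gender r that reproduces a pooled r over a two-gender mixture.

    For an equal-size two-group mixture the pooled covariance decomposes as
    ``cov_pooled = r_within * sd_wa * sd_wb + half_gap_a * half_gap_b`` (half
    gaps signed alike when one gender is larger on both parameters), so::

        r_within = (pooled_r*pooled_sd_a*pooled_sd_b - half_gap_a*half_gap_b)
                   / (within_sd_a * within_sd_b)

    clamped to [-0.99, 0.99].
    """
    if within_sd_a <= 0 or within_sd_b <= 0:
        raise ValueError("within-gender SDs must be positive")
    r = (pooled_r * pooled_sd_a * pooled_sd_b - half_gap_a * half_gap_b) / (
        within_sd_a * within_sd_b
    )
    return float(np.clip(r, -0.99, 0.99))


def nearest_correlation_matrix(corr: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal re-normalized
    to unit variance.
    """
    sym = 0.5 * (corr + corr.T)
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass
class PopulationSpec:
    """Sampling specification for a two-gender synthetic population."""

    means: dict[str, dict[str, float]]  # gender -> param -> mean (mm)
    sds: dict[str, dict[str, float]]  # gender -> param -> SD (mm)
    pooled_r: dict[frozenset[str], float] = field(
        default_factory=lambda: dict(reference.POOLED_CORRELATIONS)
    )
    default_pooled_r: float = reference.DEFAULT_POOLED_R
    n_per_gender: int = 240
    seed: int = 0
    side_noise_sd: float = 0.2  # mm, independent per side and parameter
    n_contour_points: int = 720

    def __post_init__(self) -> None:
        if self.n_per_gender < 2:
            raise ValueError("need at least 2 subjects per gender")
        for g in ("male", "female"):
            if g not in self.means or g not in self.sds:
                raise ValueError(f"means/sds must cover gender '{g}'")
            for k in GENERATOR_PARAMS:
                if self.sds[g][k] <= 0:
                    raise ValueError("SDs must be positive")
        for r in self.pooled_r.values():
            if not -1.0 < r < 1.0:
                raise ValueError("pooled correlations must be in (-1, 1)")


def default_population_spec(
    n_per_gender: int = 240, seed: int = 0, **overrides
) -> PopulationSpec:
    """PopulationSpec with the published Thai reference statistics."""
    means = {g: {k: v[0] for k, v in reference.GENDER_SUMMARY[g].items()}
             for g in ("male", "female")}
    sds = {g: {k: v[1] for k, v in reference.GENDER_SUMMARY[g].items()}
           for g in ("male", "female")}
    return PopulationSpec(
        means=means, sds=sds, n_per_gender=n_per_gender, seed=seed, **overrides
    )


def _pooled_moments(spec: PopulationSpec, param: str) -> tuple[float, float]:
    """(pooled SD, signed half gap) for the equal-mixture of both genders."""
    mu_m = spec.means["male"][param]
    mu_f = spec.means["female"][param]
    half_gap = 0.5 * (mu_m - mu_f)
    within_var = 0.5 * (spec.sds["male"][param] ** 2 + spec.sds["female"][param] ** 2)
    return float(np.sqrt(within_var + half_gap**2)), half_gap


def within_correlation_matrix(spec: PopulationSpec, gender: str) -> np.ndarray:
    """Within-gender correlation matrix calibrated from the pooled targets."""
    k = len(GENERATOR_PARAMS)
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = GENERATOR_PARAMS[i], GENERATOR_PARAMS[j]
            pooled_r = spec.pooled_r.get(frozenset({a, b}), spec.default_pooled_r)
            sd_pa, gap_a = _pooled_moments(spec, a)
            sd_pb, gap_b = _pooled_moments(spec, b)
            r = calibrate_within_correlation(
                pooled_r, sd_pa, sd_pb,
                spec.sds[gender][a], spec.sds[gender][b], gap_a, gap_b,
            )
            corr[i, j] = corr[j, i] = r
    return nearest_correlation_matrix(corr)


def _draw_vectors(
    rng: np.random.Generator, spec: PopulationSpec, gender: str, n: int
) -> list[ParameterVector]:
    """Rejection-sample n feasible parameter vectors for one gender."""
    mean = np.array([spec.means[gender][k] for k in GENERATOR_PARAMS])
    sd = np.array([spec.sds[gender][k] for k in GENERATOR_PARAMS])
    cov = within_correlation_matrix(spec, gender) * np.outer(sd, sd)
    chol = np.linalg.cholesky(cov)
    out: list[ParameterVector] = []
    consecutive_rejects = 0
    while len(out) < n:
        z = rng.standard_normal(len(GENERATOR_PARAMS))
        vec = ParameterVector.from_array(mean + chol @ z)
        if feasibility_violation(vec) is None:
            out.append(vec)
            consecutive_rejects = 0
        else:
            consecutive_rejects += 1
            if consecutive_rejects > 1000:
                raise SpecInfeasibleError(
                    "more than 1000 consecutive draws violate the "
                    "parameter-vector invariants"
                )
    return out


def sample_population(spec: PopulationSpec) -> pd.DataFrame:
    """Generate and *measure* a two-gender, two-side synthetic population.

    Each subject owns one feasible :class:`ParameterVector`; each side is a
    small independent perturbation of it (``side_noise_sd``), realized as a
    contour and measured with :func:`measure_all` — measured columns are never
    copied from the ground truth.  Deterministic under ``spec.seed``.

    Returns a tidy DataFrame with columns ``subject_id, gender, side``, the
    nine measured parameters, and ``true_*`` ground-truth columns.
    """
    rows: list[dict] = []
    for gidx, gender in enumerate(("male", "female")):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), gidx])
        )
        vectors = _draw_vectors(rng, spec, gender, spec.n_per_gender)
        for i, vec in enumerate(vectors):
            subject = f"{gender[0].upper()}{i + 1:03d}"
            for side in ("right", "left"):
                side_vec = vec
                if spec.side_noise_sd > 0:
                    for _ in range(100):
                        noise = rng.normal(
                            0.0, spec.side_noise_sd, len(GENERATOR_PARAMS)
                        )
                        cand = ParameterVector.from_array(vec.as_array() + noise)
                        if feasibility_violation(cand) is None:
                            side_vec = cand
                            break
                    else:
                        raise SpecInfeasibleError(
                            "side perturbation cannot stay feasible"
                        )
                contour = make_contour(side_vec, spec.n_contour_points)
                rec = measure_all(
                    contour, subject_id=subject, gender=gender, side=side
                )
                row = {"subject_id": subject, "gender": gender, "side": side}
                row.update(rec.as_dict())
                row.update(
                    {f"true_{k}": v for k, v in side_vec.as_dict().items()}
                )
                rows.append(row)
    return pd.DataFrame(rows)


def extrude_contour(contour: PlanarContour, height_mm: float) -> TriangleMesh:
    """Extrude a closed simple contour into a watertight prism mesh.

    Side walls are quads split into triangles; the caps are a constrained
    Delaunay triangulation of the profile polygon (no Steiner points), so a
    perpendicular cross-section of the prism equals the contour exactly.
    """
    if not contour.closed:
        raise GeometryError("can only extrude a closed contour")
    if height_mm <= 0:
        raise GeometryError("extrusion height must be positive")
    poly = Polygon(contour.points)
    if not poly.is_valid:
        raise GeometryError("contour must be a simple polygon")
    pts = contour.points
    n = len(pts)
    bottom = np.column_stack([pts, np.zeros(n)])
    top = np.column_stack([pts, np.full(n, float(height_mm))])
    vertices = np.vstack([bottom, top])

    faces: list[tuple[int, int, int]] = []
    for i in range(n):
        j = (i + 1) % n
        faces.append((i, j, n + j))
        faces.append((i, n + j, n + i))

    index_of = {
        (round(x, 9), round(y, 9)): i for i, (x, y) in enumerate(map(tuple, pts))
    }
    tris = constrained_delaunay_triangles(poly)
    for tri in tris.geoms:
        coords = list(tri.exterior.coords)[:3]
        try:
            idx = [index_of[(round(x, 9), round(y, 9))] for x, y in coords]
        except KeyError as exc:  # pragma: no cover - CDT added a point
            raise GeometryError("cap triangulation introduced new vertices") from exc
        faces.append((idx[0], idx[2], idx[1]))  # bottom cap, normal down
        faces.append((n + idx[0], n + idx[1], n + idx[2]))  # top cap
    return TriangleMesh(vertices=vertices, faces=np.asarray(faces, dtype=int))
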