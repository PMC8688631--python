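"""Resection geometry: mechanical axis, resection plane and mesh slicing.

The proximal tibia is cut, as in total knee arthroplasty planning, on a plane
6 mm below the lateral tibial plateau, perpendicular to the tibial mechanical
axis and tilted by a 7 degree posterior slope.  The cut is expressed as a 2D
:class:`PlanarContour` in a canonical anatomical frame:

* ``+x`` — medial to lateral (the sign is fixed with a user-supplied medial
  marker so left and right tibiae land in the same frame),
* ``+y`` — posterior to anterior.

STL parsing and the raw triangle/plane intersection are delegated to
``trimesh``; chaining the intersection segments into loops, choosing the
in-plane frame, and the contour contract live here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .errors import (
    DegenerateAxisError,
    EmptySliceError,
    GeometryError,
    OpenContourError,
    STLParseError,
)

__all__ = [
    "TriangleMesh",
    "MechanicalAxis",
    "ResectionPlane",
    "PlanarContour",
    "read_stl",
    "build_axis",
    "build_resection_plane",
    "slice_mesh",
    "find_lateral_plateau",
]

#: duplicate vertices closer than this are merged on load (mm)
VERTEX_MERGE_TOL = 1e-6
#: maximum endpoint gap when chaining slice segments into a loop (mm)
LOOP_GAP_TOL = 1e-3


@dataclass
class TriangleMesh:
    """A triangle surface mesh in millimetres."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (n, 3) array")
        if len(self.vertices) < 4:
            raise GeometryError("a triangle mesh needs at least 4 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError("mesh coordinates must be finite")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be an (m, 3) index array")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(
            self.vertices
        ):
            raise GeometryError("face indices out of range")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


@dataclass
class MechanicalAxis:
    """Tibial mechanical axis: proximal tibial center toward the ankle."""

    proximal_point: np.ndarray
    direction: np.ndarray  # unit, proximal -> distal

    def __post_init__(self) -> None:
        self.proximal_point = np.asarray(self.proximal_point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise GeometryError("axis direction must be a unit vector")


@dataclass
class ResectionPlane:
    """The tibial cut plane.

    ``normal`` points distally (it is the mechanical-axis direction rotated by
    the posterior slope about the mediolateral axis); ``ml_axis`` is the
    in-plane medial-to-lateral direction.
    """

    origin: np.ndarray
    normal: np.ndarray
    ml_axis: np.ndarray
    depth_mm: float = 6.0
    posterior_slope_deg: float = 7.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.ml_axis = np.asarray(self.ml_axis, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise GeometryError("plane normal must be a unit vector")
        if abs(np.linalg.norm(self.ml_axis) - 1.0) > 1e-9:
            raise GeometryError("ml_axis must be a unit vector")
        if abs(float(self.normal @ self.ml_axis)) > 1e-9:
            raise GeometryError("ml_axis must lie in the plane")


@dataclass
class PlanarContour:
    """An ordered closed loop of 2D points (mm) in the canonical frame."""

    points: np.ndarray  # (n, 2)
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise GeometryError("contour points must be an (n, 2) array")
        if len(self.points) < 3:
            raise GeometryError("a contour needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("contour coordinates must be finite")
        if self.perimeter() <= 0:
            raise GeometryError("contour perimeter must be positive")

    def perimeter(self) -> float:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def area(self) -> float:
        """Signed shoelace area (positive for counterclockwise loops)."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(
            0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    def is_simple(self) -> bool:
        return Polygon(self.points).is_valid


def read_stl(path: str | os.PathLike) -> TriangleMesh:
    """Read a binary or ASCII STL file and merge duplicate vertices.

    Binary files with a record count that disagrees with the file length are
    rejected with an :class:`STLParseError` naming the byte offset at which
    the file ends short (or runs long).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise STLParseError(f"no such file: {path}")
    with open(path, "rb") as fh:
        head = fh.read(512)
        size = os.fstat(fh.fileno()).st_size
    if size < 15:
        raise STLParseError(f"{path}: truncated at byte {size}, not an STL file")
    is_ascii = head.lstrip()[:5] == b"solid" and b"facet" in head
    if not is_ascii:
        if size < 84:
            raise STLParseError(
                f"{path}: binary STL truncated at byte {size} "
                "(header + record count need 84 bytes)"
            )
        n_facets = int(np.frombuffer(head[80:84], dtype="<u4")[0])
        expected = 84 + 50 * n_facets
        if size != expected:
            raise STLParseError(
                f"{path}: binary STL declares {n_facets} facets "
                f"({expected} bytes) but file ends at byte {size}"
            )
    try:
        mesh = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - trimesh internals
        raise STLParseError(f"{path}: unreadable STL ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise STLParseError(f"{path}: STL contains no facets")
    verts, faces = _merge_vertices(mesh.vertices.view(np.ndarray),
                                   mesh.faces.view(np.ndarray))
    return TriangleMesh(vertices=verts, faces=faces)


def _merge_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = VERTEX_MERGE_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` (grid snap) and drop degenerate faces."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    verts = vertices[first]
    faces = inverse[faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    return verts, faces[ok]


def build_axis(proximal_center, ankle_center) -> MechanicalAxis:
    """Mechanical axis through the proximal tibial center and the ankle center."""
    p = np.asarray(proximal_center, dtype=float)
    a = np.asarray(ankle_center, dtype=float)
    d = a - p
    n = np.linalg.norm(d)
    if n <= 1.0:  # landmarks within 1 mm are treated as coincident
        raise DegenerateAxisError(
            f"proximal and ankle centers are {n:.3f} mm apart; need > 1 mm"
        )
    return MechanicalAxis(proximal_point=p, direction=d / n)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return (
        v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)
    )


def build_resection_plane(
    axis: MechanicalAxis,
    lateral_plateau_point,
    ml_axis,
    depth_mm: float = 6.0,
    slope_deg: float = 7.0,
) -> ResectionPlane:
    """Resection plane ``depth_mm`` below the lateral plateau with a posterior slope.

    The plane normal is the (distally pointing) mechanical-axis direction
    rotated by ``slope_deg`` about the mediolateral axis; the rotation sense is
    chosen so that, in the anterior convention of :func:`slice_mesh`, the
    posterior edge of the plane drops distally.
    """
    ml = np.asarray(ml_axis, dtype=float)
    n_ml = np.linalg.norm(ml)
    if n_ml < 1e-12:
        raise GeometryError("ml_axis must be nonzero")
    ml = ml / n_ml
    d = axis.direction
    if np.linalg.norm(np.cross(ml, d)) < 1e-9:
        raise GeometryError("ml_axis is parallel to the mechanical axis")
    origin = np.asarray(lateral_plateau_point, dtype=float) + depth_mm * d
    normal = _rodrigues(d, ml, np.deg2rad(slope_deg))
    normal = normal / np.linalg.norm(normal)
    # re-orthogonalize the ml axis into the plane
    ml_in = ml - (ml @ normal) * normal
    ml_in = ml_in / np.linalg.norm(ml_in)
    return ResectionPlane(
        origin=origin,
        normal=normal,
        ml_axis=ml_in,
        depth_mm=float(depth_mm),
        posterior_slope_deg=float(slope_deg),
    )


def _anterior_axis(plane: ResectionPlane, axis_direction: np.ndarray | None) -> np.ndarray:
    """In-plane posterior->anterior unit vector.

    With a nonzero posterior slope the anterior direction is anatomically
    determined: the proximal direction (−axis) projects into the tilted plane
    pointing anteriorly.  At exactly zero slope this projection vanishes and
    the convention ``anterior = ml × normal`` is used instead.
    """
    if axis_direction is not None:
        proj = -axis_direction - (-axis_direction @ plane.normal) * plane.normal
        n = np.linalg.norm(proj)
        if n > 1e-8:
            return proj / n
    v = np.cross(plane.ml_axis, plane.normal)
    return v / np.linalg.norm(v)


def _chain_segments(segments: np.ndarray) -> list[np.ndarray]:
    """Chain (n, 2, 3) intersection segments into closed loops of 3D points."""
    ends = segments.reshape(-1, 3)
    tree = cKDTree(ends)
    pairs = tree.query_pairs(LOOP_GAP_TOL, output_type="ndarray")
    # union-find to cluster coincident endpoints
    parent = np.arange(len(ends))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
    labels = np.array([find(i) for i in range(len(ends))])
    _, node_of = np.unique(labels, return_inverse=True)
    n_nodes = node_of.max() + 1
    coords = np.zeros((n_nodes, 3))
    counts = np.zeros(n_nodes)
    np.add.at(coords, node_of, ends)
    np.add.at(counts, node_of, 1.0)
    coords /= counts[:, None]

    adj: dict[int, list[int]] = {}
    for k in range(len(segments)):
        a, b = int(node_of[2 * k]), int(node_of[2 * k + 1])
        if a == b:
            continue  # zero-length segment
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    loops: list[np.ndarray] = []
    visited_edges: set[tuple[int, int]] = set()
    for start in list(adj):
        if not adj.get(start):
            continue
        loop = [start]
        cur, prev = start, -1
        while True:
            nxt = None
            for cand in adj[cur]:
                edge = (min(cur, cand), max(cur, cand))
                if edge in visited_edges:
                    continue
                nxt = cand
                visited_edges.add(edge)
                break
            if nxt is None:
                break
            if nxt == start:
                loops.append(coords[np.array(loop)])
                break
            loop.append(nxt)
            prev, cur = cur, nxt
    return loops


def slice_mesh(
    mesh: TriangleMesh, plane: ResectionPlane, medial_marker,
    axis: MechanicalAxis | None = None,
) -> PlanarContour:
    """Slice the mesh with the resection plane and project the cut to 2D.

    The largest closed loop (by enclosed area) is kept; smaller loops — fibula
    remnants, noise shells — are discarded.  The +x sign is chosen so that the
    medial marker projects to negative x, and the loop is returned
    counterclockwise.
    """
    segments = trimesh.intersections.mesh_plane(
        mesh.as_trimesh(), plane.normal, plane.origin
    )
    if len(segments) == 0:
        raise EmptySliceError("resection plane does not intersect the mesh")
    loops = _chain_segments(np.asarray(segments))
    if not loops:
        raise OpenContourError(
            f"slice segments do not close within {LOOP_GAP_TOL} mm"
        )
    u = plane.ml_axis
    v = _anterior_axis(plane, axis.direction if axis is not None else None)
    m2 = np.asarray(medial_marker, dtype=float) - plane.origin
    if m2 @ u > 0:  # medial must land at negative x
        u = -u

    best = None
    best_area = -1.0
    for loop in loops:
        rel = loop - plane.origin
        pts2 = np.column_stack([rel @ u, rel @ v])
        area = abs(
            0.5
            * np.sum(
                pts2[:, 0] * np.roll(pts2[:, 1], -1)
                - np.roll(pts2[:, 0], -1) * pts2[:, 1]
            )
        )
        if area > best_area:
            best_area = area
            best = pts2
    if best is None or len(best) < 3:
        raise OpenContourError("no usable closed loop in slice")
    best = _drop_collinear(best)
    contour = PlanarContour(points=best, closed=True)
    if contour.area() < 0:
        contour = PlanarContour(points=best[::-1].copy(), closed=True)
    return contour


def _drop_collinear(pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Remove loop vertices interior to straight runs (wall-diagonal crossings)."""
    prev = np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0)
    a = pts - prev
    b = nxt - pts
    cross = np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    scale = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    keep = cross > tol * np.maximum(scale, 1e-12)
    return pts[keep] if keep.sum() >= 3 else pts


def find_lateral_plateau(
    mesh: TriangleMesh, axis: MechanicalAxis, medial_marker
) -> tuple[np.ndarray, np.ndarray]:
    """Locate the lateral plateau point and the medial->lateral direction.

    The mediolateral direction is the component of (proximal center → away
    from the medial marker) perpendicular to the axis; the lateral plateau
    point is the most proximal mesh vertex on the lateral half.
    """
    d = axis.direction
    m = np.asarray(medial_marker, dtype=float)
    w = axis.proximal_point - m
    w = w - (w @ d) * d
    n = np.linalg.norm(w)
    if n < 1e-9:
        raise GeometryError("medial marker lies on the mechanical axis")
    ml_dir = w / n  # medial -> lateral
    rel = mesh.vertices - axis.proximal_point
    lateral = rel @ ml_dir > 0
    if not np.any(lateral):
        raise GeometryError("no mesh vertices on the lateral side")
    proximality = -(rel @ d)  # large = proximal
    idx = np.flatnonzero(lateral)[np.argmax(proximality[lateral])]
    return mesh.vertices[idx].copy(), ml_dir
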