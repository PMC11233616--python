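"""Low-level geometric primitives for sac morphometry.

Every morphological parameter reduces to a handful of mesh operations
implemented here: capping the open sac along its neck, divergence-theorem
volume, triangle-sum area, convex hull quantities, the total-least-squares
neck plane, heights measured against that plane, parallel cross-sections and
axis projections.  All operations are pure functions over in-memory arrays.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from shapely.geometry import Polygon

from .datatypes import HullResult, NeckContour, PlaneFrame, SurfaceMesh
from .errors import GeometryError, InputError


# ---------------------------------------------------------------------------
# topology helpers

def boundary_loop(mesh: SurfaceMesh) -> np.ndarray:
    """Ordered vertex indices of the single open boundary loop.

    A boundary edge is a directed edge that appears in exactly one face; for
    a consistently wound open surface these edges chain into one cycle.
    """
    f = mesh.faces
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    undirected = np.sort(directed, axis=1)
    _, inverse, counts = np.unique(
        undirected, axis=0, return_inverse=True, return_counts=True
    )
    boundary = directed[counts[inverse] == 1]
    if len(boundary) == 0:
        raise GeometryError("mesh has no boundary loop (already closed)")
    succ = {int(a): int(b) for a, b in boundary}
    if len(succ) != len(boundary):
        raise GeometryError("boundary is not a single simple loop")
    start = int(boundary[0, 0])
    loop = [start]
    cur = succ[start]
    while cur != start:
        loop.append(cur)
        if len(loop) > len(boundary):
            raise GeometryError("boundary does not close into a single loop")
        cur = succ[cur]
    if len(loop) != len(boundary):
        raise GeometryError("mesh has more than one boundary loop")
    return np.asarray(loop, dtype=np.int64)


def is_watertight(mesh: SurfaceMesh) -> bool:
    """Every undirected edge in exactly two faces, with opposite directions."""
    f = mesh.faces
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    undirected = np.sort(directed, axis=1)
    _, counts = np.unique(undirected, axis=0, return_counts=True)
    if not np.all(counts == 2):
        return False
    # consistent orientation: no directed edge repeats
    _, dcounts = np.unique(directed, axis=0, return_counts=True)
    return bool(np.all(dcounts == 1))


def cap_neck(sac: SurfaceMesh, neck: NeckContour, tol: float = 1e-6) -> SurfaceMesh:
    """Close the open sac with a triangle fan from the neck-contour centroid.

    The sac's boundary loop must coincide with the neck points within ``tol``
    (mm).  Cap triangles traverse each boundary edge opposite to its sac
    direction, so the closed mesh stays consistently oriented.
    """
    loop = boundary_loop(sac)
    if len(loop) != len(neck.points):
        raise GeometryError(
            f"boundary loop has {len(loop)} vertices but neck contour has "
            f"{len(neck.points)} points"
        )
    tree = cKDTree(neck.points)
    dist, _ = tree.query(sac.vertices[loop])
    if dist.max() > tol:
        raise GeometryError(
            f"boundary/contour mismatch: max deviation {dist.max():.3g} mm > {tol} mm"
        )
    centroid = sac.vertices[loop].mean(axis=0)
    ci = len(sac.vertices)
    # boundary edge (a -> b) is wound a->b in the sac, so the cap closes b->a
    cap = np.array(
        [[loop[(i + 1) % len(loop)], loop[i], ci] for i in range(len(loop))],
        dtype=np.int64,
    )
    closed = SurfaceMesh(
        vertices=np.vstack([sac.vertices, centroid[None, :]]),
        faces=np.vstack([sac.faces, cap]),
    )
    if not is_watertight(closed):
        raise GeometryError("capping did not produce a watertight mesh")
    return closed


# ---------------------------------------------------------------------------
# bulk quantities

def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Volume of a watertight mesh by the divergence theorem (DV, mm^3).

    Sum of signed tetrahedra (origin, v0, v1, v2) over faces; the absolute
    value makes the result independent of global winding direction.
    """
    if not is_watertight(mesh):
        raise GeometryError("enclosed_volume requires a watertight, "
                            "consistently oriented mesh")
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    return float(abs(signed.sum()))


def surface_area(mesh: SurfaceMesh) -> float:
    """Sum of triangle areas (DA for the open sac, mm^2)."""
    return float(mesh.triangle_areas.sum())


def convex_hull_metrics(mesh: SurfaceMesh) -> HullResult:
    """Convex hull of the closed sac's vertices: DV_CH and DA_CH.

    DA_CH is the full outer surface of the hull (cap side included), since
    the hull is taken of the closed sac.
    """
    try:
        hull = ConvexHull(mesh.vertices)
    except QhullError as exc:
        raise GeometryError(f"degenerate (coplanar) point set: {exc}") from exc
    return HullResult(hull_volume=float(hull.volume), hull_area=float(hull.area))


# ---------------------------------------------------------------------------
# neck plane and ostium

def fit_neck_plane(neck: NeckContour, sac_centroid: np.ndarray) -> PlaneFrame:
    """Total-least-squares plane through the neck contour.

    Origin is the contour centroid; the normal (smallest-eigenvector of the
    point covariance) is flipped toward the sac centroid; (u, v, normal)
    forms a right-handed orthonormal frame.
    """
    pts = neck.points
    origin = pts.mean(axis=0)
    centered = pts - origin
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-12 * max(evals[2], 1e-300):
        raise GeometryError("neck contour points are collinear; no plane fit")
    normal = evecs[:, 0]
    if normal @ (np.asarray(sac_centroid) - origin) < 0:
        normal = -normal
    u = evecs[:, 2]
    v = np.cross(normal, u)
    return PlaneFrame(origin=origin, normal=normal, in_plane_u=u, in_plane_v=v)


def polygon_metrics(
    neck: NeckContour, plane: PlaneFrame
) -> Tuple[float, float, np.ndarray]:
    """Ostium metrics: (NA, NC, centroid).

    NA is the shoelace area of the contour projected into the neck plane
    (the ostium is a planar quantity); NC is the length of the original 3D
    closed polyline (the perimeter is a curve property).  The returned
    centroid is the projected polygon's area centroid mapped back to 3D.
    """
    uv = plane.to_plane_coords(neck.points)
    poly = Polygon(uv)
    if not poly.is_valid:
        raise GeometryError("projected neck polygon is self-intersecting")
    na = float(poly.area)
    closed = np.vstack([neck.points, neck.points[:1]])
    nc = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    cen2d = np.asarray(poly.centroid.coords[0])
    centroid = (
        plane.origin + cen2d[0] * plane.in_plane_u + cen2d[1] * plane.in_plane_v
    )
    return na, nc, centroid


# ---------------------------------------------------------------------------
# extents and heights

def max_pairwise_distance(points: np.ndarray) -> Tuple[float, Tuple[int, int]]:
    """Exact maximum pairwise distance MD over a point set, with the pair.

    Hull-accelerated for large sets (the diameter is attained at hull
    vertices); ties are broken by the lexicographically smallest index pair.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise InputError("max_pairwise_distance needs at least 2 points")
    if len(points) > 400:
        try:
            idx = np.unique(ConvexHull(points).vertices)
        except QhullError:
            idx = np.arange(len(points))
    else:
        idx = np.arange(len(points))
    sub = points[idx]
    best = -1.0
    # blocked pairwise search keeps memory bounded on fine meshes
    block = 2048
    for s in range(0, len(sub), block):
        d2 = np.sum((sub[s:s + block, None, :] - sub[None, :, :]) ** 2, axis=2)
        m = float(d2.max())
        if m > best:
            best = m
    pair = None
    for s in range(0, len(sub), block):
        d2 = np.sum((sub[s:s + block, None, :] - sub[None, :, :]) ** 2, axis=2)
        hits = np.argwhere(d2 == best)
        for i, j in hits:
            gi, gj = int(idx[s + i]), int(idx[j])
            if gi > gj:
                gi, gj = gj, gi
            if gi == gj:
                continue
            if pair is None or (gi, gj) < pair:
                pair = (gi, gj)
    return float(np.sqrt(best)), pair


def max_plane_distance(sac: SurfaceMesh, plane: PlaneFrame) -> float:
    """MPH: maximum signed vertex distance above the neck plane (mm)."""
    d = plane.signed_distance(sac.vertices)
    mph = float(d.max())
    if mph <= 0:
        raise GeometryError("no sac vertex lies above the neck plane; "
                            "check plane orientation")
    return mph


def _ray_mesh_intersections(
    mesh: SurfaceMesh, origin: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Distances t > 0 of ray origin + t*direction hits (Moller-Trumbore)."""
    v = mesh.vertices
    a = v[mesh.faces[:, 0]]
    e1 = v[mesh.faces[:, 1]] - a
    e2 = v[mesh.faces[:, 2]] - a
    h = np.cross(direction[None, :], e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = origin[None, :] - a
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    vv = q @ direction * inv
    t = np.einsum("ij,ij->i", q, e2) * inv
    eps = 1e-9
    hit = ok & (u >= -eps) & (vv >= -eps) & (u + vv <= 1 + eps) & (t > 1e-9)
    return t[hit]


def central_height(sac: SurfaceMesh, plane: PlaneFrame) -> float:
    """CPH: distance from the neck centroid to the farthest intersection of
    the ray along the plane normal with the sac surface (mm)."""
    t = _ray_mesh_intersections(sac, plane.origin, plane.normal)
    if len(t) == 0:
        raise GeometryError("central ray misses the sac surface "
                            "(pathologically tilted sac)")
    return float(t.max())


def cross_section_area(
    mesh: SurfaceMesh, point: np.ndarray, normal: np.ndarray
) -> float:
    """Area of the planar cross-section of a closed, oriented mesh.

    Each triangle crossing the plane contributes one boundary segment,
    directed as normal x triangle_normal; the area then follows from the
    shoelace sum over directed segments (order-free for a closed curve).
    """
    v = mesh.vertices
    s = (v - np.asarray(point)) @ normal
    s = np.where(s == 0.0, 1e-14, s)  # nudge on-plane vertices off the plane
    sf = s[mesh.faces]
    crossing = ~(np.all(sf > 0, axis=1) | np.all(sf < 0, axis=1))
    if not np.any(crossing):
        return 0.0
    faces = mesh.faces[crossing]
    sfc = sf[crossing]
    # build an in-plane 2D frame
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(n @ tmp) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, tmp)
    u /= np.linalg.norm(u)
    w = np.cross(n, u)

    tri = v[faces]  # (m, 3, 3)
    tri_n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    m = len(faces)
    pts = np.empty((m, 3, 3))
    crossing_edge = np.empty((m, 3), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for e, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
            di, dj = sfc[:, i], sfc[:, j]
            crossing_edge[:, e] = di * dj < 0
            t = di / (di - dj)
            pts[:, e, :] = tri[:, i, :] + t[:, None] * (tri[:, j, :] - tri[:, i, :])
    # after the on-plane nudge every crossing face has exactly 2 crossing edges
    order = np.argsort(~crossing_edge, axis=1, kind="stable")
    rows = np.arange(m)
    a3 = pts[rows, order[:, 0]]
    b3 = pts[rows, order[:, 1]]
    seg_dir = np.cross(n[None, :], tri_n)
    flip = np.einsum("ij,ij->i", b3 - a3, seg_dir) < 0
    a3, b3 = (
        np.where(flip[:, None], b3, a3),
        np.where(flip[:, None], a3, b3),
    )
    rel_a, rel_b = a3 - point, b3 - point
    area2 = np.sum((rel_a @ u) * (rel_b @ w) - (rel_a @ w) * (rel_b @ u))
    return float(abs(area2) / 2.0)


def largest_parallel_section(
    sac_closed: SurfaceMesh, plane: PlaneFrame, n_slices: int = 200
) -> float:
    """MDPN: offset of the neck-parallel cut-plane with the largest area.

    Sweeps offsets d in [0, MPH] in ``n_slices`` uniform steps over the
    closed sac; ties resolve to the offset nearest the neck.  Offsets are
    evaluated a hair inside (0, MPH) to avoid degenerate slices exactly on
    the cap or through the apex.
    """
    if n_slices < 10:
        raise InputError("n_slices must be >= 10")
    mph = max_plane_distance(sac_closed, plane)
    offsets = np.linspace(0.0, mph, n_slices)
    eps = 1e-6 * mph
    areas = np.empty(n_slices)
    for i, d in enumerate(offsets):
        d_eval = min(max(d, eps), mph - eps)
        areas[i] = cross_section_area(
            sac_closed, plane.origin + d_eval * plane.normal, plane.normal
        )
    return float(offsets[int(np.argmax(areas))])


def projection_length(sac: SurfaceMesh, vessel_axis: np.ndarray) -> float:
    """PL: extent of the sac's shadow along the parent-vessel axis (mm)."""
    proj = sac.vertices @ np.asarray(vessel_axis, dtype=float)
    return float(proj.max() - proj.min())
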