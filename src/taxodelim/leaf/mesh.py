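"""Constrained triangulation of a leaf contour with an embedded midvein.

The contour polygon is split along the midvein polyline (extended to
touch the contour at both ends) into two half-polygons; each half is
triangulated with a constrained Delaunay triangulation (no Steiner
points), so every midvein and contour segment appears as a mesh edge.
Uniform midpoint (1-to-4) subdivision then refines the mesh until no
triangle exceeds the requested maximum area, keeping triangle quality and
all constrained chains intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon

from .annotations import LeafAnnotation

_ROUND = 9  # decimals used to key vertices when merging the two halves


@dataclass
class TriMesh:
    """2-D triangle mesh with constrained contour and midvein chains."""

    vertices: np.ndarray  # (nv, 2)
    triangles: np.ndarray  # (nt, 3) CCW vertex indices
    boundary_vertex_ids: np.ndarray  # contour ring order
    midvein_vertex_ids: np.ndarray  # base -> tip order
    constrained_edges: np.ndarray = field(default=None)  # (ne, 2)
    input_contour_ids: np.ndarray | None = None  # ids of the input polygon
    # vertices, in input order (stable across refinement)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.boundary_vertex_ids = np.asarray(self.boundary_vertex_ids, dtype=np.int64)
        self.midvein_vertex_ids = np.asarray(self.midvein_vertex_ids, dtype=np.int64)
        if self.constrained_edges is None:
            ring = self.boundary_vertex_ids
            edges = [(ring[i], ring[(i + 1) % len(ring)]) for i in range(len(ring))]
            mv = self.midvein_vertex_ids
            edges += [(mv[i], mv[i + 1]) for i in range(len(mv) - 1)]
            self.constrained_edges = np.asarray(edges, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, i]] for i in range(3))
        u, v = b - a, c - a
        return 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])

    def boundary_polygon(self) -> np.ndarray:
        return self.vertices[self.boundary_vertex_ids]

    def midvein(self) -> np.ndarray:
        return self.vertices[self.midvein_vertex_ids]

    def edge_set(self) -> set[tuple[int, int]]:
        edges: set[tuple[int, int]] = set()
        for t in self.triangles:
            for i in range(3):
                a, b = int(t[i]), int(t[(i + 1) % 3])
                edges.add((min(a, b), max(a, b)))
        return edges

    def with_vertices(self, new_vertices: np.ndarray) -> "TriMesh":
        """Same topology, new vertex positions."""
        return TriMesh(
            np.asarray(new_vertices, dtype=float),
            self.triangles,
            self.boundary_vertex_ids,
            self.midvein_vertex_ids,
            self.constrained_edges,
            self.input_contour_ids,
        )


def _ray_to_ring(ring: np.ndarray, origin: np.ndarray, direction: np.ndarray):
    """First intersection of the outward ray with the contour ring."""
    d = direction / (np.linalg.norm(direction) + 1e-12)
    span = 10.0 * (ring.max(axis=0) - ring.min(axis=0)).max()
    probe = LineString([origin, origin + span * d])
    boundary = LineString(np.vstack([ring, ring[:1]]))
    hit = probe.intersection(boundary)
    if hit.is_empty:
        raise ValueError("midvein extension does not reach the contour")
    pts = (
        [hit]
        if hit.geom_type == "Point"
        else [g for g in hit.geoms if g.geom_type == "Point"]
    )
    coords = min(pts, key=lambda p: np.hypot(p.x - origin[0], p.y - origin[1]))
    return np.array([coords.x, coords.y])


def _insert_on_ring(ring: list[np.ndarray], point: np.ndarray) -> int:
    """Insert ``point`` into the ring at its nearest edge; return its index."""
    best, best_d = 0, np.inf
    n = len(ring)
    for i in range(n):
        a, b = ring[i], ring[(i + 1) % n]
        ab = b - a
        t = np.clip(np.dot(point - a, ab) / max(np.dot(ab, ab), 1e-30), 0.0, 1.0)
        d = np.linalg.norm(point - (a + t * ab))
        if d < best_d:
            best, best_d, best_t = i, d, t
    a, b = ring[best], ring[(best + 1) % n]
    if np.linalg.norm(point - a) < 1e-9:
        return best
    if np.linalg.norm(point - b) < 1e-9:
        return (best + 1) % n
    ring.insert(best + 1, point.copy())
    return best + 1


def build_mesh(leaf: LeafAnnotation, max_triangle_area: float | None = None) -> TriMesh:
    """Constrained Delaunay mesh of the leaf interior.

    The midvein chain and the contour ring are mesh edges; Steiner points
    are introduced only by the optional uniform refinement
    (``max_triangle_area``).
    """
    leaf.validate(strict=False)
    poly = Polygon(leaf.contour)
    if poly.area <= 0:
        raise ValueError("degenerate (zero-area) contour")
    contour = leaf.contour
    if _signed_area(contour) < 0:  # force CCW ring
        contour = contour[::-1]
    mid = leaf.midvein.copy()

    ring = [np.asarray(p, dtype=float) for p in contour]
    # extend midvein ends onto the ring (no-op when already on it)
    base_dir = mid[0] - mid[1]
    tip_dir = mid[-1] - mid[-2]
    base_pt = (
        mid[0]
        if _on_ring(ring, mid[0])
        else _ray_to_ring(contour, mid[0], base_dir)
    )
    tip_pt = (
        mid[-1]
        if _on_ring(ring, mid[-1])
        else _ray_to_ring(contour, mid[-1], tip_dir)
    )
    path = [base_pt] + [p for p in mid if not (
        np.linalg.norm(p - base_pt) < 1e-9 or np.linalg.norm(p - tip_pt) < 1e-9
    )] + [tip_pt]
    path = np.asarray(path)

    ib = _insert_on_ring(ring, path[0])
    it = _insert_on_ring(ring, path[-1])
    ib = _locate(ring, path[0])
    it = _locate(ring, path[-1])
    n = len(ring)
    arc_a = [ring[(ib + k) % n] for k in range((it - ib) % n + 1)]
    arc_b = [ring[(it + k) % n] for k in range((ib - it) % n + 1)]
    interior = path[1:-1]
    half1 = arc_a + list(interior[::-1])  # tip..base interior closes arc A
    half2 = arc_b + list(interior)

    verts: list[np.ndarray] = []
    index: dict[tuple, int] = {}

    def vid(p: np.ndarray) -> int:
        key = tuple(np.round(p, _ROUND))
        if key not in index:
            index[key] = len(verts)
            verts.append(np.asarray(p, dtype=float))
        return index[key]

    tris: list[tuple[int, int, int]] = []
    for half in (half1, half2):
        hp = Polygon(half)
        if not hp.is_valid or hp.area <= 0:
            raise ValueError(
                "midvein does not split the contour into two simple halves"
            )
        cdt = shapely.constrained_delaunay_triangles(hp)
        for tri in cdt.geoms:
            coords = np.asarray(tri.exterior.coords)[:3]
            ids = tuple(vid(c) for c in coords)
            a, b, c = (verts[i] for i in ids)
            if (b - a)[0] * (c - a)[1] - (b - a)[1] * (c - a)[0] < 0:
                ids = (ids[0], ids[2], ids[1])
            tris.append(ids)

    ring_ids = np.array([vid(p) for p in ring], dtype=np.int64)
    mid_ids = np.array([vid(p) for p in path], dtype=np.int64)
    input_ids = np.array([vid(p) for p in leaf.contour], dtype=np.int64)
    mesh = TriMesh(
        np.asarray(verts), np.asarray(tris), ring_ids, mid_ids,
        input_contour_ids=input_ids,
    )
    _check_constraints(mesh)
    if max_triangle_area is not None:
        while mesh.triangle_areas().max() > max_triangle_area:
            mesh = _subdivide(mesh)
    return mesh


def _signed_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _on_ring(ring: list[np.ndarray], p: np.ndarray) -> bool:
    n = len(ring)
    for i in range(n):
        a, b = ring[i], ring[(i + 1) % n]
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-30), 0.0, 1.0)
        if np.linalg.norm(p - (a + t * ab)) < 1e-9:
            return True
    return False


def _locate(ring: list[np.ndarray], p: np.ndarray) -> int:
    for i, q in enumerate(ring):
        if np.linalg.norm(p - q) < 1e-9:
            return i
    raise ValueError("point not found on ring")


def _check_constraints(mesh: TriMesh) -> None:
    edges = mesh.edge_set()
    for a, b in mesh.constrained_edges:
        if (min(a, b), max(a, b)) not in edges:
            raise ValueError("a constrained edge is missing from the mesh")
    if (mesh.triangle_areas() <= 0).any():
        raise ValueError("degenerate triangle in mesh")


def _subdivide(mesh: TriMesh) -> TriMesh:
    """Uniform 1-to-4 midpoint subdivision (no hanging nodes)."""
    verts = list(mesh.vertices)
    midpoint: dict[tuple[int, int], int] = {}

    def mid_id(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in midpoint:
            midpoint[key] = len(verts)
            verts.append((mesh.vertices[a] + mesh.vertices[b]) / 2.0)
        return midpoint[key]

    tris = []
    for a, b, c in mesh.triangles:
        ab, bc, ca = mid_id(a, b), mid_id(b, c), mid_id(c, a)
        tris += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]

    def refine_chain(chain: np.ndarray, closed: bool) -> np.ndarray:
        out = []
        m = len(chain)
        last = m if closed else m - 1
        for i in range(last):
            a, b = int(chain[i]), int(chain[(i + 1) % m])
            out += [a, mid_id(a, b)]
        if not closed:
            out.append(int(chain[-1]))
        return np.asarray(out, dtype=np.int64)

    ring_ids = refine_chain(mesh.boundary_vertex_ids, closed=True)
    mid_ids = refine_chain(mesh.midvein_vertex_ids, closed=False)
    return TriMesh(
        np.asarray(verts), np.asarray(tris), ring_ids, mid_ids,
        input_contour_ids=mesh.input_contour_ids,
    )
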