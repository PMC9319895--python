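"""As-rigid-as-possible leaf straightening.

The midvein vertices are moved onto the horizontal axis -- anchored at
the basal vertex at the origin, tip along +x, with consecutive spacing
equal to the original Euclidean spacing, so the midvein arc length is
conserved exactly.  All other vertices follow by minimizing the ARAP
energy with local-global iterations: the local step fits a per-vertex
rotation to the deformed one-ring (in 2-D the optimum has the closed
form theta_i = atan2(sum w e0 x e1, sum w e0 . e1)), the global step
solves the cotangent-Laplacian system with the fitted rotations on the
right-hand side and the midvein vertices as hard constraints.  Cotangent
weights are clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

from .mesh import TriMesh


@dataclass
class StraightenResult:
    mesh: TriMesh  # deformed mesh (same topology)
    contour: np.ndarray  # deformed boundary polygon, ring order
    converged: bool
    n_iterations: int
    final_residual: float


def _edge_weights(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Unique edges (E, 2) and their cotangent weights, clamped >= 0."""
    v = mesh.vertices
    t = mesh.triangles
    acc: dict[tuple[int, int], float] = {}
    for k in range(3):
        i = t[:, k]
        j = t[:, (k + 1) % 3]
        o = t[:, (k + 2) % 3]
        a = v[i] - v[o]
        b = v[j] - v[o]
        cross = np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
        cot = (a * b).sum(axis=1) / np.maximum(cross, 1e-12)
        for ii, jj, cc in zip(i, j, cot):
            key = (min(int(ii), int(jj)), max(int(ii), int(jj)))
            acc[key] = acc.get(key, 0.0) + 0.5 * float(cc)
    edges = np.array(list(acc.keys()), dtype=np.int64)
    w = np.maximum(np.array(list(acc.values())), 0.0)
    return edges, w


def _rigid_align(
    source: np.ndarray, target: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Apply the rigid motion (no scaling) fitting source -> target."""
    mu_s, mu_t = source.mean(axis=0), target.mean(axis=0)
    s, t = source - mu_s, target - mu_t
    theta = np.arctan2(
        float((s[:, 0] * t[:, 1] - s[:, 1] * t[:, 0]).sum()),
        float((s * t).sum()),
    )
    c, si = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -si], [si, c]])
    return (points - mu_s) @ rot.T + mu_t


def straighten(
    mesh: TriMesh, tol: float = 1e-6, max_iterations: int = 400
) -> StraightenResult:
    """Straighten the midvein and deform the rest as rigidly as possible.

    Iterates local and global steps until the maximum vertex displacement
    per iteration drops below ``tol`` (absolute, same pixel units as the
    mesh) or ``max_iterations`` is reached; non-convergence returns the
    last iterate with ``converged=False`` and a warning.
    """
    if len(mesh.midvein_vertex_ids) < 2:
        raise ValueError("need at least two midvein vertices")
    v0 = mesh.vertices
    n = len(v0)
    mv = mesh.midvein_vertex_ids
    seg = np.linalg.norm(np.diff(v0[mv], axis=0), axis=1)
    target = np.zeros((len(mv), 2))
    target[1:, 0] = np.cumsum(seg)

    edges, w = _edge_weights(mesh)
    ei, ej = edges[:, 0], edges[:, 1]
    d0 = v0[ei] - v0[ej]

    constrained = np.zeros(n, dtype=bool)
    constrained[mv] = True
    free = np.where(~constrained)[0]
    free_pos = -np.ones(n, dtype=np.int64)
    free_pos[free] = np.arange(len(free))

    pos = v0.copy()
    pos[mv] = target

    # cotangent Laplacian restricted to free vertices
    deg = np.zeros(n)
    np.add.at(deg, ei, w)
    np.add.at(deg, ej, w)
    ff = (~constrained[ei]) & (~constrained[ej])
    rows = np.concatenate([free_pos[free], free_pos[ei[ff]], free_pos[ej[ff]]])
    cols = np.concatenate([free_pos[free], free_pos[ej[ff]], free_pos[ei[ff]]])
    vals = np.concatenate([deg[free], -w[ff], -w[ff]])
    lap = coo_matrix((vals, (rows, cols)), shape=(len(free), len(free)))
    solver = splu(csc_matrix(lap)) if len(free) else None

    # static boundary term: w * (fixed neighbor position)
    def fixed_term(current: np.ndarray) -> np.ndarray:
        b = np.zeros((len(free), 2))
        fi = constrained[ej] & ~constrained[ei]
        np.add.at(b, free_pos[ei[fi]], w[fi, None] * current[ej[fi]])
        fj = constrained[ei] & ~constrained[ej]
        np.add.at(b, free_pos[ej[fj]], w[fj, None] * current[ei[fj]])
        return b

    const_b = fixed_term(pos)

    if len(free):
        # initial guess: rigid motion best aligning the midvein to its target
        pos[free] = _rigid_align(v0[mv], target, v0[free])

    converged = not len(free)
    resid = 0.0
    it = 0
    for it in range(1, max_iterations + 1):
        if converged:
            break
        d1 = pos[ei] - pos[ej]
        cross = w * (d0[:, 0] * d1[:, 1] - d0[:, 1] * d1[:, 0])
        dot = w * (d0 * d1).sum(axis=1)
        num = np.zeros(n)
        den = np.zeros(n)
        np.add.at(num, ei, cross)
        np.add.at(num, ej, cross)
        np.add.at(den, ei, dot)
        np.add.at(den, ej, dot)
        theta = np.arctan2(num, den)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.empty((n, 2, 2))
        rot[:, 0, 0] = c
        rot[:, 0, 1] = -s
        rot[:, 1, 0] = s
        rot[:, 1, 1] = c

        r_edge = 0.5 * (rot[ei] + rot[ej])
        contrib = w[:, None] * np.einsum("eab,eb->ea", r_edge, d0)
        b = const_b.copy()
        mask_i = ~constrained[ei]
        np.add.at(b, free_pos[ei[mask_i]], contrib[mask_i])
        mask_j = ~constrained[ej]
        np.add.at(b, free_pos[ej[mask_j]], -contrib[mask_j])

        new_free = solver.solve(b)
        resid = float(np.abs(new_free - pos[free]).max())
        pos[free] = new_free
        if resid < tol:
            converged = True
    if not converged:
        import warnings

        warnings.warn(
            f"ARAP did not converge in {max_iterations} iterations "
            f"(final residual {resid:.2e})",
            stacklevel=2,
        )
    deformed = mesh.with_vertices(pos)
    return StraightenResult(
        deformed, deformed.boundary_polygon(), converged, it, resid
    )
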