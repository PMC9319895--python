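"""Barycentric texture transfer between two meshes of shared topology."""

from __future__ import annotations

import numpy as np
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder
from scipy.ndimage import map_coordinates

from .mesh import TriMesh


def map_texture(
    original: TriMesh,
    deformed: TriMesh,
    image: np.ndarray,
    background: float = 0.0,
    oversample: float = 1.0,
) -> np.ndarray:
    """Sample the source image through the mesh deformation.

    Every output pixel whose center lies inside the deformed mesh is
    located in its triangle, expressed in barycentric coordinates, mapped
    to the corresponding source position in the original mesh, and
    bilinearly sampled from ``image`` (indexed ``image[y, x]``, y down).
    Pixels outside the mesh are set to ``background``.  The output grid
    covers the deformed mesh's bounding box at the source pixel scale
    times ``oversample``.
    """
    if original.triangles.shape != deformed.triangles.shape or not np.array_equal(
        original.triangles, deformed.triangles
    ):
        raise ValueError("meshes must share topology")
    image = np.asarray(image, dtype=float)

    lo = deformed.vertices.min(axis=0)
    hi = deformed.vertices.max(axis=0)
    width = max(int(np.ceil((hi[0] - lo[0]) * oversample)) + 1, 2)
    height = max(int(np.ceil((hi[1] - lo[1]) * oversample)) + 1, 2)
    xs = lo[0] + (np.arange(width) + 0.5) / oversample
    ys = lo[1] + (np.arange(height) + 0.5) / oversample
    gx, gy = np.meshgrid(xs, ys)

    tri = Triangulation(
        deformed.vertices[:, 0], deformed.vertices[:, 1], deformed.triangles
    )
    finder = TrapezoidMapTriFinder(tri)
    t_idx = finder(gx.ravel(), gy.ravel())
    inside = t_idx >= 0

    out = np.full(gx.shape, background, dtype=float).ravel()
    if inside.any():
        tids = t_idx[inside]
        tri_v = deformed.vertices[deformed.triangles[tids]]  # (m, 3, 2)
        p = np.column_stack([gx.ravel()[inside], gy.ravel()[inside]])
        bary = _barycentric(tri_v, p)
        src_tri = original.vertices[original.triangles[tids]]
        src = np.einsum("mk,mkd->md", bary, src_tri)
        sampled = map_coordinates(
            image, [src[:, 1], src[:, 0]], order=1, mode="constant", cval=background
        )
        out[inside] = sampled
    return out.reshape(gy.shape)


def rasterize_mask(contour: np.ndarray, pad: int = 2) -> np.ndarray:
    """Binary silhouette mask of a polygon at pixel resolution.

    The grid covers the contour's bounding box plus ``pad`` pixels;
    suitable for writing straightened silhouettes as image masks.
    """
    from matplotlib.path import Path as MplPath

    contour = np.asarray(contour, dtype=float)
    lo = np.floor(contour.min(axis=0)) - pad
    hi = np.ceil(contour.max(axis=0)) + pad
    xs = np.arange(lo[0], hi[0] + 1) + 0.5
    ys = np.arange(lo[1], hi[1] + 1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    path = MplPath(contour)
    inside = path.contains_points(np.column_stack([gx.ravel(), gy.ravel()]))
    return inside.reshape(gy.shape)


def _barycentric(tri_v: np.ndarray, p: np.ndarray) -> np.ndarray:
    a, b, c = tri_v[:, 0], tri_v[:, 1], tri_v[:, 2]
    v0, v1, v2 = b - a, c - a, p - a
    d00 = (v0 * v0).sum(1)
    d01 = (v0 * v1).sum(1)
    d11 = (v1 * v1).sum(1)
    d20 = (v2 * v0).sum(1)
    d21 = (v2 * v1).sum(1)
    denom = np.maximum(d00 * d11 - d01 * d01, 1e-30)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    return np.column_stack([u, v, w])
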