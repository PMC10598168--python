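"""Vectorised Moller-Trumbore ray/triangle intersection.

Shadow casting and the mesh-to-mesh distance oracle both reduce to "first
positive intersection of a ray with a triangle soup"; this module provides
that primitive without any spatial indexing (the patch/opposing-surface
sizes this package works at make the dense ray x triangle product cheap,
and the absence of broad-phase culling keeps the result exact).
"""

from __future__ import annotations

import numpy as np

__all__ = ["first_hit_distance"]

_EPS = 1e-12


def first_hit_distance(
    origins: np.ndarray,
    directions: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    t_min: float = 1e-9,
    chunk: int = 4_000_000,
) -> np.ndarray:
    """Distance along each ray to its first triangle hit (inf when none).

    Rays with non-finite or near-zero direction vectors return inf.
    ``chunk`` bounds the rays x triangles working-set size.
    """
    origins = np.atleast_2d(np.asarray(origins, float))
    directions = np.atleast_2d(np.asarray(directions, float))
    tri = np.asarray(vertices, float)[np.asarray(faces)]
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    n_rays, n_tri = len(origins), len(tri)
    best = np.full(n_rays, np.inf)
    ok = np.isfinite(directions).all(axis=1) & (np.linalg.norm(directions, axis=1) > 1e-9)
    if n_tri == 0 or not ok.any():
        return best
    rows_per_block = max(1, chunk // max(n_tri, 1))
    idx_ok = np.flatnonzero(ok)
    for lo in range(0, len(idx_ok), rows_per_block):
        rows = idx_ok[lo : lo + rows_per_block]
        o = origins[rows][:, None, :]  # (r, 1, 3)
        d = directions[rows][:, None, :]
        p = np.cross(d, e2[None, :, :])  # (r, m, 3)
        det = np.einsum("rmk,mk->rm", p, e1)
        inv = np.where(np.abs(det) > _EPS, 1.0 / np.where(det == 0, 1.0, det), np.nan)
        s = o - v0[None, :, :]
        u = np.einsum("rmk,rmk->rm", s, p) * inv
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("rmk,rmk->rm", q, d) * inv
        t = np.einsum("rmk,mk->rm", q, e2) * inv
        hit = (
            np.isfinite(t)
            & (u >= -1e-9)
            & (v >= -1e-9)
            & (u + v <= 1.0 + 1e-9)
            & (t > t_min)
        )
        t = np.where(hit, t, np.inf)
        best[rows] = t.min(axis=1)
    return best
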