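"""Closest-point queries on triangle meshes.

A KD-tree over triangle centroids supplies candidate faces for each query
point; the exact closest point on each candidate triangle is found with
the standard barycentric clamping construction and the best candidate
wins.  Candidate sets also include the faces incident to the nearest mesh
vertex, so the query is exact on the uniformly sized triangulations this
package produces.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_point_triangles", "MeshProximity"]


def closest_point_triangles(points: np.ndarray, triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on each triangle to each paired query point.

    ``points``: (n, 3); ``triangles``: (n, 3, 3).  Returns (closest (n, 3),
    barycentric (n, 3)).
    """
    p = np.asarray(points, float)
    tri = np.asarray(triangles, float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(denom != 0, vb / denom, 0.0)
        w_face = np.where(denom != 0, vc / denom, 0.0)

    n = len(p)
    u = np.empty(n)
    v = np.empty(n)
    # region tests in priority order (Ericson, Real-Time Collision Detection)
    cond_a = (d1 <= 0) & (d2 <= 0)  # vertex a
    cond_b = (d3 >= 0) & (d4 <= d3)  # vertex b
    cond_c = (d6 >= 0) & (d5 <= d6)  # vertex c
    cond_ab = (d1 * d4 - d3 * d2 <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        db = d4 - d3
        dc = d5 - d6
        t_bc = np.where(db + dc != 0, db / (db + dc), 0.0)

    # default: interior of the face
    u[:] = v_face
    v[:] = w_face
    u_list = [
        (cond_bc, 1.0 - t_bc, t_bc),
        (cond_ac, 0.0, t_ac),
        (cond_ab, t_ab, 0.0),
        (cond_c, 0.0, 1.0),
        (cond_b, 1.0, 0.0),
        (cond_a, 0.0, 0.0),
    ]
    for cond, uu, vv in u_list:
        u = np.where(cond, uu, u)
        v = np.where(cond, vv, v)
    u = np.clip(u, 0.0, 1.0)
    v = np.clip(v, 0.0, 1.0)
    closest = a + u[:, None] * ab + v[:, None] * ac
    bary = np.column_stack([1.0 - u - v, u, v])
    return closest, bary


class MeshProximity:
    """Reusable closest-point structure for one mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k_candidates: int = 8):
        self.vertices = np.asarray(vertices, float)
        self.faces = np.asarray(faces)
        self.tri = self.vertices[self.faces]
        self.k = min(k_candidates, len(self.faces))
        self._centroid_tree = cKDTree(self.tri.mean(axis=1))
        self._vertex_tree = cKDTree(self.vertices)
        # faces incident to each vertex (ragged, padded with 0)
        n_v = len(self.vertices)
        counts = np.zeros(n_v, dtype=int)
        for col in range(3):
            np.add.at(counts, self.faces[:, col], 1)
        max_deg = int(counts.max()) if n_v else 0
        incident = np.zeros((n_v, max_deg), dtype=np.int64)
        fill = np.zeros(n_v, dtype=int)
        for fi, face in enumerate(self.faces):
            for vert in face:
                incident[vert, fill[vert]] = fi
                fill[vert] += 1
        self._incident = incident
        self._incident_counts = counts

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Returns (closest points, distances, face indices, barycentric)."""
        points = np.atleast_2d(np.asarray(points, float))
        n = len(points)
        _, cand_c = self._centroid_tree.query(points, k=self.k)
        cand_c = np.atleast_2d(cand_c)
        _, nearest_v = self._vertex_tree.query(points)
        cand_v = self._incident[nearest_v]
        cands = np.hstack([cand_c, cand_v])  # (n, k + max_deg)
        m = cands.shape[1]
        flat_pts = np.repeat(points, m, axis=0)
        flat_tris = self.tri[cands.ravel()]
        closest, bary = closest_point_triangles(flat_pts, flat_tris)
        d2 = np.einsum("ij,ij->i", flat_pts - closest, flat_pts - closest).reshape(n, m)
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        flat_best = rows * m + best
        return (
            closest[flat_best],
            np.sqrt(d2[rows, best]),
            cands[rows, best],
            bary[flat_best],
        )
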