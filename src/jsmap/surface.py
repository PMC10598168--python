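"""Triangulated bone surfaces, per-vertex scalar fields and patch operations.

The articular surface of a bone is represented as a triangle mesh in
millimetres with outward unit vertex normals.  Measurements (joint space
width, bias, limits of agreement, F statistics, ...) live on the mesh as
:class:`ScalarField` objects — one value per vertex plus a validity mask.
A :class:`JointPatch` is a connected submesh delimiting one articular facet
(e.g. talonavicular or posterior subtalar), carrying the index map back to
its parent mesh so fields can be moved between the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SurfaceMesh",
    "ScalarField",
    "JointPatch",
    "EmptyPatchError",
    "EmptyFieldError",
    "patch_submesh",
    "smooth_field",
    "patch_mean",
    "load_mesh",
    "save_mesh",
    "write_vtk_polydata",
]


class EmptyPatchError(ValueError):
    """Raised when a patch mask selects no complete face."""


class EmptyFieldError(ValueError):
    """Raised when a reduction is requested over a field with no valid vertex."""


@dataclass
class SurfaceMesh:
    """Triangle mesh in mm with per-vertex outward unit normals.

    Parameters
    ----------
    vertices : (n, 3) float array, positions in mm (right-handed frame).
    faces : (m, 3) int array, 0-based vertex indices.
    normals : (n, 3) float array or None
        Per-vertex unit normals; computed (area-weighted, via trimesh) when
        omitted.  Supplied normals are renormalised and must be finite.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")
        if self.normals is None:
            tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
            self.normals = np.array(tm.vertex_normals, dtype=float)
        else:
            self.normals = np.ascontiguousarray(self.normals, dtype=float)
            if self.normals.shape != self.vertices.shape:
                raise ValueError("normals must match vertices in shape")
            norm = np.linalg.norm(self.normals, axis=1)
            bad = ~np.isfinite(norm) | (norm < 1e-12)
            safe = np.where(bad, 1.0, norm)
            self.normals = self.normals / safe[:, None]
            self.normals[bad] = np.nan  # degenerate normals flagged, not fatal
        self._adjacency: sparse.csr_matrix | None = None
        self._vertex_areas: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def vertex_adjacency(self) -> sparse.csr_matrix:
        """Symmetric boolean vertex adjacency (1-ring connectivity)."""
        if self._adjacency is None:
            i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
            j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
            n = self.n_vertices
            a = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
            a = ((a + a.T) > 0).astype(float).tocsr()
            self._adjacency = a
        return self._adjacency

    @property
    def face_areas(self) -> np.ndarray:
        v = self.vertices
        e1 = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        e2 = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric lumped vertex areas: one third of incident face areas."""
        if self._vertex_areas is None:
            w = np.zeros(self.n_vertices)
            fa = self.face_areas / 3.0
            for k in range(3):
                np.add.at(w, self.faces[:, k], fa)
            self._vertex_areas = w
        return self._vertex_areas

    @property
    def mean_edge_length(self) -> float:
        v = self.vertices
        lengths = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            lengths.append(np.linalg.norm(v[self.faces[:, a]] - v[self.faces[:, b]], axis=1))
        return float(np.mean(np.concatenate(lengths))) if self.n_faces else 0.0

    # ------------------------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "SurfaceMesh":
        return cls(np.array(tm.vertices), np.array(tm.faces))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Return a rigidly transformed copy (normals rotate with the mesh)."""
        r = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return SurfaceMesh(self.vertices @ r.T + t, self.faces.copy(), self.normals @ r.T)


@dataclass
class ScalarField:
    """One real value per vertex with a validity mask.

    ``values`` must be finite wherever ``mask`` is true; masked-out entries
    are ignored by every reduction and smoothing step.
    """

    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).ravel()
            if self.mask.shape != self.values.shape:
                raise ValueError("mask must match values in length")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("values must be finite wherever mask is true")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "ScalarField":
        return ScalarField(self.values.copy(), self.mask.copy())


@dataclass
class JointPatch:
    """A connected articular facet extracted from a parent bone surface."""

    submesh: SurfaceMesh
    parent_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    label: str = ""

    def __post_init__(self) -> None:
        self.parent_index = np.asarray(self.parent_index, dtype=np.int64)
        if len(self.parent_index) != self.submesh.n_vertices:
            raise ValueError("parent_index must have one entry per patch vertex")
        if len(np.unique(self.parent_index)) != len(self.parent_index):
            raise ValueError("parent_index must be injective")

    @property
    def n_vertices(self) -> int:
        return self.submesh.n_vertices

    def field_from_parent(self, parent_field: ScalarField) -> ScalarField:
        vals = parent_field.values[self.parent_index]
        mask = parent_field.mask[self.parent_index]
        vals = np.where(mask, vals, np.nan)
        return ScalarField(np.where(mask, vals, 0.0), mask)


# ----------------------------------------------------------------------
# operations


def patch_submesh(mesh: SurfaceMesh, vertex_mask: np.ndarray, label: str = "") -> JointPatch:
    """Extract the largest connected facet induced by a vertex mask.

    Faces are kept iff all three vertices are selected; the largest connected
    component (by face count) of the induced submesh becomes the patch.
    Raises :class:`EmptyPatchError` when the mask spans no complete face.
    """
    vertex_mask = np.asarray(vertex_mask, dtype=bool).ravel()
    if vertex_mask.shape[0] != mesh.n_vertices:
        raise ValueError("vertex_mask must have one flag per mesh vertex")
    keep_face = vertex_mask[mesh.faces].all(axis=1)
    if not keep_face.any():
        raise EmptyPatchError("empty patch: mask selects no complete face")
    faces = mesh.faces[keep_face]
    # connected components over vertices linked by kept faces
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    n = mesh.n_vertices
    g = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    n_comp, labels = connected_components(g + g.T, directed=False)
    face_comp = labels[faces[:, 0]]
    counts = np.bincount(face_comp, minlength=n_comp)
    best = int(np.argmax(counts))
    faces = faces[face_comp == best]
    used = np.unique(faces)
    remap = np.full(n, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = SurfaceMesh(mesh.vertices[used], remap[faces], mesh.normals[used])
    return JointPatch(sub, used, label)


def smooth_field(
    field_: ScalarField,
    mesh: SurfaceMesh,
    iterations: int = 5,
    weight: float = 0.5,
) -> ScalarField:
    """Iterated masked umbrella (1-ring) smoothing.

    Each iteration replaces every valid vertex value by
    ``(1 - weight) * value + weight * mean(valid 1-ring neighbours)``;
    invalid vertices neither contribute to nor receive averages, and the
    mask is unchanged.  ``weight = 0`` is the identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    if len(field_) != mesh.n_vertices:
        raise ValueError("field is not hosted on this mesh")
    adj = mesh.vertex_adjacency
    m = field_.mask.astype(float)
    v = np.where(field_.mask, field_.values, 0.0)
    for _ in range(iterations):
        s = adj @ v
        c = adj @ m
        nbr = np.divide(s, c, out=v.copy(), where=c > 0)
        v = np.where(field_.mask & (c > 0), (1.0 - weight) * v + weight * nbr, v)
    out = np.where(field_.mask, v, np.nan)
    return ScalarField(np.where(field_.mask, out, 0.0), field_.mask.copy())


def patch_mean(field_: ScalarField, patch: JointPatch) -> float:
    """Area-weighted mean of a field over a patch (barycentric vertex lumping)."""
    mesh = patch.submesh
    if len(field_) == mesh.n_vertices:
        vals, mask = field_.values, field_.mask
    else:
        sub = patch.field_from_parent(field_)
        vals, mask = sub.values, sub.mask
    if not mask.any():
        raise EmptyFieldError("empty field: no valid vertices in patch")
    w = mesh.vertex_areas[mask]
    if w.sum() <= 0:
        raise EmptyFieldError("empty field: zero total vertex area")
    return float(np.sum(w * vals[mask]) / w.sum())


# ----------------------------------------------------------------------
# I/O


def load_mesh(path: str | Path, check_manifold: bool = True) -> SurfaceMesh:
    """Load a PLY/OBJ/STL mesh; non-manifold input produces a warning only."""
    tm = trimesh.load(str(path), force="mesh", process=False)
    if check_manifold and not tm.is_winding_consistent:
        warnings.warn(f"mesh {path} is not manifold/winding-consistent", RuntimeWarning)
    return SurfaceMesh.from_trimesh(tm)


def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write PLY or OBJ, chosen by the file extension."""
    mesh.to_trimesh().export(str(path))


def write_vtk_polydata(
    path: str | Path,
    mesh: SurfaceMesh,
    fields: dict[str, ScalarField | np.ndarray] | None = None,
) -> None:
    """Write legacy ASCII VTK PolyData with named per-vertex scalar arrays.

    Masked-out vertices are written as NaN so downstream viewers can blank
    them.  Array names follow the pipeline convention: "jsw", "bias", "loa",
    "F", "p_corrected", ...
    """
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "jsmap surface map",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} float",
    ]
    lines += [" ".join(f"{x:.6f}" for x in p) for p in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines += ["3 " + " ".join(str(int(i)) for i in f) for f in mesh.faces]
    if fields:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, f in fields.items():
            if isinstance(f, ScalarField):
                vals = np.where(f.mask, f.values, np.nan)
            else:
                vals = np.asarray(f, dtype=float)
            if len(vals) != mesh.n_vertices:
                raise ValueError(f"field {name!r} length does not match mesh")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6f}" if np.isfinite(v) else "nan" for v in vals]
    path.write_text("\n".join(lines) + "\n")
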