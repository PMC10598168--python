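import numpy as np
import pytest
import trimesh

from jsmap.surface import SurfaceMesh
from jsmap.phantoms import GapField, PhantomSpec, make_joint_phantom


def grid_mesh(n: int = 5, spacing: float = 1.0) -> SurfaceMesh:
    """Regular planar n x n grid in the z = 0 plane with +z normals."""
    coords = np.arange(n) * spacing
    uu, vv = np.meshgrid(coords, coords, indexing="ij")
    verts = np.column_stack([uu.ravel(), vv.ravel(), np.zeros(n * n)])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    normals = np.tile([0.0, 0.0, 1.0], (n * n, 1))
    return SurfaceMesh(verts, faces, normals)


@pytest.fixture
def grid5() -> SurfaceMesh:
    return grid_mesh(5)


@pytest.fixture
def icosphere() -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    return SurfaceMesh(np.array(tm.vertices), np.array(tm.faces))


@pytest.fixture(scope="session")
def slab_phantom():
    """Constant-gap 2.0 mm parallel-slab phantom, 1 mm mesh."""
    spec = PhantomSpec(
        geometry="parallel-slabs",
        extent=12.0,
        gap_field=GapField(kind="constant", value=2.0),
        mesh_resolution=1.0,
    )
    return make_joint_phantom(spec)


@pytest.fixture(scope="session")
def ramp_phantom():
    """Linear-ramp gap 1.9 -> 2.9 mm across a 20 mm patch."""
    spec = PhantomSpec(
        geometry="parallel-slabs",
        extent=20.0,
        gap_field=GapField(kind="ramp", lo=1.9, hi=2.9),
        mesh_resolution=1.0,
    )
    return make_joint_phantom(spec)


def brute_force_first_hit(origins, directions, vertices, faces, t_min=1e-9):
    """Scalar Moller-Trumbore over every (ray, triangle) pair: the exhaustive
    intersection oracle used to validate the vectorised implementation."""
    hits = np.full(len(origins), np.inf)
    tri = np.asarray(vertices)[np.asarray(faces)]
    for r, (o, d) in enumerate(zip(np.asarray(origins, float), np.asarray(directions, float))):
        if not np.all(np.isfinite(d)) or np.linalg.norm(d) < 1e-9:
            continue
        for v0, v1, v2 in tri:
            e1, e2 = v1 - v0, v2 - v0
            p = np.cross(d, e2)
            det = e1 @ p
            if abs(det) < 1e-12:
                continue
            s = o - v0
            u = (s @ p) / det
            if u < -1e-9 or u > 1 + 1e-9:
                continue
            q = np.cross(s, e1)
            v = (d @ q) / det
            if v < -1e-9 or u + v > 1 + 1e-9:
                continue
            t = (e2 @ q) / det
            if t > t_min and t < hits[r]:
                hits[r] = t
    return hits
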