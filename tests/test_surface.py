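"""Mesh container, patch extraction, smoothing and area-weighted means."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jsmap.surface import (
    EmptyFieldError,
    EmptyPatchError,
    JointPatch,
    ScalarField,
    SurfaceMesh,
    patch_mean,
    patch_submesh,
    smooth_field,
    write_vtk_polydata,
    save_mesh,
    load_mesh,
)

from conftest import grid_mesh


class TestSurfaceMesh:
    def test_normals_unit_length(self, icosphere):
        norms = np.linalg.norm(icosphere.normals, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_face_index_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))

    def test_vertex_areas_sum_to_total_area(self, icosphere):
        assert np.isclose(icosphere.vertex_areas.sum(), icosphere.face_areas.sum())

    def test_ply_roundtrip(self, tmp_path, icosphere):
        p = tmp_path / "m.ply"
        save_mesh(icosphere, p)
        back = load_mesh(p)
        assert back.n_vertices == icosphere.n_vertices
        assert np.allclose(back.vertices, icosphere.vertices, atol=1e-5)


class TestPatchSubmesh:
    def test_full_mask_is_identity(self, icosphere):
        patch = patch_submesh(icosphere, np.ones(icosphere.n_vertices, bool), "all")
        assert patch.n_vertices == icosphere.n_vertices
        assert patch.submesh.n_faces == icosphere.n_faces
        assert np.array_equal(np.sort(patch.parent_index), np.arange(icosphere.n_vertices))
        assert np.isclose(patch.submesh.face_areas.sum(), icosphere.face_areas.sum())

    def test_largest_island_kept(self):
        # two disjoint vertex islands on a 7x7 grid: brute-force face counting
        # confirms the larger one (by faces) is the one returned
        mesh = grid_mesh(7)
        mask = np.zeros(mesh.n_vertices, bool)
        idx = np.arange(49).reshape(7, 7)
        mask[idx[:4, :3].ravel()] = True  # island A
        mask[idx[5:, 5:].ravel()] = True  # island B (smaller)
        keep = mask[mesh.faces].all(axis=1)
        # brute-force connected components over kept faces
        faces = mesh.faces[keep]
        groups = []
        for f in faces:
            merged = [g for g in groups if g & set(f)]
            new = set(f).union(*merged) if merged else set(f)
            groups = [g for g in groups if not (g & set(f))] + [new]
        counts = sorted(sum(1 for f in faces if set(f) <= g) for g in groups)
        patch = patch_submesh(mesh, mask, "island")
        assert patch.submesh.n_faces == counts[-1]

    def test_no_complete_face_raises(self, grid5):
        mask = np.zeros(grid5.n_vertices, bool)
        mask[0] = mask[24] = True  # two isolated corners, no shared face
        with pytest.raises(EmptyPatchError):
            patch_submesh(grid5, mask)

    def test_parent_index_injective(self, grid5):
        mask = np.ones(grid5.n_vertices, bool)
        patch = patch_submesh(grid5, mask)
        assert len(np.unique(patch.parent_index)) == patch.n_vertices


class TestSmoothField:
    def test_constant_is_fixed_point(self, icosphere):
        f = ScalarField(np.full(icosphere.n_vertices, 3.7))
        out = smooth_field(f, icosphere, iterations=10, weight=0.8)
        assert np.allclose(out.values, 3.7)

    def test_impulse_one_step_hand_computed(self, grid5):
        # unit impulse at the centre vertex of a 5x5 grid, weight 1, 1 iter:
        # the impulse vertex becomes the mean of its (zero-valued) neighbours
        # = 0, and each neighbour becomes 1/degree of that neighbour.
        centre = 12
        vals = np.zeros(grid5.n_vertices)
        vals[centre] = 1.0
        out = smooth_field(ScalarField(vals), grid5, iterations=1, weight=1.0)
        assert out.values[centre] == 0.0
        adj = grid5.vertex_adjacency
        neighbours = adj[centre].nonzero()[1]
        for nb in neighbours:
            degree = adj[nb].getnnz()
            assert np.isclose(out.values[nb], 1.0 / degree)
        assert out.values.max() < vals.max()

    def test_converges_to_constant_on_closed_mesh(self, icosphere):
        rng = np.random.default_rng(0)
        f = ScalarField(rng.normal(size=icosphere.n_vertices))
        out = smooth_field(f, icosphere, iterations=1000, weight=1.0)
        assert out.values.max() - out.values.min() < 1e-3

    @settings(deadline=None, max_examples=20)
    @given(iters=st.integers(0, 5), seed=st.integers(0, 10))
    def test_weight_zero_is_identity(self, iters, seed):
        mesh = grid_mesh(4)
        vals = np.random.default_rng(seed).normal(size=mesh.n_vertices)
        out = smooth_field(ScalarField(vals), mesh, iterations=iters, weight=0.0)
        assert np.allclose(out.values, vals)

    def test_masked_vertices_excluded(self, grid5):
        vals = np.zeros(grid5.n_vertices)
        mask = np.ones(grid5.n_vertices, bool)
        vals[12] = 100.0
        mask[12] = False  # invalid spike must not leak into neighbours
        out = smooth_field(ScalarField(np.where(mask, vals, 0.0), mask), grid5, 3, 0.5)
        assert np.all(out.values[out.mask] == 0.0)
        assert np.array_equal(out.mask, mask)

    def test_negative_iterations_rejected(self, grid5):
        with pytest.raises(ValueError):
            smooth_field(ScalarField(np.zeros(25)), grid5, iterations=-1)


class TestPatchMean:
    def test_uniform_field(self, icosphere):
        patch = patch_submesh(icosphere, np.ones(icosphere.n_vertices, bool))
        f = ScalarField(np.full(patch.n_vertices, 2.73))
        assert np.isclose(patch_mean(f, patch), 2.73)

    def test_area_weighting_two_triangles(self):
        # right triangles of areas 0.5 and 1.5 sharing edge (0,0)-(0,1):
        # vertex weights are one third of summed incident face areas.
        verts = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 0], [-3, 0, 0.0]])
        faces = np.array([[0, 2, 1], [0, 1, 3]])
        mesh = SurfaceMesh(verts, faces, np.tile([0.0, 0, 1], (4, 1)))
        patch = JointPatch(mesh, np.arange(4), "two")
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([0.5 + 1.5, 0.5 + 1.5, 0.5, 1.5]) / 3.0
        expected = (w * vals).sum() / w.sum()
        got = patch_mean(ScalarField(vals), patch)
        assert np.isclose(got, expected)
        assert not np.isclose(got, vals.mean())  # weighting actually matters

    def test_all_masked_raises(self, icosphere):
        patch = patch_submesh(icosphere, np.ones(icosphere.n_vertices, bool))
        f = ScalarField(np.zeros(patch.n_vertices), np.zeros(patch.n_vertices, bool))
        with pytest.raises(EmptyFieldError):
            patch_mean(f, patch)

    @settings(deadline=None, max_examples=20)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5), seed=st.integers(0, 10))
    def test_linear_in_field_and_rigid_invariant(self, a, b, seed):
        mesh = grid_mesh(4)
        patch = JointPatch(mesh, np.arange(mesh.n_vertices), "g")
        rng = np.random.default_rng(seed)
        f1 = rng.normal(size=mesh.n_vertices)
        f2 = rng.normal(size=mesh.n_vertices)
        lhs = patch_mean(ScalarField(a * f1 + b * f2), patch)
        rhs = a * patch_mean(ScalarField(f1), patch) + b * patch_mean(ScalarField(f2), patch)
        assert np.isclose(lhs, rhs, atol=1e-9)
        # rigid motion of the mesh leaves the mean unchanged
        c, s = np.cos(0.7), np.sin(0.7)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = mesh.transformed(rot, np.array([3.0, -2.0, 1.0]))
        patch2 = JointPatch(moved, np.arange(mesh.n_vertices), "g")
        assert np.isclose(patch_mean(ScalarField(f1), patch2),
                          patch_mean(ScalarField(f1), patch), atol=1e-9)


class TestVTKWriter:
    def test_writes_named_scalar_arrays(self, tmp_path, grid5):
        f = ScalarField(np.arange(25.0), np.arange(25) % 2 == 0)
        path = tmp_path / "map.vtk"
        write_vtk_polydata(path, grid5, {"jsw": f, "bias": np.zeros(25)})
        text = path.read_text()
        assert "DATASET POLYDATA" in text
        assert "POINTS 25 float" in text
        assert "SCALARS jsw float 1" in text
        assert "SCALARS bias float 1" in text
        assert "nan" in text  # masked vertices blanked

    def test_length_mismatch_rejected(self, tmp_path, grid5):
        with pytest.raises(ValueError):
            write_vtk_polydata(tmp_path / "bad.vtk", grid5, {"jsw": np.zeros(3)})
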