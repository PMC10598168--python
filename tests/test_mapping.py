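"""Shadow casting, profile extraction and the blurred two-edge model."""

import numpy as np
import pytest
from scipy.special import ndtr

from jsmap.mapping import (
    MapParams,
    Profile,
    cast_shadow,
    extract_profile,
    fit_blur_model,
    map_jsw,
    ray_distance_oracle,
)
from jsmap.phantoms import GapField, PhantomSpec, make_joint_phantom, rasterize_ct
from jsmap.surface import JointPatch, SurfaceMesh, patch_mean
from jsmap.volume import OutOfBoundsError, VoxelVolume

from conftest import brute_force_first_hit, grid_mesh


def flat_patch(extent=10.0, spacing=1.0, z=0.0, flip=False, shift=(0.0, 0.0)):
    n = int(extent / spacing) + 1
    mesh = grid_mesh(n, spacing)
    verts = mesh.vertices.copy()
    verts[:, 0] += shift[0] - extent / 2
    verts[:, 1] += shift[1] - extent / 2
    verts[:, 2] = z
    normals = np.tile([0.0, 0.0, -1.0 if flip else 1.0], (len(verts), 1))
    return SurfaceMesh(verts, mesh.faces.copy(), normals)


def two_edge(t, b, a1, a2, e1, e2, s):
    return b + (a1 - b) * ndtr((e1 - t) / s) + (a2 - b) * ndtr((t - e2) / s)


class TestCastShadow:
    def test_parallel_flats_full_overlap(self):
        ref = flat_patch()
        opp = flat_patch(z=2.0, flip=True)
        flags = cast_shadow(ref, opp, t_max=10.0)
        assert flags.all()

    def test_gap_beyond_t_max_excluded(self):
        ref = flat_patch()
        opp = flat_patch(z=2.0, flip=True)
        assert not cast_shadow(ref, opp, t_max=1.0).any()

    def test_lateral_shift_matches_brute_force_oracle(self):
        ref = flat_patch()
        opp = flat_patch(z=2.0, flip=True, shift=(5.0, 0.0))
        flags = cast_shadow(ref, opp, t_max=10.0)
        t = brute_force_first_hit(ref.vertices, ref.normals, opp.vertices, opp.faces)
        expect = (t > 0) & (t <= 10.0)
        assert np.array_equal(flags, expect)
        assert 0 < flags.sum() < ref.n_vertices

    def test_degenerate_normal_flagged_invalid_not_fatal(self):
        ref = flat_patch()
        ref.normals[3] = np.nan
        flags = cast_shadow(ref, flat_patch(z=2.0, flip=True), t_max=10.0)
        assert not flags[3]
        assert flags.sum() == ref.n_vertices - 1

    @pytest.mark.parametrize("t_small,t_big", [(1.5, 2.5), (2.5, 8.0)])
    def test_shadow_monotone_in_t_max(self, t_small, t_big):
        ref = flat_patch()
        opp = flat_patch(z=2.0, flip=True, shift=(3.0, 2.0))
        small = cast_shadow(ref, opp, t_small)
        big = cast_shadow(ref, opp, t_big)
        assert np.all(big[small])  # enlarging t_max never shrinks the set


class TestExtractProfile:
    def test_constant_volume(self):
        vol = VoxelVolume(np.full((20, 20, 20), 7.0), 0.5, np.zeros(3))
        p = extract_profile(vol, [5, 5, 5], [0, 0, 1], back=2.0, forward=3.0, step=0.1)
        assert np.allclose(p.intensities, 7.0)
        assert p.positions[0] == -2.0 and np.isclose(p.positions[-1], 3.0)

    def test_linear_gradient_sampled_linearly(self):
        data = np.fromfunction(lambda i, j, k: 3.0 * k, (10, 10, 30))
        vol = VoxelVolume(data, 0.5, np.zeros(3))
        p = extract_profile(vol, [2.5, 2.5, 7.0], [0, 0, 1], 3.0, 5.0, 0.25)
        expect = 3.0 * (7.0 + p.positions) / 0.5
        assert np.allclose(p.intensities, expect, atol=1e-9)

    def test_segment_exit_raises(self):
        vol = VoxelVolume(np.zeros((10, 10, 10)), 0.5, np.zeros(3))
        with pytest.raises(OutOfBoundsError):
            extract_profile(vol, [2, 2, 2], [0, 0, 1], back=1.0, forward=50.0, step=0.5)


class TestFitBlurModel:
    def test_noiseless_self_consistency(self):
        t = np.arange(0, 101) * 0.1
        y = two_edge(t, 0.0, 1000.0, 1000.0, 3.0, 5.0, 0.5)
        fit = fit_blur_model(Profile(t, y))
        assert fit.converged
        assert abs(fit.jsw - 2.0) < 0.01
        # identifiability: every generating parameter recovered
        assert abs(fit.b) < 1.0 and abs(fit.a1 - 1000) < 1.0 and abs(fit.a2 - 1000) < 1.0
        assert abs(fit.e1 - 3.0) < 0.01 and abs(fit.s - 0.5) < 0.01
        assert fit.rms_residual < 1e-6

    def test_subvoxel_gap_with_noise_fixed_nuisance(self):
        # 0.30 mm gap (below the 0.37 mm voxel) at s = 0.5, noise SD 20:
        # with background and PSF pinned (they are global image properties)
        # the median absolute error over 100 seeds stays within 0.10 mm
        t = np.arange(-40, 101) * 0.1
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(100):
            y = two_edge(t, 0.0, 1000.0, 1000.0, 0.0, 0.3, 0.5) + rng.normal(0, 20, len(t))
            fit = fit_blur_model(Profile(t, y), fix_b=0.0, fix_s=0.5)
            errs.append(abs(fit.jsw - 0.3) if fit.converged else np.inf)
        assert np.median(errs) <= 0.10

    def test_grid_search_oracle_agrees_at_fixed_nuisance(self):
        # dense 2-D grid search over (e1, e2) with nuisance parameters fixed
        # is the independent optimum; the fit must land on the same edges
        t = np.arange(-40, 101) * 0.1
        rng = np.random.default_rng(5)
        y = two_edge(t, 0.0, 1000.0, 1000.0, 0.0, 0.3, 0.5) + rng.normal(0, 20, len(t))
        e1g = np.arange(-0.5, 0.5, 0.01)
        e2g = np.arange(-0.3, 1.0, 0.01)
        best, best_sse = None, np.inf
        for e1 in e1g:
            for e2 in e2g[e2g >= e1]:
                sse = np.sum((two_edge(t, 0.0, 1000.0, 1000.0, e1, e2, 0.5) - y) ** 2)
                if sse < best_sse:
                    best, best_sse = (e1, e2), sse
        fit = fit_blur_model(Profile(t, y), fix_b=0.0, fix_s=0.5)
        assert fit.converged
        assert abs(fit.jsw - (best[1] - best[0])) < 0.02

    def test_no_opposing_edge_flagged(self):
        t = np.arange(-40, 101) * 0.1
        y = two_edge(t, 0.0, 1000.0, 0.0, 0.0, 5.0, 0.5)  # A2 == b: bone then nothing
        fit = fit_blur_model(Profile(t, y))
        assert not fit.converged
        assert fit.failure == "no opposing edge"

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            Profile(np.arange(5.0), np.zeros(5))  # too short
        with pytest.raises(ValueError):
            Profile(np.linspace(0, 1, 25)[::-1], np.zeros(25))  # decreasing


class TestMapJSW:
    def test_constant_gap_phantom_recovered(self, slab_phantom):
        vol = rasterize_ct(slab_phantom, spacing=0.37, psf_sigma=0.5, noise_sd=20.0, seed=2)
        patch = slab_phantom.patch("core")
        jm = map_jsw(vol, patch, slab_phantom.opposing)
        assert jm.field.mask.sum() > 0.9 * patch.n_vertices
        assert abs(patch_mean(jm.field, patch) - 2.0) < 0.10

    def test_map_invariant_under_common_rigid_motion(self):
        # posing the whole phantom (meshes + re-rasterized volume) must not
        # change the measured map beyond fit tolerance
        from jsmap.register import RigidTransform

        base = PhantomSpec(extent=8.0, mesh_resolution=1.0,
                           gap_field=GapField(kind="constant", value=2.2))
        posed = PhantomSpec(extent=8.0, mesh_resolution=1.0,
                            gap_field=GapField(kind="constant", value=2.2),
                            pose=RigidTransform.from_axis_angle([0.3, 1.0, 0.2], 10.0,
                                                                [2.0, -1.0, 3.0]))
        means = []
        for spec in (base, posed):
            ph = make_joint_phantom(spec)
            vol = rasterize_ct(ph, spacing=0.37, psf_sigma=0.5, noise_sd=0.0)
            jm = map_jsw(vol, ph.patch("p"), ph.opposing)
            means.append(patch_mean(jm.field, ph.patch("p")))
        assert abs(means[0] - means[1]) < 0.05

    def test_mostly_failed_fits_warn(self, slab_phantom):
        # an empty (background-only) volume makes every profile fail
        vol = VoxelVolume(np.zeros((80, 80, 60)), 0.4, np.array([-16.0, -16.0, -20.0]))
        patch = slab_phantom.patch("core")
        with pytest.warns(RuntimeWarning, match="fits failed"):
            jm = map_jsw(vol, patch, slab_phantom.opposing)
        assert jm.field.mask.sum() == 0


class TestRayDistanceOracle:
    def test_parallel_flats_exact(self):
        ref = flat_patch()
        patch = JointPatch(ref, np.arange(ref.n_vertices), "p")
        opp = flat_patch(z=2.0, flip=True)
        jm = ray_distance_oracle(patch, opp)
        assert np.allclose(jm.field.values[jm.field.mask], 2.0, atol=1e-12)

    def test_tilted_plane_distance_analytic(self):
        # opposing plane tilted 45 deg about y: ray-plane distance from a
        # point at height 0 along +z is gap + x (plane z = 2 + x)
        ref = flat_patch(extent=4.0, shift=(3.0, 0.0))  # x in [1, 5]: plane stays above
        patch = JointPatch(ref, np.arange(ref.n_vertices), "p")
        big = flat_patch(extent=40.0, spacing=2.0, flip=True)
        verts = big.vertices.copy()
        verts[:, 2] = 2.0 + verts[:, 0]
        opp = SurfaceMesh(verts, big.faces.copy())
        jm = ray_distance_oracle(patch, opp)
        expect = 2.0 + ref.vertices[:, 0]
        m = jm.field.mask
        assert m.all()
        assert np.allclose(jm.field.values[m], expect[m], atol=1e-9)

    def test_non_overlapping_fully_masked(self):
        ref = flat_patch()
        opp = flat_patch(z=2.0, flip=True, shift=(100.0, 0.0))
        jm = ray_distance_oracle(JointPatch(ref, np.arange(ref.n_vertices), "p"), opp)
        assert not jm.field.mask.any()
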