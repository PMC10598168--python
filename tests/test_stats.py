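"""Bland-Altman maps, paired t, landmark angles, permutation SPM and the
cohort table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from jsmap.stats import (
    bland_altman_map,
    cohort_summary,
    load_ankle_cohort,
    paired_t,
    sagittal_angle,
    spm_f_map,
    stack_fields,
)
from jsmap.surface import ScalarField


class TestBlandAltman:
    def test_identical_inputs_zero_bias_zero_loa(self):
        rng = np.random.default_rng(0)
        a = rng.normal(2.4, 0.3, (10, 50))
        out = bland_altman_map(a, a.copy())
        assert np.all(out.bias.values[out.bias.mask] == 0.0)
        assert np.all(out.loa.values[out.loa.mask] == 0.0)

    def test_uniform_offset(self):
        rng = np.random.default_rng(1)
        a = rng.normal(2.4, 0.3, (12, 40))
        out = bland_altman_map(a, a + 0.2)
        assert np.allclose(out.bias.values[out.bias.mask], 0.2, atol=1e-12)
        assert np.allclose(out.loa.values[out.loa.mask], 0.0, atol=1e-9)

    def test_sample_sd_uses_n_minus_1(self):
        a = np.zeros((3, 1))
        b = np.array([[1.0], [2.0], [4.0]])
        out = bland_altman_map(a, b)
        d = b[:, 0]
        assert np.isclose(out.loa.values[0], 1.96 * d.std(ddof=1))
        assert np.isclose(out.bias.values[0], d.mean())

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 100), c=st.floats(0.1, 10.0))
    def test_swap_antisymmetry_and_scaling(self, seed, c):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 15))
        b = a + rng.normal(size=(6, 15))
        ab = bland_altman_map(a, b)
        ba = bland_altman_map(b, a)
        assert np.allclose(ab.bias.values, -ba.bias.values, atol=1e-12)
        assert np.allclose(ab.loa.values, ba.loa.values, atol=1e-12)
        scaled = bland_altman_map(c * a, c * b)
        assert np.allclose(scaled.bias.values, c * ab.bias.values, atol=1e-9)
        assert np.allclose(scaled.loa.values, c * ab.loa.values, atol=1e-9)

    def test_vertices_with_fewer_than_two_pairs_masked(self):
        a = np.full((4, 3), 1.0)
        b = np.full((4, 3), 1.5)
        a[1:, 0] = np.nan  # vertex 0 valid in only one pair
        a[2:, 1] = np.nan  # vertex 1 valid in two pairs
        out = bland_altman_map(a, b)
        assert not out.bias.mask[0]
        assert out.bias.mask[1] and out.bias.mask[2]

    def test_subject_count_mismatch_names_counts(self):
        with pytest.raises(ValueError, match="5 vs 4"):
            bland_altman_map(np.zeros((5, 3)), np.zeros((4, 3)))


class TestPairedT:
    def test_known_example(self):
        out = paired_t([1.0, 2.0, 3.0])
        assert np.isclose(out.t, 3.4641, atol=1e-4)
        assert out.df == 2
        assert np.isclose(out.p, 0.0742, atol=1e-4)

    def test_symmetric_pair_gives_t_zero(self):
        out = paired_t([-1.0, 1.0])
        assert out.t == 0.0 and out.p == 1.0

    def test_all_zero_gives_p_one(self):
        out = paired_t([0.0, 0.0, 0.0])
        assert out.t == 0.0 and out.p == 1.0

    def test_zero_variance_nonzero_mean_p_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = paired_t([2.0, 2.0, 2.0])
        assert out.p == 0.0

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 1000), n=st.integers(3, 30))
    def test_matches_scipy_ttest_rel(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        ours = paired_t(y - x)
        ref = sps.ttest_rel(y, x)
        assert np.isclose(ours.t, ref.statistic, atol=1e-10)
        assert np.isclose(ours.p, ref.pvalue, atol=1e-10)


class TestSagittalAngle:
    def test_collinear_landmarks_180(self):
        assert np.isclose(sagittal_angle([0, 0, 10], [0, 0, 0], [0, 0, -5], [1, 0, 0]), 180.0)

    def test_right_angle(self):
        assert np.isclose(sagittal_angle([0, 0, 10], [0, 0, 0], [0, 5, 0], [1, 0, 0]), 90.0)

    def test_45_degrees(self):
        assert np.isclose(sagittal_angle([0, 1, 1], [0, 0, 0], [0, 1, 0], [1, 0, 0]), 45.0)

    def test_projection_onto_sagittal_plane(self):
        # out-of-plane x components must be discarded before measuring
        assert np.isclose(sagittal_angle([7, 0, 10], [0, 0, 0], [-4, 5, 0], [1, 0, 0]), 90.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            sagittal_angle([0, 0, 0], [0, 0, 0], [1, 1, 1])


class TestSPM:
    def _cohort(self, seed=0, n=23, n_vert=80):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 9.3, n)
        y = rng.normal(2.4, 0.1, (n, n_vert))
        return y, x

    def test_f_equals_t_squared_at_single_vertex(self):
        y, x = self._cohort()
        res = spm_f_map(y[:, :1], x, n_permutations=19, seed=1)
        slope_t = sps.linregress(x, y[:, 0])
        assert np.isclose(res.f.values[0], slope_t.rvalue**2 /
                          (1 - slope_t.rvalue**2) * (len(x) - 2), atol=1e-9)

    def test_p_corrected_bounds_and_monotone_in_f(self):
        y, x = self._cohort(3)
        res = spm_f_map(y, x, n_permutations=99, seed=2)
        p = res.p_corrected.values
        assert np.all(p >= 1.0 / 100.0 - 1e-12)
        assert np.all(p <= 1.0)
        order = np.argsort(res.f.values)
        assert np.all(np.diff(p[order]) <= 1e-12)  # higher F never raises p

    def test_constant_covariate_rejected(self):
        y, _ = self._cohort()
        with pytest.raises(ValueError):
            spm_f_map(y, np.ones(23), n_permutations=9)

    def test_constant_field_vertex_f_zero(self):
        y, x = self._cohort()
        y[:, 5] = 2.0
        res = spm_f_map(y, x, n_permutations=19, seed=0)
        assert res.f.values[5] == 0.0

    def test_deterministic_given_seed(self):
        y, x = self._cohort(7)
        a = spm_f_map(y, x, n_permutations=49, seed=11)
        b = spm_f_map(y, x, n_permutations=49, seed=11)
        assert np.array_equal(a.p_corrected.values, b.p_corrected.values)

    def test_constant_fields_no_significance(self):
        x = np.random.default_rng(0).normal(0, 9, 23)
        y = np.full((23, 40), 2.5)
        res = spm_f_map(y, x, n_permutations=99, seed=3)
        assert not res.significant.any()

    def test_null_parametric_p_uniform(self):
        # under the null the per-vertex parametric p-values are U(0, 1)
        rng = np.random.default_rng(42)
        x = rng.normal(0, 9.3, 23)
        y = rng.normal(2.4, 0.1, (23, 10_000))
        res = spm_f_map(y, x, n_permutations=9, seed=0)
        ks = sps.kstest(res.p_uncorrected, "uniform")
        assert ks.pvalue > 0.01

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 9.3, 23)
        y = rng.normal(2.4, 0.1, (23, 60))
        y[:, :10] += 0.1 * x[:, None]  # 0.1 mm per degree
        res = spm_f_map(y, x, n_permutations=199, seed=5)
        assert res.significant[:10].all()
        assert not res.significant[10:].any()


class TestCohortTable:
    def test_fixture_summary_matches_published_demographics(self):
        table = load_ankle_cohort()
        s = cohort_summary(table)
        assert s["n"] == 23
        assert np.isclose(round(s["interval_days"]["mean"], 1), 74.0)
        assert np.isclose(round(s["age_years"]["mean"], 1), 52.7)
        assert s["age_years"]["min"] == 23 and s["age_years"]["max"] == 74
        assert s["sex"] == {"Female": 16, "Male": 7}
        assert s["side"] == {"Left": 13, "Right": 10}

    def test_single_row_sd_not_available(self):
        table = load_ankle_cohort().iloc[:1]
        s = cohort_summary(table)
        assert np.isnan(s["age_years"]["sd"])
        assert s["age_years"]["mean"] == table.age_years.iloc[0]

    def test_missing_numeric_cell_names_row(self):
        table = load_ankle_cohort().copy()
        table.loc[4, "interval_days"] = np.nan
        with pytest.raises(ValueError, match="row 4"):
            cohort_summary(table)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary(load_ankle_cohort().iloc[:0])


class TestStackFields:
    def test_ragged_lengths_rejected(self):
        fields = [ScalarField(np.zeros(5)), ScalarField(np.zeros(4))]
        with pytest.raises(ValueError, match="subject 1"):
            stack_fields(fields)
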