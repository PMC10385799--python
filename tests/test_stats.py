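"""Unit and property tests for the statistical primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from singlebud.stats import (kde_density, mann_whitney_u, spearman,
                             spearman_matrix, tukey_upper_outliers)

from oracles import (mann_whitney_enumeration, mann_whitney_permutation,
                     spearman_midrank_oracle)

floats_list = st.lists(
    st.floats(-50, 50, allow_nan=False, allow_infinity=False),
    min_size=4, max_size=25)


class TestMannWhitney:
    def test_fully_separated_samples_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.method_detail == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = mann_whitney_u(x, x)
        assert res.method_detail == "approximate"  # ties force approximation
        assert res.p_value > 0.95

    def test_large_sample_routes_to_approximation(self):
        rng = np.random.default_rng(0)
        res = mann_whitney_u(rng.normal(size=10), rng.normal(size=71))
        assert res.method_detail == "approximate"
        res = mann_whitney_u(rng.normal(size=10), rng.normal(size=10))
        assert res.method_detail == "exact"

    def test_exact_mode_rejects_ties(self):
        with pytest.raises(ValueError):
            mann_whitney_u([1, 1, 2], [3, 4, 5], mode="exact")

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n_x,n_y", [(2, 3), (4, 4), (3, 6), (5, 5)])
    def test_exact_matches_enumeration(self, n_x, n_y):
        rng = np.random.default_rng(n_x * 10 + n_y)
        for _ in range(5):
            pooled = rng.permutation(np.arange(n_x + n_y, dtype=float))
            x, y = pooled[:n_x], pooled[n_x:]
            res = mann_whitney_u(x, y, mode="exact")
            u_oracle, p_oracle = mann_whitney_enumeration(x, y)
            assert res.statistic == pytest.approx(u_oracle)
            assert res.p_value == pytest.approx(p_oracle)

    def test_tied_data_approximation_near_permutation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.integers(0, 6, 18).astype(float)
            y = rng.integers(1, 7, 22).astype(float)
            res = mann_whitney_u(x, y, mode="normal_approx")
            p_perm = mann_whitney_permutation(x, y, 10_000, rng)
            assert abs(res.p_value - p_perm) < 0.02

    @given(x=floats_list, y=floats_list)
    def test_u_statistics_sum_to_nx_ny(self, x, y):
        u_x = mann_whitney_u(x, y).statistic
        u_y = mann_whitney_u(y, x).statistic
        assert u_x + u_y == pytest.approx(len(x) * len(y))


class TestSpearman:
    def test_monotone_sequences_have_rho_one(self):
        res = spearman([1, 5, 9, 12], [0.1, 0.2, 0.5, 0.9])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_single_transposition_worked_value(self):
        # d = (0,0,1,1): rho = 1 - 6*2/(4*15) = 0.8
        res = spearman([1, 2, 3, 4], [1, 2, 4, 3])
        assert res.statistic == pytest.approx(0.8)

    def test_tied_data_matches_midrank_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 8, n).astype(float)
            y = rng.integers(0, 8, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y).statistic == pytest.approx(
                spearman_midrank_oracle(x, y), abs=1e-12)

    def test_exact_permutation_p_close_to_approximation(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.5, 8.5]
        exact = spearman(x, y, p_mode="exact")
        approx = spearman(x, y)
        assert exact.method_detail == "exact"
        assert abs(exact.p_value - approx.p_value) < 0.15

    @given(x=st.lists(st.floats(0.01, 20, allow_nan=False), min_size=5,
                      max_size=15, unique=True),
           y=st.lists(st.floats(0.01, 20, allow_nan=False), min_size=5,
                      max_size=15, unique=True))
    def test_invariant_under_monotone_transforms(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        base = spearman(x, y).statistic
        assert spearman(np.exp(np.asarray(x) / 10), y).statistic == \
            pytest.approx(base, abs=1e-12)
        assert spearman(x, np.asarray(y) ** 3).statistic == \
            pytest.approx(base, abs=1e-12)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_matrix_route_agrees_with_pairwise(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(25, 5))
        data[:, 2] = np.round(data[:, 2])  # inject ties
        rho, p = spearman_matrix(data)
        for i in range(5):
            for j in range(i + 1, 5):
                res = spearman(data[:, i], data[:, j])
                assert rho[i, j] == pytest.approx(res.statistic, abs=1e-12)
                assert p[i, j] == pytest.approx(res.p_value, abs=1e-12)


class TestTukeyFences:
    def test_single_far_out_value_flagged(self):
        rule = tukey_upper_outliers([1, 2, 3, 4, 5, 6, 7, 8, 100], k=3)
        assert rule.q3 == pytest.approx(7.0)
        assert rule.iqr == pytest.approx(4.0)
        assert rule.flagged == (8,)

    def test_constant_sample_flags_nothing(self):
        rule = tukey_upper_outliers([5.0] * 6, k=3)
        assert rule.iqr == 0
        assert rule.flagged == ()

    def test_k_zero_flags_values_above_q3(self):
        x = np.arange(1.0, 9.0)
        rule = tukey_upper_outliers(x, k=0)
        assert set(rule.flagged) == set(np.nonzero(x > rule.q3)[0])

    def test_median_anchor_lowers_fence(self):
        x = [1.0, 2, 3, 4, 5, 6, 7, 8, 30]
        q3_rule = tukey_upper_outliers(x, k=1, anchor="q3")
        med_rule = tukey_upper_outliers(x, k=1, anchor="median")
        assert med_rule.upper_fence < q3_rule.upper_fence

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=5,
                    max_size=40))
    def test_raising_k_never_flags_more(self, x):
        flags = [set(tukey_upper_outliers(x, k=k).flagged)
                 for k in (0.0, 0.5, 1.5, 3.0, 6.0)]
        for tighter, looser in zip(flags[1:], flags):
            assert tighter <= looser


class TestKde:
    def test_mode_of_standard_normal_samples_near_zero(self):
        # the KDE mode of a single n=500 draw scatters ~0.2 around 0;
        # check each draw loosely and the average tightly
        modes = []
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=500)
            grid, dens = kde_density(x)
            modes.append(grid[np.argmax(dens)])
            assert abs(modes[-1]) < 0.5
        assert abs(np.mean(modes)) < 0.2

    def test_density_integrates_to_one(self):
        x = np.random.default_rng(1).exponential(size=200)
        grid, dens = kde_density(x)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_translation_equivariance(self):
        x = np.random.default_rng(2).normal(size=80)
        g0, d0 = kde_density(x)
        g1, d1 = kde_density(x + 7.5)
        np.testing.assert_allclose(g1, g0 + 7.5, atol=1e-9)
        np.testing.assert_allclose(d1, d0, atol=1e-12)

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError):
            kde_density([2.0, 2.0, 2.0])
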