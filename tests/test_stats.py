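"""Unit and property tests for the reproducibility-optimized statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rotspeaks import (
    AlphaParams,
    GroupDesign,
    RotsConfig,
    bootstrap_pair,
    null_pair,
    optimize,
    permutation_fdr,
    reproducibility,
    t_type_statistic,
    z_score,
)
from rotspeaks.stats import FeatureStat, _ranks


def make_stat(ranks):
    ranks = np.asarray(ranks)
    n = ranks.size
    return FeatureStat(
        feature_ids=np.array([f"f{i}" for i in range(n)], dtype=object),
        d=(n - ranks).astype(float),
        ranks=ranks,
        mean_diff=np.zeros(n),
        se=np.ones(n),
    )


class TestTTypeStatistic:
    def test_equal_means_give_zero(self, matrix_factory, design_3v3):
        data = matrix_factory(np.full((4, 6), 5.0))
        stat = t_type_statistic(data, design_3v3, AlphaParams(1, 1))
        assert np.all(stat.d == 0)

    def test_alpha_1_0_is_absolute_mean_difference(
        self, matrix_factory, design_3v3
    ):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2, 10, (30, 6))
        data = matrix_factory(vals)
        stat = t_type_statistic(data, design_3v3, AlphaParams(1, 0))
        expected = np.abs(vals[:, :3].mean(1) - vals[:, 3:].mean(1))
        np.testing.assert_allclose(stat.d, expected)

    def test_alpha_0_1_equals_textbook_t(self, matrix_factory, design_3v3):
        """d at alpha=(0,1) is the pooled-variance two-sample |t|, checked
        against a direct textbook-formula computation."""
        x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        data = matrix_factory(x)
        stat = t_type_statistic(data, design_3v3, AlphaParams(0, 1))
        xi, xj = x[0, :3], x[0, 3:]
        sp2 = (2 * xi.var(ddof=1) + 2 * xj.var(ddof=1)) / 4
        t_oracle = abs(xi.mean() - xj.mean()) / np.sqrt(sp2 * (2 / 3))
        assert stat.d[0] == pytest.approx(t_oracle)

    def test_t_ordering_matches_scipy(self, matrix_factory, design_3v3):
        """Feature ordering at alpha=(0,1) equals ordering by |t| from the
        independent equal-variance t implementation, 500 features."""
        rng = np.random.default_rng(42)
        vals = rng.gamma(3, 20, (500, 6))
        data = matrix_factory(vals)
        stat = t_type_statistic(data, design_3v3, AlphaParams(0, 1))
        t = sps.ttest_ind(
            vals[:, :3], vals[:, 3:], axis=1, equal_var=True
        ).statistic
        np.testing.assert_allclose(stat.d, np.abs(t))
        assert np.array_equal(
            np.argsort(-stat.d, kind="stable"),
            np.argsort(-np.abs(t), kind="stable"),
        )

    def test_zero_denominator_names_feature(self, matrix_factory, design_3v3):
        vals = np.ones((3, 6))
        vals[1] = [1, 2, 3, 4, 5, 6]
        data = matrix_factory(vals)
        with pytest.raises(ValueError, match="f0"):
            t_type_statistic(data, design_3v3, AlphaParams(0, 1))

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            GroupDesign({"a": "x", "b": "y", "c": "y"})

    def test_shift_invariance_alpha2_zero(self, matrix_factory, design_3v3):
        rng = np.random.default_rng(1)
        vals = rng.gamma(2, 10, (20, 6))
        d0 = t_type_statistic(
            matrix_factory(vals), design_3v3, AlphaParams(1, 0)
        ).d
        d1 = t_type_statistic(
            matrix_factory(vals + 7.0), design_3v3, AlphaParams(1, 0)
        ).d
        np.testing.assert_allclose(d0, d1)

    def test_scale_equivariance(self, matrix_factory, design_3v3):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2, 10, (20, 6))
        c = 3.5
        d_fc = t_type_statistic(
            matrix_factory(vals), design_3v3, AlphaParams(1, 0)
        ).d
        d_fc_scaled = t_type_statistic(
            matrix_factory(c * vals), design_3v3, AlphaParams(1, 0)
        ).d
        np.testing.assert_allclose(d_fc_scaled, c * d_fc)
        d_t = t_type_statistic(
            matrix_factory(vals), design_3v3, AlphaParams(0, 1)
        ).d
        d_t_scaled = t_type_statistic(
            matrix_factory(c * vals), design_3v3, AlphaParams(0, 1)
        ).d
        np.testing.assert_allclose(d_t_scaled, d_t)

    def test_ranks_are_permutation(self, matrix_factory, design_3v3):
        rng = np.random.default_rng(3)
        data = matrix_factory(rng.poisson(30, (50, 6)).astype(float))
        stat = t_type_statistic(data, design_3v3, AlphaParams(1, 1))
        assert sorted(stat.ranks) == list(range(1, 51))
        # d sorted descending along rank order
        order = np.argsort(stat.ranks)
        assert np.all(np.diff(stat.d[order]) <= 0)


class TestResampling:
    def test_bootstrap_constant_condition(self, matrix_factory, design_3v3):
        vals = np.tile([[1.0], [2.0]], (1, 6))
        data = matrix_factory(vals)
        m1, m2 = bootstrap_pair(data, design_3v3, seed=0)
        np.testing.assert_array_equal(m1.values, vals)
        np.testing.assert_array_equal(m2.values, vals)

    def test_bootstrap_deterministic(self, matrix_factory, design_3v3):
        rng = np.random.default_rng(4)
        data = matrix_factory(rng.poisson(20, (10, 6)).astype(float))
        p1 = bootstrap_pair(data, design_3v3, seed=11)
        p2 = bootstrap_pair(data, design_3v3, seed=11)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_bootstrap_inclusion_frequency(self, matrix_factory):
        """Each of 4 samples appears in a bootstrap draw with probability
        1 - (3/4)^4; empirical frequency over 2000 draws within 3 SE."""
        design = GroupDesign(
            {"a1": "x", "a2": "x", "a3": "x", "a4": "x",
             "b1": "y", "b2": "y", "b3": "y", "b4": "y"}
        )
        vals = np.arange(8, dtype=float)[None, :]  # distinct marker values
        data = type(matrix_factory(np.ones((1, 8))))(
            values=vals,
            feature_ids=np.array(["f0"], dtype=object),
            sample_ids=np.array(
                ["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"], dtype=object
            ),
        )
        n_draws = 2000
        included = np.zeros(8)
        for s in range(n_draws // 2):
            m1, m2 = bootstrap_pair(data, design, seed=s)
            for m in (m1, m2):
                present = set(m.values[0].astype(int))
                for v in present:
                    included[v] += 1
        p = 1 - (3 / 4) ** 4
        se = np.sqrt(p * (1 - p) / n_draws)
        np.testing.assert_allclose(
            included / n_draws, p, atol=3 * se + 1e-12
        )

    def test_null_pair_deterministic_and_sizes(
        self, matrix_factory, design_3v3
    ):
        rng = np.random.default_rng(5)
        data = matrix_factory(rng.poisson(20, (10, 6)).astype(float))
        p1 = null_pair(data, design_3v3, seed=7)
        p2 = null_pair(data, design_3v3, seed=7)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.values, b.values)
            assert a.values.shape == (10, 6)  # 3+3 stays 3+3

    def test_null_destroys_signal(self, matrix_factory, design_5v5):
        """Mean d over null pairs is far below mean d over bootstrap pairs
        when the groups differ strongly: permuted groups are bimodal,
        which shrinks the mean difference and inflates the within-group
        variance."""
        rng = np.random.default_rng(6)
        vals = rng.normal(100, 5, (50, 10))
        vals[:, 5:] += 60  # strong group shift on every feature
        vals = np.abs(vals)
        data = matrix_factory(vals)
        alpha = AlphaParams(1, 1)

        def mean_d(pair_fn):
            total = 0.0
            for s in range(30):
                for member in pair_fn(data, design_5v5, seed=s):
                    half = member.n_samples // 2
                    ids = list(member.sample_ids)
                    dsg = GroupDesign(
                        {i: ("g1" if p < half else "g2")
                         for p, i in enumerate(ids)}
                    )
                    total += t_type_statistic(member, dsg, alpha).d.mean()
            return total / 60

        assert mean_d(null_pair) < 0.25 * mean_d(bootstrap_pair)


class TestReproducibility:
    def test_identical_rankings(self):
        s = make_stat([3, 1, 2, 4, 5])
        for k in (1, 3, 5):
            assert reproducibility(s, s, k) == 1.0

    def test_disjoint_top_k(self):
        a = make_stat([1, 2, 3, 4, 5, 6])
        b = make_stat([4, 5, 6, 1, 2, 3])
        assert reproducibility(a, b, 3) == 0.0

    def test_partial_overlap(self):
        # top-5 sets {0..4} and {0,1,5,6,7}: share exactly 2
        a = make_stat([1, 2, 3, 4, 5, 6, 7, 8])
        b = make_stat([1, 2, 6, 7, 8, 3, 4, 5])
        assert reproducibility(a, b, 5) == pytest.approx(0.4)

    def test_mismatched_features_rejected(self):
        a = make_stat([1, 2, 3])
        b = make_stat([1, 2, 3])
        b.feature_ids = np.array(["x", "y", "z"], dtype=object)
        with pytest.raises(ValueError, match="feature sets"):
            reproducibility(a, b, 2)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(data=st.data(), n=st.integers(2, 40))
    def test_bounds_and_identity_property(self, data, n):
        """For arbitrary rankings: R_k stays in [0, 1], equals 1 for a
        ranking against itself, and is symmetric in its arguments."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        a = make_stat(rng.permutation(n) + 1)
        b = make_stat(rng.permutation(n) + 1)
        k = data.draw(st.integers(1, n))
        r = reproducibility(a, b, k)
        assert 0.0 <= r <= 1.0
        assert reproducibility(a, a, k) == 1.0
        assert reproducibility(b, a, k) == r


class TestZScore:
    def test_equal_means_zero(self):
        assert z_score([0.5, 0.7, 0.9], [0.9, 0.7, 0.5]) == 0.0

    def test_direct_arithmetic_oracle(self):
        r_boot = np.array([0.8, 0.9, 1.0])
        r_null = np.array([0.1, 0.2, 0.3])
        expected = (r_boot.mean() - r_null.mean()) / r_boot.std(ddof=1)
        assert z_score(r_boot, r_null) == pytest.approx(expected)

    def test_constant_equal_vectors(self):
        assert z_score([0.5] * 4, [0.5] * 4) == 0.0

    def test_zero_sd_unequal_means_is_inf(self):
        assert z_score([1.0, 1.0], [0.0, 0.0]) == np.inf


class TestOptimize:
    def test_single_cell_grid_reduces_to_statistic(
        self, matrix_factory, design_3v3
    ):
        rng = np.random.default_rng(9)
        data = matrix_factory(rng.poisson(40, (60, 6)).astype(float))
        alpha = AlphaParams(0.5, 1)
        cfg = RotsConfig(b=20, k_grid=[10], alpha_grid=[alpha],
                         n_perm=20, seed=2)
        res = optimize(data, design_3v3, cfg)
        ref = t_type_statistic(data, design_3v3, alpha)
        np.testing.assert_array_equal(res.stat.d, ref.d)
        assert res.alpha == alpha and res.k == 10

    def test_null_data_z_near_zero(self, matrix_factory, design_3v3):
        """Duplicated columns across groups: no real signal, so the
        optimized Z stays small."""
        rng = np.random.default_rng(10)
        base = rng.poisson(50, (200, 3)).astype(float)
        vals = np.hstack([base, base])  # two identical conditions
        zs = []
        for seed in range(3):
            cfg = RotsConfig(b=60, k_grid=[20, 50], n_perm=20, seed=seed)
            zs.append(optimize(matrix_factory(vals), design_3v3, cfg).z)
        assert all(abs(z) < 3 for z in zs)

    def test_spiked_features_recovered(self, matrix_factory, design_3v3):
        """50 features shifted by 5 SD land almost entirely in the top 50."""
        rng = np.random.default_rng(11)
        vals = rng.normal(100, 10, (400, 6))
        vals[:50, 3:] += 50  # 5 SD shift
        vals = np.abs(vals)
        cfg = RotsConfig(b=100, k_grid=[25, 50, 100], n_perm=20, seed=0)
        res = optimize(matrix_factory(vals), design_3v3, cfg)
        top50 = set(res.stat.top(50))
        spiked = {f"f{i}" for i in range(50)}
        assert len(top50 & spiked) >= 45

    def test_deterministic_given_seed(self, matrix_factory, design_3v3):
        rng = np.random.default_rng(12)
        data = matrix_factory(rng.poisson(30, (80, 6)).astype(float))
        cfg = RotsConfig(b=30, n_perm=30, seed=5)
        r1 = optimize(data, design_3v3, cfg)
        r2 = optimize(data, design_3v3, cfg)
        assert r1.alpha == r2.alpha and r1.k == r2.k and r1.z == r2.z
        np.testing.assert_array_equal(r1.fdr, r2.fdr)
        np.testing.assert_array_equal(r1.pvalue, r2.pvalue)


class TestPermutationFdr:
    def test_counting_oracle(self):
        """FDR from one permutation matches brute-force enumeration over
        all features: observed [3, 2, 1] against null [2.5, 0.5, 0.1]."""
        from rotspeaks.stats import fdr_from_null

        d_obs = np.array([3.0, 2.0, 1.0])
        null = [np.array([2.5, 0.5, 0.1])]
        pvalue, fdr = fdr_from_null(d_obs, null)
        # brute force: raw FDR(g) = #{null >= d_g} / #{obs >= d_g}, capped,
        # then running max down the (already sorted) ranking
        raw = np.array(
            [
                np.sum(null[0] >= d) / np.sum(d_obs >= d)
                for d in d_obs
            ]
        )
        expected_fdr = np.maximum.accumulate(np.minimum(raw, 1.0))
        np.testing.assert_allclose(fdr, expected_fdr)
        expected_p = np.array(
            [(1 + np.sum(null[0] >= d)) / (1 + 1 * 3) for d in d_obs]
        )
        np.testing.assert_allclose(pvalue, expected_p)

    def test_multi_permutation_oracle(self):
        """Averaging over several permutations equals direct enumeration."""
        from rotspeaks.stats import fdr_from_null

        rng = np.random.default_rng(99)
        d_obs = rng.exponential(1.0, 20)
        nulls = [rng.exponential(1.0, 20) for _ in range(7)]
        pvalue, fdr = fdr_from_null(d_obs, nulls)
        raw = np.array(
            [
                np.mean([np.sum(nl >= d) for nl in nulls]) / np.sum(d_obs >= d)
                for d in d_obs
            ]
        )
        capped = np.minimum(raw, 1.0)
        order = np.lexsort((np.arange(20), -d_obs))
        expected = capped.copy()
        expected[order] = np.maximum.accumulate(capped[order])
        np.testing.assert_allclose(fdr, expected)
        total = np.array([np.sum([np.sum(nl >= d) for nl in nulls])
                          for d in d_obs])
        np.testing.assert_allclose(pvalue, (1 + total) / (1 + 7 * 20))

    def test_dominant_feature_gets_zero_fdr(self):
        """A feature whose observed d exceeds every null statistic in
        every permutation has FDR exactly 0 (empty null exceedance)."""
        from rotspeaks.stats import fdr_from_null

        d_obs = np.array([50.0, 1.0, 0.5])
        nulls = [np.array([2.0, 0.3, 0.1]), np.array([1.5, 0.8, 0.2])]
        pvalue, fdr = fdr_from_null(d_obs, nulls)
        assert fdr[0] == 0.0
        assert pvalue[0] == pytest.approx(1 / (1 + 2 * 3))

    def test_strong_feature_ranks_most_significant(
        self, matrix_factory, design_3v3
    ):
        """End to end, an overwhelming signal gets the smallest FDR and
        p-value of the matrix."""
        rng = np.random.default_rng(13)
        vals = np.abs(rng.normal(50, 2, (40, 6)))
        vals[0, :3] += 1000
        data = matrix_factory(vals)
        cfg = RotsConfig(b=20, n_perm=50, seed=1)
        fdr, pvalue = permutation_fdr(
            data, design_3v3, AlphaParams(1, 0), cfg
        )
        assert fdr[0] == fdr.min()
        assert pvalue[0] == pvalue.min()

    def test_fdr_monotone_along_ranking(self, matrix_factory, design_3v3):
        rng = np.random.default_rng(14)
        data = matrix_factory(rng.poisson(30, (100, 6)).astype(float))
        cfg = RotsConfig(b=20, n_perm=40, seed=3)
        alpha = AlphaParams(1, 1)
        fdr, _ = permutation_fdr(data, design_3v3, alpha, cfg)
        stat = t_type_statistic(data, design_3v3, alpha)
        order = np.argsort(stat.ranks)
        assert np.all(np.diff(fdr[order]) >= 0)
        assert np.all((fdr >= 0) & (fdr <= 1))

    def test_too_few_permutations_rejected(
        self, matrix_factory, design_3v3
    ):
        data = matrix_factory(np.ones((5, 6)) + np.arange(6))
        cfg = RotsConfig(b=20, n_perm=5, seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_fdr(data, design_3v3, AlphaParams(1, 0), cfg)
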