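"""AUC summaries, permutation inference, FDR, hubs and clinical correlation."""

import numpy as np
import pytest
from scipy import stats

from fcnet.graph_metrics import modularity_q
from fcnet.group_inference import (
    auc,
    clinical_correlation,
    count_modules_per_subject,
    fdr_correct,
    hub_sign_test,
    mean_group_network,
    per_threshold_ttest,
    permutation_test,
    residualize,
)
from fcnet.net_build import SparsityGrid, ZConnectivity, binarize_at_sparsity

import oracles
from conftest import complete_graph


class TestAuc:
    def test_constant_curve_on_default_grid(self, default_grid):
        c = 3.7
        assert auc(np.full(24, c), default_grid) == pytest.approx(0.23 * c)

    def test_hand_computed_trapezoid(self):
        grid = SparsityGrid(0.1, 0.3, 0.1)
        # (0.1+0.2)/2*0.1 + (0.2+0.3)/2*0.1 = 0.04
        assert auc(np.array([0.1, 0.2, 0.3]), grid) == pytest.approx(0.04)

    def test_linearity(self, rng, default_grid):
        y = rng.standard_normal(24)
        z = rng.standard_normal(24)
        lhs = auc(2.5 * y - 1.3 * z, default_grid)
        rhs = 2.5 * auc(y, default_grid) - 1.3 * auc(z, default_grid)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_length_mismatch_errors(self, default_grid):
        with pytest.raises(ValueError, match="length"):
            auc(np.ones(10), default_grid)


class TestResidualize:
    def test_uncorrelated_covariates_just_demean(self, rng):
        n = 40
        age = rng.uniform(40, 70, n)
        sex = np.array(["M", "F"] * (n // 2))
        vals = rng.standard_normal(n)
        # orthogonalize values against covariates to build the trivial case
        x = np.column_stack([np.ones(n), age, sex == "M"]).astype(float)
        proj = x @ np.linalg.lstsq(x, vals, rcond=None)[0]
        clean = vals - proj + 5.0  # constant offset only
        np.testing.assert_allclose(
            residualize(clean, age, sex), clean - clean.mean(), atol=1e-10
        )

    def test_perfect_covariate_fit_gives_zero(self, rng):
        age = rng.uniform(40, 70, 30)
        sex = np.array(["M"] * 15 + ["F"] * 15)
        np.testing.assert_allclose(residualize(2 * age, age, sex), 0.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        n = 25
        age = rng.uniform(30, 80, n)
        sex = (rng.random(n) > 0.5).astype(float)
        vals = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), age, sex])
        beta = np.linalg.inv(x.T @ x) @ x.T @ vals
        np.testing.assert_allclose(residualize(vals, age, sex), vals - x @ beta, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, rng):
        n = 30
        age = rng.uniform(30, 80, n)
        sex = (rng.random(n) > 0.4).astype(float)
        vals = 0.3 * age + sex + rng.standard_normal(n)
        res = residualize(vals, age, sex)
        for cov in (np.ones(n), age, sex):
            assert abs(res @ cov) <= 1e-8 * np.linalg.norm(res) * np.linalg.norm(cov) + 1e-9

    def test_collinear_covariate_named(self, rng):
        age = np.full(20, 50.0)  # constant age collides with intercept
        sex = (rng.random(20) > 0.5).astype(float)
        with pytest.raises(ValueError, match="age"):
            residualize(rng.standard_normal(20), age, sex)


class TestPermutationTest:
    def test_identical_constant_groups_give_p_one(self):
        a = np.full(10, 2.0)
        b = np.full(12, 2.0)
        _, p = permutation_test(a, b, n_perm=500, seed=0)
        assert p == 1.0

    def test_large_offset_detected(self, rng):
        a = rng.standard_normal(15) + 10.0
        b = rng.standard_normal(15)
        diff, p = permutation_test(a, b, n_perm=2000, seed=1)
        assert diff == pytest.approx(10.0, abs=1.5)
        assert p <= 0.001

    def test_p_never_zero_and_valid_range(self, rng):
        a = rng.standard_normal(8)
        b = rng.standard_normal(8)
        _, p = permutation_test(a, b, n_perm=99, seed=2)
        assert 0 < p <= 1

    def test_null_calibration_on_gaussian_groups(self):
        """Under H0 the rejection rate at alpha=0.05 must sit near 0.05."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            a = rng.standard_normal(14)
            b = rng.standard_normal(16)
            _, p = permutation_test(a, b, n_perm=400, seed=int(rng.integers(2**31)))
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestPerThresholdTtest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            per_threshold_ttest(np.full(5, 1.0), np.full(5, 1.0))
        t, p = per_threshold_ttest(a, a)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_from_summary_stats(self):
        """Groups rebuilt to hit mean/SD 3 (0.64, n=30) vs 2.88 (0.9, n=26)
        must give the pooled t = 0.581 the textbook formula yields."""

        def synth(mean, sd, n, seed):
            x = np.random.default_rng(seed).standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            return x * sd + mean

        a = synth(3.0, 0.64, 30, 0)
        b = synth(2.88, 0.9, 26, 1)
        t, _ = per_threshold_ttest(a, b)
        assert t == pytest.approx(0.5806, abs=1e-3)

    def test_matches_textbook_formula_on_random_groups(self, rng):
        a = rng.standard_normal(12) * 2 + 1
        b = rng.standard_normal(17) * 2
        t, p = per_threshold_ttest(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), na + nb - 2), abs=1e-10)


class TestFdr:
    def test_all_tiny_all_rejected(self):
        assert fdr_correct(np.full(20, 0.001), 0.05).all()

    def test_all_large_none_rejected(self):
        assert not fdr_correct(np.full(20, 0.9), 0.05).any()

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(3, 40)) ** 2
            np.testing.assert_array_equal(
                fdr_correct(p, 0.05), oracles.bh_flags_exhaustive(p, 0.05)
            )

    def test_flags_invariant_under_reordering(self, rng):
        p = rng.uniform(0, 0.2, 15)
        perm = rng.permutation(15)
        np.testing.assert_array_equal(fdr_correct(p, 0.05)[perm], fdr_correct(p[perm], 0.05))

    def test_flags_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(0, 1, 12))
        flags = fdr_correct(p, 0.1)
        # once a sorted p is not rejected, no larger p may be rejected
        assert all(flags[i] or not flags[i + 1] for i in range(11))


class TestHubSignTest:
    def test_always_exceeding_region_is_hub(self, default_grid):
        n_levels, n_regions = 24, 30
        curves = np.abs(np.random.default_rng(0).standard_normal((n_levels, n_regions)))
        curves[:, 3] = curves.max() * 10  # region 3 dominates every level
        table = hub_sign_test(curves, default_grid, alpha=0.002)
        row = table.iloc[3]
        assert row["n_exceed"] == 24
        assert row["p_sign"] == pytest.approx(0.5**24, rel=1e-9)
        assert bool(row["is_hub"])

    def test_never_exceeding_region_not_hub(self, default_grid):
        curves = np.ones((24, 10))
        curves[:, 0] = 0.0
        table = hub_sign_test(curves, default_grid, alpha=0.002)
        assert table.iloc[0]["p_sign"] == pytest.approx(1.0)
        assert not bool(table.iloc[0]["is_hub"])

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            hub_sign_test(np.ones((1, 5)), SparsityGrid(0.2, 0.2, 0.1))


class TestMeanGroupNetwork:
    def test_single_subject_identity(self, random_z):
        conn = random_z(8)
        out = mean_group_network([conn])
        np.testing.assert_array_equal(out.z, conn.z)

    def test_opposite_matrices_cancel(self, random_z):
        conn = random_z(8)
        neg = ZConnectivity(z=-conn.z, region_labels=conn.region_labels)
        np.testing.assert_allclose(mean_group_network([conn, neg]).z, 0.0)

    def test_equals_elementwise_mean(self, random_z):
        conns = [random_z(6) for _ in range(5)]
        out = mean_group_network(conns)
        np.testing.assert_allclose(out.z, np.mean([c.z for c in conns], axis=0))

    def test_region_mismatch_errors(self, random_z):
        a, b = random_z(6), random_z(6)
        b.region_labels = [f"X{i}" for i in range(6)]
        with pytest.raises(ValueError, match="mismatch"):
            mean_group_network([a, b])


class TestClinicalCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.arange(10, dtype=float)
        assoc = clinical_correlation(x, -x)
        assert assoc.r == pytest.approx(-1.0)

    def test_null_scores_give_uniform_p(self):
        """Independent scores at n=26: |r| stays small on average and the
        p-value distribution is roughly uniform over replicates."""
        rng = np.random.default_rng(5)
        rs, ps = [], []
        for _ in range(300):
            a = rng.standard_normal(26)
            s = rng.standard_normal(26)
            assoc = clinical_correlation(a, s)
            rs.append(assoc.r)
            ps.append(assoc.p)
        assert abs(np.mean(rs)) < 0.05
        assert np.mean(np.array(ps) < 0.05) < 0.1
        # uniformity: KS distance from U(0,1) should be small at this n
        assert stats.kstest(ps, "uniform").statistic < 0.08

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            clinical_correlation(np.ones(10), np.arange(10.0))


class TestModuleCounts:
    def test_identical_graphs_surface_degenerate_ttest(self, net_factory):
        adj = np.zeros((8, 8), dtype=np.uint8)
        adj[:4, :4] = complete_graph(4)
        adj[4:, 4:] = complete_graph(4)
        adj[0, 4] = adj[4, 0] = 1
        nets = [net_factory(adj) for _ in range(4)]
        with pytest.raises(ValueError):
            count_modules_per_subject(nets, nets)

    def test_disconnected_components_lower_bound(self, net_factory):
        from fcnet.graph_metrics import newman_partition

        adj = np.zeros((9, 9), dtype=np.uint8)
        for s in (0, 3, 6):
            adj[s : s + 3, s : s + 3] = complete_graph(3)
        part = newman_partition(net_factory(adj))
        assert part.n_modules >= 3

    def test_planted_module_count_difference_recovered(self, rng, random_z):
        """Stacks of block matrices with 2 vs 3 planted modules must yield
        module counts differing in the planted direction."""
        from fcnet.graph_metrics import newman_partition

        def block_conn(sizes, seed):
            n = sum(sizes)
            g = np.random.default_rng(seed)
            z = g.normal(0.05, 0.02, (n, n))
            start = 0
            for size in sizes:
                z[start : start + size, start : start + size] = g.normal(
                    0.6, 0.05, (size, size)
                )
                start += size
            z = (z + z.T) / 2
            np.fill_diagonal(z, 0)
            return ZConnectivity(z=z)

        counts2 = [
            newman_partition(binarize_at_sparsity(block_conn([6, 6], s), 0.3)).n_modules
            for s in range(6)
        ]
        counts3 = [
            newman_partition(binarize_at_sparsity(block_conn([4, 4, 4], s + 50), 0.3)).n_modules
            for s in range(6)
        ]
        assert np.mean(counts3) > np.mean(counts2)
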