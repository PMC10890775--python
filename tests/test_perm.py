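import numpy as np
import pytest
from scipy import stats

from isoqtl import assoc, perm
from isoqtl.perm import (
    BetaNullFit,
    beta_adjust,
    direct_perm_pvalue,
    fit_beta_mle,
    gene_rng,
    perm_pass_aggregated,
    perm_pass_grouped,
    perm_pass_multivariate,
    perm_pass_single,
    qtltools_iso_aggregate,
    storey_qvalue,
    call_egenes,
)
from isoqtl.simulate import simulate_genotypes


class TestDirectPerm:
    @pytest.mark.parametrize("r,R,expect", [
        (0, 100, 1 / 101), (100, 100, 1.0), (4, 999, 0.005),
    ])
    def test_values(self, r, R, expect):
        assert direct_perm_pvalue(r, R) == pytest.approx(expect)

    def test_r_exceeding_R_rejected(self):
        with pytest.raises(ValueError):
            direct_perm_pvalue(5, 4)


class TestBetaMle:
    def test_uniform_recovers_1_1(self, rng):
        fit = fit_beta_mle(rng.uniform(size=10_000))
        assert abs(fit.a - 1.0) < 0.05
        assert abs(fit.b - 1.0) < 0.05

    def test_beta_half_three_recovered(self, rng):
        fit = fit_beta_mle(rng.beta(0.5, 3.0, size=10_000))
        assert fit.a == pytest.approx(0.5, rel=0.1)
        assert fit.b == pytest.approx(3.0, rel=0.1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_beta_mle(np.full(100, 0.42))

    def test_matches_scipy_mle(self, rng):
        data = rng.beta(0.8, 12.0, size=500)
        fit = fit_beta_mle(data)
        a_ref, b_ref, *_ = stats.beta.fit(data, floc=0, fscale=1)
        assert fit.a == pytest.approx(a_ref, rel=1e-3)
        assert fit.b == pytest.approx(b_ref, rel=1e-3)


class TestBetaAdjust:
    def test_uniform_fit_is_identity(self):
        fit = BetaNullFit(1.0, 1.0, 100, np.linspace(0.01, 0.99, 100))
        for p in (0.01, 0.3, 1.0):
            assert beta_adjust(p, fit) == pytest.approx(p)

    def test_monotone(self, rng):
        fit = fit_beta_mle(rng.beta(0.9, 40, size=200))
        grid = np.linspace(1e-6, 1, 50)
        out = beta_adjust(grid, fit)
        assert (np.diff(out) >= 0).all()

    def test_agrees_with_direct_within_2x(self):
        """On simulated nulls the Beta tail approximation tracks the direct
        (r+1)/(R+1) estimate within a factor of two where the direct
        estimate is informative (both estimates are noisy at the low end,
        so the bound is asserted in bulk)."""
        rng = np.random.default_rng(77)
        within = []
        for g in range(60):
            gm = simulate_genotypes(50, 20, rng)
            y = rng.standard_normal(50)
            res = perm_pass_single(f"g{g}", y, gm.dosages, R=300, rng=rng)
            if res.p_direct >= 0.01:
                within.append(
                    res.p_direct / 2 <= res.p_adjusted <= 2 * res.p_direct)
        assert len(within) > 30
        assert np.mean(within) >= 0.9


class TestSinglePass:
    def test_single_variant_null_minima_are_perm_pvalues(self, rng):
        """With s=1 the adjusted p approximates the nominal p itself."""
        devs = []
        for g in range(40):
            x = rng.integers(0, 3, size=60).astype(float)
            y = rng.standard_normal(60)
            res = perm_pass_single(f"g{g}", y, x[:, None], R=500, rng=rng)
            if 0.2 < res.p_nominal < 0.8:
                devs.append(abs(res.p_adjusted - res.p_nominal) / res.p_nominal)
        assert np.median(devs) < 0.2

    def test_duplicate_variant_column_no_change(self, rng):
        x = rng.integers(0, 3, size=40).astype(float)
        X = np.column_stack([x, rng.integers(0, 3, size=40)]).astype(float)
        Xdup = np.column_stack([X, X[:, 0]])
        y = rng.standard_normal(40)
        a = perm_pass_single("g", y, X, R=100, rng=gene_rng(1, "g"))
        b = perm_pass_single("g", y, Xdup, R=100, rng=gene_rng(1, "g"))
        assert a.p_nominal == b.p_nominal

    def test_no_cis_snps_flag(self, rng):
        res = perm_pass_single("g", rng.normal(size=20), np.empty((20, 0)),
                               R=100, rng=rng)
        assert res.flag == "no_cis_snps"
        assert res.p_adjusted == 1.0

    def test_null_calibration(self, rng):
        ps = []
        for g in range(200):
            gm = simulate_genotypes(60, 25, rng)
            res = perm_pass_single(f"g{g}", rng.standard_normal(60),
                                   gm.dosages, R=200, rng=rng)
            ps.append(res.p_adjusted)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestGroupedPass:
    def test_m1_identical_to_single(self, rng):
        gm = simulate_genotypes(40, 15, rng)
        y = rng.standard_normal(40)
        a = perm_pass_single("g", y, gm.dosages, R=120, rng=gene_rng(3, "g"))
        b = perm_pass_grouped("g", y[None, :], gm.dosages, R=120,
                              rng=gene_rng(3, "g"))
        assert a.p_nominal == pytest.approx(b.p_nominal)
        assert a.p_adjusted == pytest.approx(b.p_adjusted)

    def test_reported_pair_attains_matrix_minimum(self, rng):
        gm = simulate_genotypes(40, 15, rng)
        Y = rng.standard_normal((4, 40))
        res = perm_pass_grouped("g", Y, gm.dosages, R=100, rng=rng,
                                variant_ids=gm.variant_ids)
        block = assoc.isoform_pvalue_block("g", Y, gm.dosages)
        assert res.p_nominal == pytest.approx(np.nanmin(block.pvals))
        i = int(res.best_isoform)
        j = list(gm.variant_ids).index(res.best_variant)
        assert block.pvals[i, j] == pytest.approx(np.nanmin(block.pvals))

    def test_null_calibration_correlated_isoforms(self, rng):
        """Correlated null isoforms: the shared-permutation scheme stays
        calibrated."""
        ps = []
        L = np.linalg.cholesky(0.9 * np.ones((4, 4)) + 0.1 * np.eye(4))
        for g in range(200):
            gm = simulate_genotypes(60, 20, rng)
            Y = L @ rng.standard_normal((4, 60))
            res = perm_pass_grouped(f"g{g}", Y, gm.dosages, R=200, rng=rng)
            ps.append(res.p_adjusted)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_independent_permutation_is_miscalibrated(self, rng):
        """Permuting isoforms independently (the correctness bug the shared
        scheme avoids) breaks the null on correlated isoforms."""
        ps = []
        L = np.linalg.cholesky(0.9 * np.ones((4, 4)) + 0.1 * np.eye(4))
        df = 60 - 2
        for g in range(200):
            gm = simulate_genotypes(60, 20, rng)
            Y = L @ rng.standard_normal((4, 60))
            Xn, _ = perm._normalize_columns(gm.dosages)
            Yc = Y - Y.mean(axis=1, keepdims=True)
            Yn = Yc / np.sqrt((Yc ** 2).sum(axis=1))[:, None]
            obs = perm._corr_to_minp(np.abs(Yn @ Xn).max(), df)
            null = np.empty(150)
            for r in range(150):
                # BUG on purpose: a fresh permutation per isoform
                Yp = np.vstack([row[rng.permutation(60)] for row in Yn])
                null[r] = perm._corr_to_minp(np.abs(Yp @ Xn).max(), df)
            fit = fit_beta_mle(null)
            ps.append(beta_adjust(obs, fit))
        assert stats.kstest(ps, "uniform").pvalue < 0.01
        # biased conservative: independent permutations overstate the
        # effective number of tests
        assert np.mean(ps) > 0.55


class TestAggregatedPass:
    def test_m1_reduces_to_single(self, rng):
        gm = simulate_genotypes(40, 12, rng)
        y = rng.standard_normal(40)
        a = perm_pass_single("g", y, gm.dosages, R=100, rng=gene_rng(5, "g"))
        for aggregator in ("fisher", "cauchy", "min"):
            b = perm_pass_aggregated("g", y[None, :], gm.dosages, aggregator,
                                     R=100, rng=gene_rng(5, "g"))
            assert b.p_nominal == pytest.approx(a.p_nominal, rel=1e-9)
            assert b.p_adjusted == pytest.approx(a.p_adjusted, rel=1e-6)

    def test_min_aggregator_matches_grouped_nominal(self, rng):
        gm = simulate_genotypes(40, 12, rng)
        Y = rng.standard_normal((3, 40))
        a = perm_pass_grouped("g", Y, gm.dosages, R=80, rng=gene_rng(5, "g"))
        b = perm_pass_aggregated("g", Y, gm.dosages, "min", R=80,
                                 rng=gene_rng(5, "g"))
        assert a.p_nominal == pytest.approx(b.p_nominal, rel=1e-9)

    def test_observed_statistic_matches_block_aggregation(self, rng):
        gm = simulate_genotypes(40, 12, rng)
        Y = rng.standard_normal((3, 40))
        block = assoc.isoform_pvalue_block("g", Y, gm.dosages)
        expect = min(assoc.aggregate_fisher(block.pvals[:, j])
                     for j in range(12))
        res = perm_pass_aggregated("g", Y, gm.dosages, "fisher", R=80, rng=rng)
        assert res.p_nominal == pytest.approx(expect, rel=1e-9)

    @pytest.mark.parametrize("aggregator", ["fisher", "cauchy", "min"])
    def test_null_calibration(self, aggregator, rng):
        ps = []
        for g in range(200):
            gm = simulate_genotypes(50, 15, rng)
            Y = rng.standard_normal((4, 50))
            res = perm_pass_aggregated(f"g{g}", Y, gm.dosages, aggregator,
                                       R=150, rng=rng)
            ps.append(res.p_adjusted)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMultivariatePass:
    def test_m1_ftest_equals_single_pass(self, rng):
        """With one isoform the F-test pass matches the single-phenotype
        pass through the F(1, nu) = t^2(nu) identity (up to the swapped
        regression direction, which shares the same p)."""
        gm = simulate_genotypes(40, 10, rng)
        y = rng.standard_normal(40)
        a = perm_pass_multivariate("g", y[None, :], gm.dosages, "ftest",
                                   R=100, rng=gene_rng(9, "g"))
        block = assoc.isoform_pvalue_block("g", y, gm.dosages)
        assert a.p_nominal == pytest.approx(np.nanmin(block.pvals), rel=1e-9)

    def test_observed_matches_looped_tests(self, rng):
        gm = simulate_genotypes(30, 8, rng)
        Y = rng.standard_normal((3, 30))
        for test, fn in (("ftest", assoc.ftest_multiple_regression),
                         ("wilks", assoc.wilks_bartlett_test)):
            res = perm_pass_multivariate("g", Y, gm.dosages, test, R=60,
                                         rng=rng, variant_ids=gm.variant_ids)
            loop = [fn(gm.dosages[:, j], Y.T).pvalue for j in range(8)]
            assert res.p_nominal == pytest.approx(min(loop), rel=1e-9)
            assert res.best_variant == gm.variant_ids[int(np.argmin(loop))]

    @pytest.mark.parametrize("test", ["ftest", "wilks"])
    def test_null_calibration(self, test, rng):
        ps = []
        for g in range(200):
            gm = simulate_genotypes(50, 15, rng)
            Y = rng.standard_normal((3, 50))
            res = perm_pass_multivariate(f"g{g}", Y, gm.dosages, test,
                                         R=150, rng=rng)
            ps.append(res.p_adjusted)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestIsoAggregate:
    def _results(self, pvals):
        return [perm.GeneResult("g", "qtl-single", f"v{i}", f"iso{i}",
                                p / 2, p) for i, p in enumerate(pvals)]

    def test_single_isoform_identity(self):
        out = qtltools_iso_aggregate(self._results([0.3]), "fisher")
        assert out.p_adjusted == pytest.approx(0.3)

    def test_min_returns_smallest_adjusted(self):
        out = qtltools_iso_aggregate(self._results([0.5, 0.2, 0.9]), "min")
        assert out.p_adjusted == pytest.approx(0.2)
        assert out.best_variant == "v1"
        assert out.best_isoform == "iso1"

    def test_fisher_spot_value(self):
        out = qtltools_iso_aggregate(self._results([0.5, 0.5]), "fisher")
        assert out.p_adjusted == pytest.approx(0.5966, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qtltools_iso_aggregate([], "min")


class TestStoreyQvalue:
    def test_all_ones(self):
        with pytest.warns(UserWarning):
            q = storey_qvalue(np.ones(50))
        assert np.allclose(q, 1.0)

    def test_bh_equivalence_when_pi0_is_one(self, rng):
        # a right-skewed p distribution keeps the smoother at pi0 ~ 1
        p = rng.uniform(size=2000) ** 0.8
        q = storey_qvalue(p)
        order = np.argsort(p)
        bh = np.minimum.accumulate(
            (2000 * p[order] / np.arange(1, 2001))[::-1])[::-1]
        bh_full = np.empty(2000)
        bh_full[order] = np.minimum(bh, 1.0)
        pi0_implied = np.median(q / bh_full)
        assert np.allclose(q, np.clip(pi0_implied * bh_full, 0, 1), atol=1e-8)
        assert q.max() <= 1.0

    def test_pi0_recovery_on_mixture(self):
        rng = np.random.default_rng(0)
        p = np.concatenate([rng.uniform(size=5000),
                            rng.beta(0.1, 1.0, size=5000)])
        assert perm.estimate_pi0(p) == pytest.approx(0.5, abs=0.1)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q = storey_qvalue(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_never_below_scaled_bh(self, rng):
        p = rng.uniform(size=1000) ** 0.7
        q = storey_qvalue(p)
        order = np.argsort(p)
        bh = np.minimum.accumulate(
            (1000 * p[order] / np.arange(1, 1001))[::-1])[::-1]
        pi0 = q[order][-1] / min(bh[-1], 1.0)
        assert (q[order] >= pi0 * np.minimum(bh, 1.0) - 1e-9).all()

    def test_degenerate_tail_falls_back_to_bh(self, rng):
        # min-of-4 aggregation leaves no p-values near 1
        p = np.min(rng.uniform(size=(500, 4)), axis=1)
        with pytest.warns(UserWarning, match="lambda grid"):
            q = storey_qvalue(p)
        order = np.argsort(p)
        bh = np.minimum.accumulate(
            (500 * p[order] / np.arange(1, 501))[::-1])[::-1]
        expect = np.empty(500)
        expect[order] = np.minimum(bh, 1.0)
        assert np.allclose(q, expect)

    def test_call_egenes_thresholds(self, rng):
        q = rng.uniform(size=300)
        assert call_egenes(q, 0.0).sum() == 0
        assert call_egenes(q, 1.0).sum() == 300
        small = call_egenes(q, 0.05)
        large = call_egenes(q, 0.2)
        assert (large | ~small).all()  # superset at larger threshold


class TestReproducibility:
    def test_bit_identical_reruns(self, rng):
        gm = simulate_genotypes(40, 12, np.random.default_rng(4))
        Y = np.random.default_rng(5).standard_normal((3, 40))
        a = perm_pass_grouped("geneA", Y, gm.dosages, R=100,
                              rng=gene_rng(42, "geneA"))
        b = perm_pass_grouped("geneA", Y, gm.dosages, R=100,
                              rng=gene_rng(42, "geneA"))
        assert a.p_adjusted == b.p_adjusted
        assert a.beta_fit.a == b.beta_fit.a

    def test_rank_concordance_adjusted_vs_direct(self, rng):
        """Across genes with mixed weak signal, Beta-adjusted and direct
        permutation p-values rank genes almost identically."""
        res = []
        for g in range(150):
            gm = simulate_genotypes(50, 20, rng)
            y = rng.standard_normal(50)
            if g % 2:  # weak signal in half the genes
                y += 0.35 * gm.dosages[:, 3]
            res.append(perm_pass_single(f"g{g}", y, gm.dosages, R=300,
                                        rng=rng))
        adj = [r.p_adjusted for r in res]
        direct = [r.p_direct for r in res]
        rho = stats.spearmanr(adj, direct).statistic
        assert rho > 0.99
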