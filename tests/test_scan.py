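import numpy as np
import pytest
from scipy import stats

import outbredgwas as og
from outbredgwas.scan import reml_fit, reml_workspace

from conftest import make_matrix


def ols_f_oracle(y, X_full, X_reduced):
    """Brute-force F test via normal equations on two nested designs."""
    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)
    rss_f, rss_r = rss(X_full), rss(X_reduced)
    df1 = X_full.shape[1] - X_reduced.shape[1]
    df2 = y.size - X_full.shape[1]
    F = (rss_r - rss_f) / df1 / (rss_f / df2)
    return F, stats.f.sf(F, df1, df2)


class TestTrendTest:
    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 30
            g = rng.integers(0, 3, n).astype(float)
            if np.unique(g).size < 2:
                continue
            y = rng.standard_normal(n) + 0.3 * g
            F, p = og.trend_test(y, g)
            s = g - 1.0
            Fo, po = ols_f_oracle(y, np.column_stack([np.ones(n), s]), np.ones((n, 1)))
            assert F == pytest.approx(Fo, rel=1e-10)
            assert p == pytest.approx(po, rel=1e-8)

    def test_with_covariates_matches_oracle(self):
        rng = np.random.default_rng(1)
        n = 40
        g = rng.integers(0, 3, n).astype(float)
        C = rng.standard_normal((n, 2))
        y = rng.standard_normal(n) + C @ [0.5, -0.2] + 0.2 * g
        F, p = og.trend_test(y, g, covariates=C)
        s = g - 1.0
        X_r = np.column_stack([np.ones(n), C])
        X_f = np.column_stack([X_r, s])
        Fo, po = ols_f_oracle(y, X_f, X_r)
        assert F == pytest.approx(Fo, rel=1e-10)

    def test_perfect_fit(self):
        g = np.array([0.0, 1, 2, 0, 1, 2, 0, 1, 2])
        y = g - 1.0
        F, p = og.trend_test(y, g)
        assert p == 0.0 and np.isinf(F)

    def test_constant_genotype_rejected(self):
        with pytest.raises(ValueError):
            og.trend_test(np.arange(5.0), np.ones(5))

    def test_null_p_uniform(self):
        # 10^4 null replicates: p uniform on (0, 1) by KS
        rng = np.random.default_rng(2)
        n = 30
        g = rng.integers(0, 3, n).astype(np.int8)
        G1 = make_matrix(g[:, None])
        ps = []
        Y = rng.standard_normal((10_000, n))
        for y in Y:
            _, p = og.trend_test(y, g.astype(float))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, 50).astype(float)
        y = rng.standard_normal(50)
        _, p1 = og.trend_test(y, g)
        _, p2 = og.trend_test(3.7 * y - 11.0, g)
        assert p1 == pytest.approx(p2, rel=1e-10)


class TestAnovaTest:
    def test_two_class_equals_two_group(self):
        rng = np.random.default_rng(4)
        g = np.array([0] * 15 + [2] * 15, dtype=float)
        y = rng.standard_normal(30) + 0.5 * (g == 2)
        F, p, df1 = og.anova_test(y, g)
        assert df1 == 1
        t = stats.ttest_ind(y[g == 0], y[g == 2])
        assert F == pytest.approx(t.statistic**2, rel=1e-10)

    def test_group_sums_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = rng.integers(0, 3, 30).astype(float)
            if np.unique(g).size < 3:
                continue
            y = rng.standard_normal(30)
            F, p, df1 = og.anova_test(y, g)
            # brute-force between/within sums of squares
            groups = [y[g == c] for c in np.unique(g)]
            k = len(groups)
            gm = y.mean()
            ssb = sum(len(gr) * (gr.mean() - gm) ** 2 for gr in groups)
            ssw = sum(((gr - gr.mean()) ** 2).sum() for gr in groups)
            Fo = (ssb / (k - 1)) / (ssw / (y.size - k))
            assert F == pytest.approx(Fo, rel=1e-10)
            assert df1 == k - 1

    def test_separated_classes_p_zero(self):
        g = np.array([0.0] * 10 + [1.0] * 10 + [2.0] * 10)
        y = g.copy()  # constant within class
        F, p, _ = og.anova_test(y, g)
        assert p == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            og.anova_test(np.arange(5.0), np.zeros(5))

    def test_nesting_vs_trend(self):
        # genotype-factor model nests the trend model: never larger RSS
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, 60).astype(float)
        y = rng.standard_normal(60) + 0.3 * g
        n = 60
        s = g - 1
        X_trend = np.column_stack([np.ones(n), s])
        X_anova = np.column_stack([np.ones(n), g == 1, g == 2]).astype(float)
        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r
        assert rss(X_anova) <= rss(X_trend) + 1e-9


class TestAnovaScan:
    def test_matches_single_snp_tests(self, tiny_pop):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(tiny_pop.n_samples)
        res = og.anova_scan(y, tiny_pop)
        for j in [0, 5, 17, 100, 250]:
            g = tiny_pop.genotypes[:, j].astype(float)
            if np.unique(g).size < 2:
                continue
            F, p, df1 = og.anova_test(y, g)
            row = res.table.iloc[j]
            assert row["statistic"] == pytest.approx(F, rel=1e-8)
            assert row["df"] == df1


class TestRemlFit:
    def test_null_heritability_small(self, nmri_kinship):
        K = nmri_kinship.matrix
        n = K.shape[0]
        ws = reml_workspace(K, np.ones((n, 1)))
        low = 0
        rng = np.random.default_rng(8)
        for s in range(50):
            y = rng.standard_normal(n)
            vc = reml_fit(y, workspace=ws)
            if vc.heritability < 0.1:
                low += 1
        assert low >= 45  # 90% of seeds

    def test_heritability_recovery(self, nmri_pop, nmri_kinship):
        K = nmri_kinship.matrix
        ws = reml_workspace(K, np.ones((K.shape[0], 1)))
        h = []
        for s in range(50):
            y, _ = og.simulate_trait(
                nmri_pop, K, og.TruthRecord([], [], 1.0, 1.0), seed=1000 + s
            )
            h.append(reml_fit(y, workspace=ws).heritability)
        assert abs(np.median(h) - 0.5) < 0.1

    def test_identity_kinship_unidentifiable(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(50)
        vc = reml_fit(y, np.eye(50))
        assert vc.unidentifiable

    def test_non_psd_rejected(self):
        K = np.eye(5)
        K[0, 1] = K[1, 0] = 2.0
        with pytest.raises(ValueError):
            reml_fit(np.arange(5.0), K)


class TestMixedScan:
    def test_identity_kinship_equals_trend(self, tiny_pop):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(tiny_pop.n_samples)
        res_m = og.mixed_scan(y, tiny_pop, np.eye(tiny_pop.n_samples))
        res_t = og.trend_scan(y, tiny_pop)
        pm = res_m.table["p"].to_numpy()
        pt = res_t.table["p"].to_numpy()
        ok = ~np.isnan(pm)
        assert np.allclose(pm[ok], pt[ok], atol=1e-8)

    def test_refit_modes_agree_on_null(self, tiny_pop, tiny_kinship):
        rng = np.random.default_rng(11)
        y = rng.standard_normal(tiny_pop.n_samples)
        G = tiny_pop.take_snps(np.arange(25))
        once = og.mixed_scan(y, G, tiny_kinship.matrix, refit="once")
        per = og.mixed_scan(y, G, tiny_kinship.matrix, refit="per_snp")
        a = once.table["neg_log10_p"].to_numpy()
        b = per.table["neg_log10_p"].to_numpy()
        ok = ~np.isnan(a) & ~np.isnan(b)
        assert np.corrcoef(a[ok], b[ok])[0, 1] > 0.98

    def test_inflation_less_than_trend(self, nmri_pop, nmri_kinship):
        # strongly structured null trait: mixed scan less inflated than trend
        K = nmri_kinship.matrix
        lam_m, lam_t = [], []
        for s in range(5):
            y, _ = og.simulate_trait(
                nmri_pop, K, og.TruthRecord([], [], 3.0, 1.0), seed=500 + s
            )
            pm = og.mixed_scan(y, nmri_pop, K).table["p"].dropna().to_numpy()
            pt = og.trend_scan(y, nmri_pop).table["p"].dropna().to_numpy()
            chi_m = stats.chi2.isf(pm, 1)
            chi_t = stats.chi2.isf(pt, 1)
            lam_m.append(np.median(chi_m) / stats.chi2.ppf(0.5, 1))
            lam_t.append(np.median(chi_t) / stats.chi2.ppf(0.5, 1))
        assert np.median(lam_m) < np.median(lam_t)
        assert abs(np.median(lam_m) - 1) < abs(np.median(lam_t) - 1)

    def test_causal_recovery(self):
        # 20%-variance QTL at cohort size 288: top SNP is the causal one or
        # an LD twin in >= 95% of seeds.  (At n=64 the claim is unattainable:
        # genome-wide top-SNP identification power is only ~70%.)
        G = og.simulate_population(og.tiny(seed=42, n_samples=288))
        G, _ = og.filter_snps(G)
        K = og.ibs_kinship(G).matrix
        j = 200
        snp = str(G.snp_ids[j])
        beta = og.effect_for_variance_fraction(G, snp, 0.20, 0.2, 0.8)
        hits = 0
        n_seeds = 40
        s_target = G.scores()[:, j]
        for seed in range(n_seeds):
            y, _ = og.simulate_trait(G, K, og.TruthRecord([snp], [beta], 0.2, 0.8), seed=seed)
            res = og.mixed_scan(y, G, K)
            top = res.table["neg_log10_p"].idxmax()
            s_top = G.scores()[:, top]
            r2 = np.corrcoef(s_target, s_top)[0, 1] ** 2
            if top == j or r2 > 0.99:
                hits += 1
        assert hits >= int(0.95 * n_seeds)

    def test_missing_genotypes_refused(self, tiny_pop):
        G = og.inject_missing(tiny_pop, 0.05, seed=0)
        with pytest.raises(ValueError):
            og.mixed_scan(np.zeros(G.n_samples), G, np.eye(G.n_samples))


class TestConditionalScan:
    def test_conditioning_snp_excluded(self, tiny_pop, tiny_kinship):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(tiny_pop.n_samples)
        snp = str(tiny_pop.snp_ids[10])
        res = og.conditional_scan(y, tiny_pop, tiny_kinship.matrix, [snp])
        assert snp not in set(res.table["snp_id"])

    def test_conditioning_kills_linked_signal(self, tiny_pop, tiny_kinship):
        G, K = tiny_pop, tiny_kinship.matrix
        j = 60
        snp = str(G.snp_ids[j])
        beta = og.effect_for_variance_fraction(G, snp, 0.35, 0.1, 0.9)
        y, _ = og.simulate_trait(G, K, og.TruthRecord([snp], [beta], 0.1, 0.9), seed=3)
        base = og.mixed_scan(y, G, K)
        cond = og.conditional_scan(y, G, K, [snp])
        # linked neighbors (r2 > 0.5 with the causal SNP) lose signal
        s = G.scores()
        r2 = np.corrcoef(s.T)[j] ** 2
        linked = [
            str(sid) for k, sid in enumerate(G.snp_ids)
            if k != j and r2[k] > 0.5
        ]
        if linked:
            b = base.table.set_index("snp_id").loc[linked, "neg_log10_p"]
            c = cond.table.set_index("snp_id").loc[linked, "neg_log10_p"]
            assert (c.to_numpy() < b.to_numpy() + 1e-9).all()
            assert c.mean() < b.mean()

    def test_conditioning_on_null_snp_harmless(self, tiny_pop, tiny_kinship):
        rng = np.random.default_rng(13)
        G, K = tiny_pop, tiny_kinship.matrix
        y = rng.standard_normal(G.n_samples)
        base = og.mixed_scan(y, G, K)
        # pick a SNP uncorrelated with y
        ps = base.table["p"].to_numpy()
        j = int(np.nanargmax(ps))
        snp = str(G.snp_ids[j])
        cond = og.conditional_scan(y, G, K, [snp])
        merged = base.table.set_index("snp_id")[["neg_log10_p"]].join(
            cond.table.set_index("snp_id")[["neg_log10_p"]], rsuffix="_c"
        ).dropna()
        delta = (merged["neg_log10_p"] - merged["neg_log10_p_c"]).abs().max()
        assert delta < 0.5

    def test_collinear_conditioning_pruned(self, tiny_pop, tiny_kinship):
        # duplicate a SNP by conditioning on an identical pair
        G = tiny_pop
        col = G.genotypes[:, 5]
        dup_ids = [str(G.snp_ids[5])]
        # conditioning twice on the same SNP id
        res = og.conditional_scan(
            np.random.default_rng(14).standard_normal(G.n_samples),
            G, tiny_kinship.matrix, dup_ids + dup_ids,
        )
        assert res.covariate_snp_ids == dup_ids


class TestVarianceExplained:
    def test_exact_function_r2_one(self, tiny_pop):
        s = tiny_pop.scores()[:, 7]
        res = og.variance_explained(2.0 * s + 1.0, tiny_pop, [[str(tiny_pop.snp_ids[7])]])
        assert res["r2"].iloc[0] == pytest.approx(1.0)

    def test_empty_set_zero(self, tiny_pop):
        y = np.random.default_rng(15).standard_normal(tiny_pop.n_samples)
        res = og.variance_explained(y, tiny_pop, [[]])
        assert res["r2"].iloc[0] == pytest.approx(0.0)

    def test_correlated_snps_marginal_exceeds_incremental(self, tiny_pop):
        # find a correlated SNP pair (r ~ 0.3-0.9) and give both effects
        G = tiny_pop
        s = G.scores()
        rng = np.random.default_rng(16)
        corr = None
        for a in range(0, G.n_snps, 7):
            for b in range(a + 1, min(a + 30, G.n_snps)):
                r = abs(np.corrcoef(s[:, a], s[:, b])[0, 1])
                if 0.25 < r < 0.9:
                    corr = (a, b)
                    break
            if corr:
                break
        assert corr is not None
        a, b = corr
        y = s[:, a] + s[:, b] + rng.standard_normal(G.n_samples)
        ida, idb = str(G.snp_ids[a]), str(G.snp_ids[b])
        res = og.variance_explained(y, G, [[idb], [ida, idb]])
        marginal_b = res["r2"].iloc[0]
        incremental_b = res["incremental_r2"].iloc[1][1]
        assert marginal_b > incremental_b
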