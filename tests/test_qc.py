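import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import outbredgwas as og
from outbredgwas.genotypes import MISSING

from conftest import make_matrix


class TestComputeMaf:
    def test_all_heterozygous(self):
        G = make_matrix(np.ones((10, 1), dtype=np.int8))
        assert og.compute_maf(G)[0] == pytest.approx(0.5)

    def test_direct_count(self):
        G = make_matrix(np.array([[0], [0], [1], [2]], dtype=np.int8))
        assert og.compute_maf(G)[0] == pytest.approx(3 / 8)

    def test_monomorphic_zero(self):
        G = make_matrix(np.zeros((6, 1), dtype=np.int8))
        assert og.compute_maf(G)[0] == 0.0

    def test_all_missing_nan(self):
        G = make_matrix(np.full((4, 1), MISSING, dtype=np.int8))
        assert np.isnan(og.compute_maf(G)[0])

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=50))
    def test_bounds(self, calls):
        G = make_matrix(np.array(calls, dtype=np.int8)[:, None])
        maf = og.compute_maf(G)[0]
        assert 0.0 <= maf <= 0.5


class TestHweChisq:
    def _from_counts(self, n0, n1, n2):
        g = np.array([0] * n0 + [1] * n1 + [2] * n2, dtype=np.int8)
        return make_matrix(g[:, None])

    def test_exact_hwe_proportions(self):
        assert og.hwe_chisq(self._from_counts(25, 50, 25))[0] == pytest.approx(0.0)

    def test_no_heterozygotes(self):
        # counts (50, 0, 50): expected (25, 50, 25) -> chi2 = 25 + 50 + 25
        assert og.hwe_chisq(self._from_counts(50, 0, 50))[0] == pytest.approx(100.0)

    def test_monomorphic_is_zero(self):
        assert og.hwe_chisq(self._from_counts(30, 0, 0))[0] == 0.0

    def test_nonnegative_property(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 60)
            g = rng.integers(0, 3, size=n).astype(np.int8)
            chi2 = og.hwe_chisq(make_matrix(g[:, None]))[0]
            assert chi2 >= 0

    def test_null_distribution_matches_chi2_1df(self):
        # multinomial draws under HWE at n=288: chi2 values follow the 1-df
        # chi-square law (KS test over 5000 replicates)
        rng = np.random.default_rng(12)
        p = 0.3
        probs = [(1 - p) ** 2, 2 * p * (1 - p), p * p]
        counts = rng.multinomial(288, probs, size=5000)
        geno = np.zeros((288, 5000), dtype=np.int8)
        for j, (n0, n1, n2) in enumerate(counts):
            geno[n0:n0 + n1, j] = 1
            geno[n0 + n1:, j] = 2
        chi2 = og.hwe_chisq(make_matrix(geno))
        ks = stats.kstest(chi2, "chi2", args=(1,))
        assert ks.pvalue > 1e-3


class TestFilterSnps:
    def _fixture(self):
        rng = np.random.default_rng(1)
        cols = []
        # 7 well-behaved SNPs in approximate HWE, common alleles
        for _ in range(7):
            g = rng.choice([0, 1, 2], size=100, p=[0.36, 0.48, 0.16]).astype(np.int8)
            g[:3] = [0, 1, 2]  # guarantee polymorphism
            cols.append(g)
        # one MAF failure (1 minor allele in 200)
        low = np.zeros(100, dtype=np.int8)
        low[0] = 1
        cols.append(low)
        # one HWE failure: no hets, half/half homozygotes -> chi2 = 100
        hwe = np.array([0] * 50 + [2] * 50, dtype=np.int8)
        cols.append(hwe)
        # one missingness failure: 50% missing, polymorphic remainder
        miss = np.array([0, 1, 2, 1] * 25, dtype=np.int8)
        miss[:50] = MISSING
        cols.append(miss)
        return make_matrix(np.column_stack(cols))

    def test_constructed_fixture_counts(self):
        G = self._fixture()
        Gf, rep = og.filter_snps(G)
        assert rep.n_input_snps == 10
        assert rep.n_pass_filters == 7
        assert Gf.n_snps == 7
        assert (rep.removed_maf, rep.removed_hwe, rep.removed_missing) == (1, 1, 1)

    def test_vacuous_thresholds_keep_polymorphic(self):
        G = self._fixture()
        Gf, rep = og.filter_snps(G, maf_min=0.0, hwe_max=np.inf, miss_max=1.01)
        assert rep.n_pass_filters == rep.n_polymorphic

    def test_brute_force_recount(self, tiny_pop):
        G = og.inject_missing(tiny_pop, 0.05, seed=3)
        Gf, rep = og.filter_snps(G)
        # independent per-SNP re-evaluation
        kept = 0
        for j in range(G.n_snps):
            col = G.genotypes[:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                continue
            p = (2 * (obs == 2).sum() + (obs == 1).sum()) / (2 * obs.size)
            maf = min(p, 1 - p)
            n = obs.size
            pa = (2 * (obs == 0).sum() + (obs == 1).sum()) / (2 * n)
            exp = np.array([n * pa**2, 2 * n * pa * (1 - pa), n * (1 - pa) ** 2])
            obs_counts = np.array([(obs == 0).sum(), (obs == 1).sum(), (obs == 2).sum()])
            chi2 = ((obs_counts - exp) ** 2)[exp > 0] / exp[exp > 0]
            chi2 = chi2.sum() if maf > 0 else 0.0
            miss = (col == MISSING).mean()
            if maf > 0.02 and chi2 < 20 and miss < 0.40:
                kept += 1
        assert rep.n_pass_filters == kept

    def test_idempotent(self, tiny_pop):
        G1, _ = og.filter_snps(tiny_pop)
        G2, rep2 = og.filter_snps(G1)
        assert G2 == G1
        assert rep2.n_pass_filters == G1.n_snps


class TestCollapseIdentical:
    def test_within_window_collapsed(self):
        col = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        G = make_matrix(np.column_stack([col, col]), pos=[1_000_000, 2_000_000])
        Gc, mapping = og.collapse_identical(G)
        assert Gc.n_snps == 1
        assert mapping == {"s0": ["s1"]}

    def test_outside_window_kept(self):
        col = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        G = make_matrix(np.column_stack([col, col]), pos=[1_000_000, 4_000_001])
        Gc, _ = og.collapse_identical(G)
        assert Gc.n_snps == 2

    def test_different_chromosomes_kept(self):
        col = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        G = make_matrix(np.column_stack([col, col]), chrom=["1", "2"], pos=[1000, 2000])
        Gc, _ = og.collapse_identical(G)
        assert Gc.n_snps == 2

    def test_expand_recovers_full_set(self, tiny_pop):
        Gc, mapping = og.collapse_identical(tiny_pop)
        inv = og.expand_collapsed(mapping)
        recovered = set(Gc.snp_ids.tolist()) | set(inv.keys())
        assert recovered == set(tiny_pop.snp_ids.tolist())
        # representatives are never themselves collapsed
        assert not (set(inv.keys()) & set(Gc.snp_ids.tolist()))

    def test_leftmost_kept(self):
        col = np.array([0, 2, 1, 1], dtype=np.int8)
        other = np.array([2, 0, 1, 1], dtype=np.int8)
        G = make_matrix(np.column_stack([col, other, col]), pos=[100, 500, 900])
        Gc, mapping = og.collapse_identical(G)
        assert list(Gc.snp_ids) == ["s0", "s1"]
        assert mapping["s0"] == ["s2"]


class TestImputeMissing:
    def test_identity_when_complete(self, tiny_pop):
        assert og.impute_missing(tiny_pop, seed=0) == tiny_pop

    def test_degenerate_frequency(self):
        col = np.full(20, 2, dtype=np.int8)
        col[5] = MISSING
        G = make_matrix(col[:, None])
        Gi = og.impute_missing(G, seed=0)
        assert np.all(Gi.genotypes == 2)

    def test_never_alters_observed(self, tiny_pop):
        G = og.inject_missing(tiny_pop, 0.05, seed=1)
        Gi = og.impute_missing(G, seed=2)
        obs = G.genotypes != MISSING
        assert np.array_equal(Gi.genotypes[obs], G.genotypes[obs])
        assert not Gi.has_missing

    def test_maf_preserved_after_imputation(self, tiny_pop):
        maf_true = og.compute_maf(tiny_pop)
        G = og.inject_missing(tiny_pop, 0.013, seed=4)
        Gi = og.impute_missing(G, seed=5)
        maf_post = og.compute_maf(Gi)
        # at n=64 each resampled call moves MAF by 1/(2n) = 0.0078, so the
        # worst SNP can shift by a few multiples of that; the mean shift
        # must stay near zero
        assert np.max(np.abs(maf_post - maf_true)) < 0.05
        assert np.mean(np.abs(maf_post - maf_true)) < 0.005

    def test_all_missing_raises(self):
        G = make_matrix(np.full((4, 1), MISSING, dtype=np.int8))
        with pytest.raises(ValueError):
            og.impute_missing(G, seed=0)


class TestLogAcr:
    def test_known_values(self):
        v = np.array([0.0, np.e - 1, np.e**2 - 1])
        assert np.allclose(og.log_acr(v), [0.0, 1.0, 2.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            og.log_acr(np.array([-0.1]))

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=30))
    def test_monotone_nonnegative(self, vals):
        out = og.log_acr(np.array(vals))
        assert np.all(out >= 0)


class TestTrimReadings:
    def test_constant_vector(self):
        res = og.trim_readings(np.full(45, 7.0))
        assert res.n_retained == 45
        assert res.mean == 7.0 and res.sd == 0.0
        assert res.passed
        res2 = og.trim_readings(np.full(39, 7.0))
        assert not res2.passed

    def test_single_outlier_removed(self):
        x = np.array([100.0] * 50 + [1e6])
        res = og.trim_readings(x)
        assert res.n_retained == 50
        assert res.mean == pytest.approx(100.0)
        assert res.passed

    def test_39_readings_fail(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 1, size=39)
        res = og.trim_readings(x)
        assert not res.passed


class TestDropDuplicates:
    def test_both_vs_one(self, tiny_pop):
        idx = np.arange(tiny_pop.n_samples).tolist() + [0]
        G = tiny_pop.take_samples(np.array(idx))
        G.sample_ids[-1] = "dup_of_0"
        Gb, flagged = og.drop_duplicate_samples(G, drop="both")
        assert len(flagged) == 1 and flagged[0][2] == 1.0
        assert Gb.n_samples == tiny_pop.n_samples - 1
        Go, _ = og.drop_duplicate_samples(G, drop="one")
        assert Go.n_samples == tiny_pop.n_samples
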