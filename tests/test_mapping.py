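import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from nmdqtl import mapping
from nmdqtl.annotation import GeneModel, TranscriptModel


def _ols_oracle(y, X):
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return fit.params[-1], fit.bse[-1], fit.pvalues[-1]


class TestFitNominal:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=60)
        g = rng.binomial(2, 0.3, 60).astype(float)
        b, se, p = mapping.fit_nominal(y, g)
        ob, ose, op = _ols_oracle(y, g)
        assert b == pytest.approx(ob)
        assert se == pytest.approx(ose)
        assert p == pytest.approx(op)

    def test_matches_statsmodels_with_covariates(self):
        rng = np.random.default_rng(1)
        n = 80
        C = rng.normal(size=(n, 3))
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.4 * g + C @ [1.0, -2.0, 0.5] + rng.normal(size=n)
        b, se, p = mapping.fit_nominal(y, g, C)
        ob, ose, op = _ols_oracle(y, np.column_stack([C, g]))
        assert b == pytest.approx(ob)
        assert se == pytest.approx(ose)
        assert p == pytest.approx(op)

    def test_collinear_raises(self):
        y = np.arange(10.0)
        with pytest.raises(mapping.CollinearGenotypeError):
            mapping.fit_nominal(y, np.ones(10))

    def test_exact_fit_conventions(self):
        g = np.array([0.0, 1, 2, 0, 1, 2, 0, 1, 2, 1])
        b, se, p = mapping.fit_nominal(3.0 + 2.0 * g, g)
        assert b == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-12)
        b, se, p = mapping.fit_nominal(np.full(10, 3.0), g)
        assert b == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(2)
        n, m = 40, 25
        C = rng.normal(size=(n, 2))
        G = rng.binomial(2, 0.4, (m, n)).astype(float)
        Y = rng.normal(size=(m, n))
        B, SE, P = mapping.fit_nominal_many(Y, G, C)
        for i in range(m):
            b, se, p = mapping.fit_nominal(Y[i], G[i], C)
            assert B[i] == pytest.approx(b)
            assert SE[i] == pytest.approx(se)
            assert P[i] == pytest.approx(p)

    def test_vectorized_constant_row_nan(self):
        Y = np.random.default_rng(3).normal(size=(2, 20))
        G = np.vstack([np.ones(20), np.arange(20.0)])
        B, _, P = mapping.fit_nominal_many(Y, G)
        assert np.isnan(B[0]) and np.isnan(P[0])
        assert np.isfinite(B[1])


class TestPermutation:
    def test_exhaustive_matches_enumeration_oracle(self):
        for seed, n, m in [(3, 6, 3), (4, 5, 2), (5, 7, 2)]:
            rng = np.random.default_rng(seed)
            y = rng.normal(size=n)
            G = rng.binomial(2, 0.4, (m, n)).astype(float)
            while any(len(set(row)) == 1 for row in G):
                G = rng.binomial(2, 0.4, (m, n)).astype(float)
            p_perm, _ = mapping.permutation_pvalue(y, G, exhaustive=True)

            def min_p(vec):
                return min(stats.pearsonr(vec, g).pvalue for g in G)

            obs = min_p(y)
            hits = sum(
                min_p(y[list(pm)]) <= obs + 1e-12
                for pm in itertools.permutations(range(n))
            )
            assert p_perm == pytest.approx(hits / math.factorial(n))

    def test_exhaustive_guard(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            mapping.permutation_pvalue(
                rng.normal(size=9), rng.normal(size=(1, 9)), exhaustive=True
            )

    def test_adaptive_null_is_large(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=100)
        G = rng.binomial(2, 0.3, (5, 100)).astype(float)
        p, per_var = mapping.permutation_pvalue(y, G, n_min=200, n_max=500, seed=1)
        assert 0.0 < p <= 1.0
        assert p > 0.01  # a null gene should not look significant
        assert per_var.shape == (5,)

    def test_adaptive_signal_is_small(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.3, 200).astype(float)
        y = 1.5 * g + rng.normal(size=200)
        p, _ = mapping.permutation_pvalue(y, g[None, :], n_min=500, n_max=1000, seed=2)
        assert p <= 2 / 501


class TestQvalues:
    def test_small_m_falls_back_to_bh(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        q = mapping.compute_qvalues(p)
        _, q_bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_bh)

    def test_storey_properties(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(size=900), rng.uniform(0, 1e-4, 100)])
        q = mapping.compute_qvalues(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p
        # the planted signals should survive at FDR 5%
        assert (q[900:] < 0.05).all()

    def test_explicit_pi0(self):
        p = np.linspace(0.01, 1, 200)
        q1 = mapping.compute_qvalues(p, pi0=1.0)
        q05 = mapping.compute_qvalues(p, pi0=0.5)
        assert np.allclose(q05, q1 * 0.5)


class TestCisScan:
    @staticmethod
    def _gene(gid, chrom, start, strand="+"):
        t = TranscriptModel(f"{gid}.T", gid, chrom, strand, [(start, start + 1000)])
        return GeneModel(gid, chrom, strand, [t])

    def test_enumerate_window(self):
        genes = [self._gene("G1", "chr1", 1_000_000)]
        variants = pd.DataFrame(
            {
                "variant_id": ["in_edge", "out", "wrong_chrom"],
                "chrom": ["chr1", "chr1", "chr2"],
                "pos": [0, 2_000_001 + 1, 1_000_000],
            }
        )
        pairs = mapping.enumerate_cis_pairs(variants, genes, window=1_000_000)
        assert list(pairs.variant_id) == ["in_edge"]

    def test_map_cis_schema_and_qvalues(self, toy, toy_genes, two_tissues):
        res = two_tissues[11]["res_nmd"]
        assert {
            "variant_id", "gene_id", "channel", "beta", "se",
            "p_nominal", "p_perm", "q",
        } <= set(res.columns)
        assert res.p_nominal.between(0, 1).all()
        assert res.p_perm.between(0, 1).all()
        # one permutation p per gene
        assert (res.groupby("gene_id").p_perm.nunique() == 1).all()
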