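import numpy as np
import pandas as pd
import pytest

from nmdqtl import simulate as sim


class TestAllelicModel:
    def test_expected_channel_means(self):
        p = sim.AllelicNmdParams(
            t_ref=100, t_alt=100, alpha_ref=0.3, alpha_alt=0.4,
            theta_ref=0.5, theta_alt=0.5,
        )
        nmd0, non0 = sim.expected_channel_means(p, 0)
        assert nmd0 == pytest.approx(2 * 100 * 0.3 * 0.5)
        assert non0 == pytest.approx(2 * 100 * 0.7)
        nmd1, non1 = sim.expected_channel_means(p, 1)
        assert nmd1 == pytest.approx(100 * 0.3 * 0.5 + 100 * 0.4 * 0.5)
        assert non1 == pytest.approx(100 * 0.7 + 100 * 0.6)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            sim.AllelicNmdParams(100, 100, 1.2, 0.3, 0.5, 0.5)
        with pytest.raises(ValueError):
            sim.AllelicNmdParams(-1, 100, 0.3, 0.3, 0.5, 0.5)

    def test_bad_dosage(self):
        p = sim.AllelicNmdParams(100, 100, 0.3, 0.3, 0.5, 0.5)
        with pytest.raises(ValueError):
            sim.expected_channel_means(p, 3)


class TestGenotypes:
    def test_dosage_range_and_maf(self):
        X = sim.simulate_genotypes(200, 5000, 0.05, seed=1)
        assert set(np.unique(X)) <= {0, 1, 2}
        assert X.mean() / 2 == pytest.approx(0.05, abs=0.005)

    def test_maf_validation(self):
        with pytest.raises(ValueError):
            sim.simulate_genotypes(10, 10, 0.0, seed=0)
        with pytest.raises(ValueError):
            sim.simulate_genotypes(10, 10, 0.6, seed=0)


class TestSimulateExpression:
    def test_shapes_and_truth(self):
        cfg = sim.SimulationConfig(n_variants=500, n_samples=100)
        ds = sim.simulate_expression(cfg, seed=0)
        assert ds.y_nmd.shape == (500, 100)
        assert set(ds.truth.label) <= {"pNMD", "dNMD", "null"}
        frac = (ds.truth.label == "null").mean()
        assert frac == pytest.approx(0.9, abs=0.05)

    def test_classes_touch_expected_parameters(self):
        cfg = sim.SimulationConfig(n_variants=2000, n_samples=10)
        t = sim.simulate_expression(cfg, seed=1).truth
        p, d, nul = (t[t.label == c] for c in ("pNMD", "dNMD", "null"))
        assert (p.alpha_alt != p.alpha_ref).all()
        assert (p.theta_alt == p.theta_ref).all()
        assert (d.theta_alt != d.theta_ref).all()
        assert (d.alpha_alt == d.alpha_ref).all()
        assert (nul.alpha_alt == nul.alpha_ref).all()
        assert (nul.theta_alt == nul.theta_ref).all()
        eq = nul.is_eqtl_null
        assert (nul[eq].t_alt != nul[eq].t_ref).all()
        assert (nul[~eq].t_alt == nul[~eq].t_ref).all()
        # effect magnitudes stay in the configured band
        mag = (p.alpha_alt - p.alpha_ref).abs()
        assert mag.between(*cfg.effect_range).all()

    def test_noise_free_means_match_model(self):
        cfg = sim.SimulationConfig(n_variants=50, n_samples=30, noise_sd=0.0)
        ds = sim.simulate_expression(cfg, seed=2)
        i = int(np.flatnonzero(ds.truth.label == "pNMD")[0])
        row = ds.truth.iloc[i]
        params = sim.AllelicNmdParams(
            row.t_ref, row.t_alt, row.alpha_ref, row.alpha_alt,
            row.theta_ref, row.theta_alt,
        )
        for j in range(cfg.n_samples):
            nmd, non = sim.expected_channel_means(params, int(ds.genotypes[i, j]))
            assert ds.y_nmd[i, j] == pytest.approx(nmd)
            assert ds.y_non[i, j] == pytest.approx(non)

    def test_seed_reproducible(self):
        cfg = sim.SimulationConfig(n_variants=100, n_samples=50)
        a = sim.simulate_expression(cfg, seed=7)
        b = sim.simulate_expression(cfg, seed=7)
        assert np.array_equal(a.y_nmd, b.y_nmd)
        assert a.truth.equals(b.truth)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(class_proportions=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            sim.SimulationConfig(effect_range=(0.1, 0.9))  # pushes theta past 1


class TestNullRegrouping:
    def test_partitions_preserve_totals(self):
        rng = np.random.default_rng(0)
        tpm = pd.DataFrame(
            rng.uniform(1, 10, (9, 6)),
            index=[f"t{i}" for i in range(9)],
            columns=[f"s{j}" for j in range(6)],
        )
        tx_gene = pd.Series(
            {f"t{i}": f"g{i // 3}" for i in range(9)}
        )
        a, b = sim.generate_null_regrouping(tpm, tx_gene, n_genes=3, seed=1)
        total = (a + b).sort_index()
        expected = tpm.groupby(tx_gene).sum().sort_index()
        assert np.allclose(total, expected)
        assert (a > 0).all().all() and (b > 0).all().all()

    def test_warns_on_singletons_and_overrequest(self):
        tpm = pd.DataFrame(
            np.ones((3, 4)), index=["t0", "t1", "t2"], columns=list("abcd")
        )
        tx_gene = pd.Series({"t0": "g0", "t1": "g0", "t2": "g1"})
        with pytest.warns(UserWarning):
            a, _ = sim.generate_null_regrouping(tpm, tx_gene, n_genes=5, seed=0)
        assert list(a.index) == ["g0"]


class TestToyResources:
    def test_sizes_and_schemas(self, toy):
        assert toy.variant_positions.columns.tolist() == ["variant_id", "chrom", "pos"]
        assert {"snp_id", "disease_id", "mesh_class"} <= set(toy.disease_snps.columns)
        for track in toy.bed_tracks.values():
            assert (track.end > track.start).all()
        assert len(toy.covariates) == 80

    def test_tissue_tpm_truth(self, toy, toy_genes):
        tpm, tx_gene, X, truth = sim.simulate_tissue_tpm(
            toy_genes, toy.variant_positions, 40, seed=3
        )
        assert tpm.shape == (20, 40)
        assert X.shape == (len(toy.variant_positions), 40)
        assert set(truth.label) == {"pNMD", "dNMD", "null"}
        assert set(tx_gene) == {g.gene_id for g in toy_genes}
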