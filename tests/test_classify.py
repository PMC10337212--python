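import itertools

import numpy as np
import pandas as pd
import pytest

from nmdqtl import classify


class TestRules:
    def test_pnmd_requires_both_significant_opposite(self):
        assert classify.classify_from_qvalues(0.01, 0.01, 1.0, -1.0) == "pNMD-candidate"
        assert classify.classify_from_qvalues(0.01, 0.01, 1.0, 1.0) == "none"
        assert classify.classify_from_qvalues(0.2, 0.01, 1.0, -1.0) == "none"

    def test_dnmd_requires_clear_null_other_channel(self):
        assert classify.classify_from_qvalues(0.01, 0.9, 1.0, 0.0) == "dNMD-candidate"
        assert classify.classify_from_qvalues(0.01, 0.5, 1.0, 0.0) == "none"  # gap zone
        assert classify.classify_from_qvalues(0.06, 0.9, 1.0, 0.0) == "none"

    def test_rules_mutually_exclusive_on_grid(self):
        qs = [0.0, 0.01, 0.05, 0.2, 0.8, 0.81, 1.0]
        bs = [-1.0, 0.0, 1.0]
        for qn, qo, bn, bo in itertools.product(qs, qs, bs, bs):
            label = classify.classify_from_qvalues(qn, qo, bn, bo)
            assert label in {"pNMD-candidate", "dNMD-candidate", "none"}

    def test_nonfinite_inputs_are_none(self):
        assert classify.classify_from_qvalues(np.nan, 0.01, 1.0, -1.0) == "none"
        assert classify.classify_from_qvalues(0.01, 0.9, np.inf, 0.0) == "none"

    def test_boundaries_inclusive(self):
        assert classify.classify_from_qvalues(0.05, 0.05, 1.0, -1.0) == "pNMD-candidate"
        assert classify.classify_from_qvalues(0.05, 0.8, 1.0, 0.0) == "none"
        assert (
            classify.classify_from_qvalues(0.05, 0.8 + 1e-12, 1.0, 0.0)
            == "dNMD-candidate"
        )


class TestClassifyTable:
    def test_merges_channels(self):
        nmd = pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3"],
                "gene_id": ["g1", "g1", "g2"],
                "beta": [1.0, 1.0, 1.0],
                "q": [0.01, 0.01, 0.5],
            }
        )
        non = pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3"],
                "gene_id": ["g1", "g1", "g2"],
                "beta": [-1.0, 0.0, 1.0],
                "q": [0.01, 0.9, 0.01],
            }
        )
        out = classify.classify_table(nmd, non, tissue="toy")
        assert dict(zip(out.variant_id, out.label)) == {"v1": "pNMD", "v2": "dNMD"}
        assert (out.tissue == "toy").all()


class TestQuantileConfirmation:
    @staticmethod
    def _pnmd_data(n=300, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, n).astype(float)
        nmd = 30 + 3.0 * g + rng.normal(0, 2, n)
        non = 140 - 8.0 * g + rng.normal(0, 2, n)
        return nmd, non, g

    def test_median_regression_slope(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.4, 400).astype(float)
        y = 5.0 + 2.0 * g + rng.laplace(0, 1, 400)
        b, p = classify.median_regression(y, g)
        assert b == pytest.approx(2.0, abs=0.3)
        assert p < 1e-6

    def test_pnmd_confirmed(self):
        nmd, non, g = self._pnmd_data()
        assert classify.quantile_confirm(nmd, non, g, label="pNMD")

    def test_pnmd_rejects_same_sign(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, 300).astype(float)
        nmd = 30 + 3.0 * g + rng.normal(0, 2, 300)
        non = 140 + 8.0 * g + rng.normal(0, 2, 300)
        assert not classify.quantile_confirm(nmd, non, g, label="pNMD")

    def test_pnmd_rejects_larger_nmd_magnitude(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, 300).astype(float)
        nmd = 30 + 9.0 * g + rng.normal(0, 2, 300)
        non = 140 - 3.0 * g + rng.normal(0, 2, 300)
        assert not classify.quantile_confirm(nmd, non, g, label="pNMD")

    def test_degenerate_phenotype_not_confirmed(self):
        g = np.array([0.0, 1, 2] * 10)
        flat = np.full(30, 5.0)
        assert not classify.quantile_confirm(flat, flat + 1, g, label="pNMD")

    def test_unknown_label(self):
        nmd, non, g = self._pnmd_data()
        with pytest.raises(ValueError):
            classify.quantile_confirm(nmd, non, g, label="eQTL")


class TestInterpretSign:
    def test_directions(self):
        assert "NMD" in classify.interpret_sign("pNMD", 1.0)
        assert classify.interpret_sign("pNMD", 1.0) != classify.interpret_sign(
            "pNMD", -1.0
        )
        assert classify.interpret_sign("dNMD", 1.0) != classify.interpret_sign(
            "dNMD", -1.0
        )
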