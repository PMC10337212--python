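"""Shared fixtures: toy genome resources and a two-tissue toy QTL pipeline."""

import numpy as np
import pandas as pd
import pytest

from nmdqtl import annotation, classify, mapping, prep, simulate


@pytest.fixture(scope="session")
def toy():
    return simulate.generate_toy_resources(seed=0)


@pytest.fixture(scope="session")
def toy_genes(toy):
    return annotation.parse_gtf(toy.gtf_text.splitlines())


def run_tissue_pipeline(
    genes,
    toy,
    seed,
    n_samples=80,
    permute=(200, 2000),
    tissue=None,
):
    """simulate TPM -> group channels -> normalize -> cis-map -> classify."""
    tpm, tx_gene, X, truth = simulate.simulate_tissue_tpm(
        genes, toy.variant_positions, n_samples, seed=seed
    )
    nmd, non = prep.group_transcript_tpm(tpm, genes)
    nmd_int, non_int, factors = prep.prepare_channels(nmd, non)
    genotypes = pd.DataFrame(
        X,
        index=toy.variant_positions.variant_id.to_numpy(),
        columns=tpm.columns,
    )
    res_nmd = mapping.map_cis(
        nmd_int, genotypes, toy.variant_positions, genes,
        channel="nmd", permute=permute, seed=seed,
    )
    res_non = mapping.map_cis(
        non_int, genotypes, toy.variant_positions, genes,
        channel="non", permute=permute, seed=seed,
    )
    calls = classify.classify_table(
        res_nmd, res_non, tissue=tissue or f"T{seed}"
    )
    return {
        "tpm": tpm,
        "tx_gene": tx_gene,
        "genotypes": genotypes,
        "truth": truth,
        "res_nmd": res_nmd,
        "res_non": res_non,
        "calls": calls,
        "nmd_raw": nmd,
        "non_raw": non,
        "nmd_int": nmd_int,
        "non_int": non_int,
    }


@pytest.fixture(scope="session")
def two_tissues(toy, toy_genes):
    return {s: run_tissue_pipeline(toy_genes, toy, s) for s in (11, 12)}
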