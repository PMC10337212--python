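"""Shared helpers for the numbered analysis drivers."""

import pathlib

import pandas as pd

from nmdqtl import annotation, classify, mapping, prep, simulate

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def load_toy(seed: int = 0):
    toy = simulate.generate_toy_resources(seed=seed)
    genes = annotation.parse_gtf(toy.gtf_text.splitlines())
    return toy, genes


def run_tissue_pipeline(genes, toy, seed, tissue, n_samples=80, permute=(200, 2000)):
    """simulate TPM -> group channels -> normalize -> cis-map -> classify."""
    tpm, tx_gene, X, truth = simulate.simulate_tissue_tpm(
        genes, toy.variant_positions, n_samples, seed=seed
    )
    nmd, non = prep.group_transcript_tpm(tpm, genes)
    nmd_int, non_int, factors = prep.prepare_channels(nmd, non)
    genotypes = pd.DataFrame(
        X, index=toy.variant_positions.variant_id.to_numpy(), columns=tpm.columns
    )
    res_nmd = mapping.map_cis(
        nmd_int, genotypes, toy.variant_positions, genes,
        channel="nmd", permute=permute, seed=seed,
    )
    res_non = mapping.map_cis(
        non_int, genotypes, toy.variant_positions, genes,
        channel="non", permute=permute, seed=seed,
    )
    calls = classify.classify_table(res_nmd, res_non, tissue=tissue)
    return {
        "tpm": tpm,
        "tx_gene": tx_gene,
        "genotypes": genotypes,
        "truth": truth,
        "res_nmd": res_nmd,
        "res_non": res_non,
        "calls": calls,
    }


def write_tsv(df: pd.DataFrame, name: str) -> pathlib.Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False)
    print(f"wrote {path} ({len(df)} rows)")
    return path
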