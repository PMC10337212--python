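#!/usr/bin/env python
"""Splicing-QTL mapping from cassette-exon inclusion ratios and its overlap
with NMD-QTL calls, including the gene-level AS-NMD coupling contingency."""

import pandas as pd

from _common import load_toy, run_tissue_pipeline, write_tsv
from nmdqtl import annotation, splicing


def main() -> None:
    toy, genes = load_toy()
    t = run_tissue_pipeline(genes, toy, seed=11, tissue="tissueA")

    cassettes = [ce for g in genes for ce in annotation.find_cassette_exons(g)]
    ratios = splicing.inclusion_ratio_matrix(t["tpm"], cassettes)
    res = splicing.map_splicing_qtls(
        ratios, t["genotypes"], toy.variant_positions, genes
    )
    write_tsv(res, "08_splicing_mapping.tsv")

    splicing_calls = res[res.q <= 0.05]
    nmd_calls = t["calls"]
    # eQTL stand-in: nominally significant non-channel associations that are
    # not NMD-QTL calls
    eqtl = t["res_non"][
        (t["res_non"].q <= 0.05)
        & ~t["res_non"].variant_id.isin(nmd_calls.variant_id)
    ][["variant_id"]]
    if len(eqtl) == 0:
        eqtl = pd.DataFrame({"variant_id": ["none_placeholder"]})
    overlap = splicing.overlap_with_nmdqtls(splicing_calls, nmd_calls, eqtl)
    write_tsv(overlap, "08_overlap_with_nmdqtls.tsv")

    genes_with_overlap = set(
        nmd_calls[nmd_calls.variant_id.isin(splicing_calls.variant_id)].gene_id
    )
    table, oratio, p = splicing.coupling_contingency(genes, genes_with_overlap)
    write_tsv(
        pd.DataFrame(
            [
                {
                    "a_coupled_overlap": table.a,
                    "b_coupled_no_overlap": table.b,
                    "c_uncoupled_overlap": table.c,
                    "d_uncoupled_no_overlap": table.d,
                    "odds_ratio": oratio,
                    "p_fisher": p,
                }
            ]
        ),
        "08_coupling_contingency.tsv",
    )
    print(f"coupling contingency OR={oratio:.2f} p={p:.3g}")


if __name__ == "__main__":
    main()
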