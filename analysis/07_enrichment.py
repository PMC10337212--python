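#!/usr/bin/env python
"""Enrichment of toy NMD-QTL calls: disease-SNP overlap with Fisher odds
ratios, MeSH-style per-term scores, and factor (track) ranking with the
de-enrichment test."""

import pandas as pd

from _common import load_toy, run_tissue_pipeline, write_tsv
from nmdqtl import enrich


def main() -> None:
    toy, genes = load_toy()
    calls = run_tissue_pipeline(genes, toy, seed=11, tissue="tissueA")["calls"]
    qtl_ids = list(calls.variant_id.unique())
    disease_ids = set(toy.disease_snps.snp_id)
    all_ids = list(toy.variant_positions.variant_id)
    non_qtl = [v for v in all_ids if v not in set(qtl_ids)]

    count, frac = enrich.overlap_proportion(qtl_ids, disease_ids)
    bg_count, bg_frac = enrich.overlap_proportion(non_qtl, disease_ids)
    table = enrich.OverlapTable(
        count, len(qtl_ids) - count, bg_count, len(non_qtl) - bg_count
    )
    oratio, p, corrected = enrich.fisher_odds_ratio(table)
    write_tsv(
        pd.DataFrame(
            [
                {
                    "n_qtls": len(qtl_ids),
                    "n_overlap": count,
                    "proportion": frac,
                    "background_proportion": bg_frac,
                    "odds_ratio": oratio,
                    "p_fisher": p,
                    "haldane_corrected": corrected,
                }
            ]
        ),
        "07_disease_overlap.tsv",
    )

    mesh = enrich.mesh_overlap_score(qtl_ids, toy.disease_snps)
    write_tsv(pd.DataFrame([m.__dict__ for m in mesh]), "07_mesh_scores.tsv")

    vpos = toy.variant_positions.set_index("variant_id")
    qtl_pos = pd.DataFrame(
        {
            "chrom": [vpos.loc[v, "chrom"] for v in qtl_ids],
            "pos": [int(vpos.loc[v, "pos"]) for v in qtl_ids],
        }
    )
    ranking = enrich.factor_ranking(qtl_pos, toy.bed_tracks, top_k=2)
    write_tsv(ranking, "07_factor_ranking.tsv")
    print(ranking.to_string(index=False))


if __name__ == "__main__":
    main()
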