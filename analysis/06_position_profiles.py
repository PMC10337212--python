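#!/usr/bin/env python
"""Positional annotation of toy NMD-QTL calls: gene-body location model,
ordinal exon/intron profiles, boundary and TSS distances, and distances to
each isoform's stop codon."""

import pandas as pd

from _common import load_toy, run_tissue_pipeline, write_tsv
from nmdqtl import positions


def main() -> None:
    toy, genes = load_toy()
    calls = run_tissue_pipeline(genes, toy, seed=11, tissue="tissueA")["calls"]
    vpos = toy.variant_positions.set_index("variant_id")
    calls = calls.assign(
        chrom=[vpos.loc[v, "chrom"] for v in calls.variant_id],
        pos=[int(vpos.loc[v, "pos"]) for v in calls.variant_id],
    )

    # density profiles use every tested variant (the classified calls alone
    # are too sparse to populate per-rank counts on the toy genome)
    tested = toy.variant_positions.copy()
    counts, fit = positions.count_in_out_and_fit(tested, genes)
    write_tsv(
        pd.DataFrame([c.__dict__ for c in counts]), "06_gene_location_counts.tsv"
    )
    print(f"location model: w0={fit.w0:.3f} w1={fit.w1:.3f} w2={fit.w2:.3f}")

    for kind in ("exon", "intron"):
        for end in ("5", "3"):
            tab = positions.ordinal_distribution(tested, genes, end=end, kind=kind)
            write_tsv(tab, f"06_ordinal_{kind}_{end}prime.tsv")

    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    stop_rows = []
    for call in calls.itertuples():
        gene = gene_by_id[call.gene_id]
        dist, kind, stratum = positions.boundary_and_tss_distances(call.pos, gene)
        rows.append(
            {
                "variant_id": call.variant_id,
                "gene_id": call.gene_id,
                "label": call.label,
                "boundary_distance": dist,
                "interval_kind": kind,
                "tss_stratum": stratum,
            }
        )
        sc = positions.stop_codon_distances(call.pos, gene)
        sc.insert(0, "variant_id", call.variant_id)
        sc.insert(1, "gene_id", call.gene_id)
        stop_rows.append(sc)
    write_tsv(pd.DataFrame(rows), "06_boundary_tss_distances.tsv")
    write_tsv(pd.concat(stop_rows, ignore_index=True), "06_stop_codon_distances.tsv")


if __name__ == "__main__":
    main()
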