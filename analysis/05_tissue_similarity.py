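#!/usr/bin/env python
"""Tissue-similarity network and sign-consistency summary over four simulated
toy tissues."""

import pandas as pd

from _common import RESULTS, load_toy, run_tissue_pipeline, write_tsv
from nmdqtl import similarity


def main() -> None:
    toy, genes = load_toy()
    calls = pd.concat(
        [
            run_tissue_pipeline(genes, toy, seed=40 + i, tissue=f"tissue{i}")["calls"]
            for i in range(4)
        ],
        ignore_index=True,
    )
    write_tsv(calls, "05_multi_tissue_calls.tsv")

    mat, edges = similarity.similarity_matrix(calls)
    RESULTS.mkdir(parents=True, exist_ok=True)
    mat.to_csv(RESULTS / "05_similarity_matrix.tsv", sep="\t")
    print(f"wrote {RESULTS / '05_similarity_matrix.tsv'}")
    write_tsv(edges, "05_similarity_edges.tsv")

    per_qtl, summary = similarity.sharing_and_sign_consistency(
        calls, min_tissues=1
    )
    write_tsv(per_qtl, "05_sharing_sign_consistency.tsv")
    print(summary)


if __name__ == "__main__":
    main()
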