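"""Genomic-position annotation of QTL calls.

Gene-body membership and the inside/outside linear model, strand-aware
ordinal ranks of collapsed exon/intron intervals with count- and
length-normalized QTL distributions, base-pair distances to interval
boundaries, TSS distance strata, and spliced/genomic distances to stop
codons (PTCs for NMD isoforms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotation import GeneModel

__all__ = [
    "GeneLocationCounts",
    "LocationModelFit",
    "count_in_out_and_fit",
    "ordinal_ranks",
    "ordinal_distribution",
    "boundary_and_tss_distances",
    "stop_codon_distances",
    "TSS_STRATA",
]

# distance-from-TSS strata (bp upper bounds)
TSS_STRATA = ((100_000, "<100k"), (500_000, "100-500k"), (1_000_000, "500k-1M"))


@dataclass
class GeneLocationCounts:
    gene_id: str
    n_in: int
    n_out: int
    gene_length: int


@dataclass
class LocationModelFit:
    w0: float
    w1: float
    w2: float
    conf_int: np.ndarray  # 3 × 2 (w0, w1, w2 rows)


def count_in_out_and_fit(
    calls: pd.DataFrame, genes, window: int = 1_000_000
) -> tuple[list[GeneLocationCounts], LocationModelFit]:
    """Counts of QTLs inside vs outside each gene body and the OLS fit
    N_in = w0 + w1·N_out + w2·log2(gene_length).

    "Outside" is restricted to the gene's cis window around the TSS (an
    unbounded outside is ill-defined per gene). ``calls`` needs chrom/pos
    columns.
    """
    counts = []
    for g in genes:
        sub = calls[calls.chrom == g.chrom]
        span_lo, span_hi = g.span
        inside = ((sub.pos >= span_lo) & (sub.pos < span_hi)).sum()
        in_window = (sub.pos - g.tss).abs() <= window
        outside = int(in_window.sum() - inside)
        counts.append(
            GeneLocationCounts(
                gene_id=g.gene_id,
                n_in=int(inside),
                n_out=outside,
                gene_length=g.gene_length,
            )
        )
    if len(counts) < 3:
        raise ValueError("need >= 3 genes to fit the location model")
    X = np.column_stack(
        [
            [c.n_out for c in counts],
            [np.log2(c.gene_length) for c in counts],
        ]
    )
    y = np.array([c.n_in for c in counts], dtype=float)
    # always keep the intercept column, even when a regressor is constant
    design = np.column_stack([np.ones(len(y)), X])
    fit = sm.OLS(y, design).fit()
    return counts, LocationModelFit(
        w0=float(fit.params[0]),
        w1=float(fit.params[1]),
        w2=float(fit.params[2]),
        conf_int=np.asarray(fit.conf_int()),
    )


def ordinal_ranks(gene: GeneModel) -> pd.DataFrame:
    """Strand-aware ordinal ranks (from 5' and from 3', starting at 0) for
    each collapsed exon and intron interval.

    For k intervals of a kind, rank5 + rank3 = k − 1 for every interval.
    """
    rows = []
    for kind, ivs in (("exon", gene.collapsed_exons), ("intron", gene.collapsed_introns)):
        k = len(ivs)
        for idx, (s, e) in enumerate(ivs):
            rank5 = idx if gene.strand == "+" else k - 1 - idx
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "kind": kind,
                    "start": s,
                    "end": e,
                    "length": e - s,
                    "rank5": rank5,
                    "rank3": k - 1 - rank5,
                }
            )
    return pd.DataFrame(rows)


def _assign_calls_to_intervals(calls: pd.DataFrame, genes) -> pd.DataFrame:
    """One row per (call, containing collapsed interval)."""
    tables = []
    for g in genes:
        ivs = ordinal_ranks(g)
        sub = calls[calls.chrom == g.chrom]
        if not len(sub) or not len(ivs):
            continue
        for iv in ivs.itertuples():
            hit = sub[(sub.pos >= iv.start) & (sub.pos < iv.end)]
            for call in hit.itertuples():
                tables.append(
                    {
                        "variant_id": call.variant_id,
                        "gene_id": g.gene_id,
                        "kind": iv.kind,
                        "rank5": iv.rank5,
                        "rank3": iv.rank3,
                        "length": iv.length,
                    }
                )
    return pd.DataFrame(
        tables,
        columns=["variant_id", "gene_id", "kind", "rank5", "rank3", "length"],
    )


def ordinal_distribution(
    calls: pd.DataFrame, genes, end: str = "3", kind: str = "exon"
) -> pd.DataFrame:
    """QTL counts per ordinal rank with count- and length-normalization.

    Per rank: raw QTL count, the number of intervals occupying that rank
    (over genes with ≥1 assigned QTL), their median length, raw/interval
    count, and raw/interval count/median length. Ranks with zero intervals
    are omitted.
    """
    if end not in {"5", "3"}:
        raise ValueError("end must be '5' or '3'")
    rank_col = f"rank{end}"
    assigned = _assign_calls_to_intervals(calls, genes)
    genes_with_calls = set(assigned.gene_id.unique())
    ivs = pd.concat(
        [ordinal_ranks(g) for g in genes if g.gene_id in genes_with_calls],
        ignore_index=True,
    ) if genes_with_calls else pd.DataFrame(columns=["kind", "rank5", "rank3", "length"])

    ivs = ivs[ivs.kind == kind]
    sub = assigned[assigned.kind == kind]
    rows = []
    for rank, grp in ivs.groupby(rank_col):
        n_intervals = len(grp)
        med_len = float(grp.length.median())
        raw = int((sub[rank_col] == rank).sum())
        count_norm = raw / n_intervals
        rows.append(
            {
                "rank": int(rank),
                "raw_count": raw,
                "n_intervals": n_intervals,
                "median_length": med_len,
                "count_normalized": count_norm,
                "fully_normalized": count_norm / med_len if med_len > 0 else np.nan,
            }
        )
    cols = [
        "rank",
        "raw_count",
        "n_intervals",
        "median_length",
        "count_normalized",
        "fully_normalized",
    ]
    return pd.DataFrame(rows, columns=cols).sort_values("rank", ignore_index=True)


def boundary_and_tss_distances(
    pos: int, gene: GeneModel, window: int = 1_000_000
) -> tuple[int | None, str | None, str | None]:
    """(distance to the containing interval's nearest boundary, interval
    kind, TSS stratum) for one call position.

    The boundary distance is min(pos − start, end − 1 − pos) within the
    containing collapsed exon or intron; None when the call is not inside
    the gene body. The TSS stratum uses |pos − TSS| cut at 100 kb / 500 kb /
    1 Mb; None beyond the window.
    """
    dist = None
    kind_hit = None
    for kind, ivs in (("exon", gene.collapsed_exons), ("intron", gene.collapsed_introns)):
        for s, e in ivs:
            if s <= pos < e:
                dist = int(min(pos - s, e - 1 - pos))
                kind_hit = kind
                break
        if dist is not None:
            break
    d_tss = abs(pos - gene.tss)
    stratum = None
    if d_tss <= window:
        for ub, name in TSS_STRATA:
            if d_tss < ub or (ub == window and d_tss <= ub):
                stratum = name
                break
    return dist, kind_hit, stratum


def stop_codon_distances(pos: int, gene: GeneModel) -> pd.DataFrame:
    """Signed distances from one call to each isoform's stop codon.

    One record per transcript with an annotated stop (the PTC for NMD
    isoforms). ``exonic_distance`` counts only exonic (spliced) positions
    and is None for intronic calls; ``genomic_distance`` counts all bases.
    Sign: negative upstream of the stop in transcript orientation, anchored
    at the stop codon's first base (distance 0 there).
    """
    rows = []
    for t in gene.transcripts:
        if t.cds_end is None:
            continue
        stop_spliced = t.spliced_position(t.cds_end)
        var_spliced = t.spliced_position(pos)
        exonic = (
            None
            if var_spliced is None or stop_spliced is None
            else int(var_spliced - stop_spliced)
        )
        genomic = pos - t.cds_end if t.strand == "+" else t.cds_end - pos
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "nmd_flag": t.nmd_flag,
                "exonic_distance": exonic,
                "genomic_distance": int(genomic),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "nmd_flag", "exonic_distance", "genomic_distance"],
    )
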