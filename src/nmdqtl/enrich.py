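"""Overlap/enrichment statistics of QTL sets against disease SNPs, MeSH
disease classes, and genomic interval tracks (miRNA targets, RBP binding
sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import collapse_intervals

__all__ = [
    "OverlapTable",
    "MeshScore",
    "overlap_proportion",
    "fisher_odds_ratio",
    "pooled_disease_tests",
    "mesh_overlap_score",
    "factor_ranking",
    "positions_in_track",
]


@dataclass
class OverlapTable:
    a: int  # QTLs overlapping the feature
    b: int  # QTLs not overlapping
    c: int  # comparison set overlapping
    d: int  # comparison set not overlapping

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class MeshScore:
    term: str
    overlap: int
    total_qtls: int
    total_term_snps: int
    score: float


def _merge_track(track: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    out = {}
    for chrom, sub in track.groupby("chrom"):
        out[chrom] = collapse_intervals(zip(sub.start.astype(int), sub.end.astype(int)))
    return out


def positions_in_track(positions: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Boolean mask: which (chrom, pos) rows fall inside the merged track."""
    merged = _merge_track(track)
    mask = np.zeros(len(positions), dtype=bool)
    for i, row in enumerate(positions.itertuples()):
        for s, e in merged.get(row.chrom, ()):
            if s <= row.pos < e:
                mask[i] = True
                break
    return mask


def overlap_proportion(qtls, features) -> tuple[int, float]:
    """Count and fraction of QTLs overlapping a feature set.

    ``features`` may be a set of variant IDs (``qtls`` then an iterable of
    IDs) or an interval-track DataFrame (``qtls`` then a DataFrame with
    chrom/pos).
    """
    if isinstance(features, pd.DataFrame):
        if len(qtls) == 0:
            raise ValueError("empty QTL set")
        count = int(positions_in_track(qtls, features).sum())
        total = len(qtls)
    else:
        ids = list(qtls)
        if not ids:
            raise ValueError("empty QTL set")
        fset = set(features)
        count = sum(1 for v in ids if v in fset)
        total = len(ids)
    return count, count / total


def fisher_odds_ratio(table: OverlapTable) -> tuple[float, float, bool]:
    """Cross-product odds ratio and two-sided Fisher exact p-value.

    A zero cell gets the Haldane 0.5 continuity correction for the OR (the
    p-value stays exact); the returned flag marks the correction.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    _or_sample, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), float(p), corrected


def pooled_disease_tests(
    n_qtls: int,
    n_qtls_overlap: int,
    n_comparison: int,
    n_comparison_overlap: int,
    background_size: int,
    term_size: int,
    n_qtls_nonredundant: int,
    n_overlap_nonredundant: int,
) -> tuple[float, float]:
    """Disease-SNP overlap significance: proportion test + hypergeometric.

    The proportion test compares the tissue-pooled overlap rate of the QTL
    set (with multiplicity: a QTL found in several tissues counts several
    times) against the comparison set's rate, via a two-sample pooled-
    variance z-test. The hypergeometric test is an upper-tail draw of the
    nonredundant QTL set from the tested-variant background against the
    disease-term SNPs.
    """
    if background_size < n_qtls_nonredundant:
        raise ValueError("background smaller than the QTL set")
    p1 = n_qtls_overlap / n_qtls
    p2 = n_comparison_overlap / n_comparison
    pool = (n_qtls_overlap + n_comparison_overlap) / (n_qtls + n_comparison)
    se = np.sqrt(pool * (1 - pool) * (1 / n_qtls + 1 / n_comparison))
    if se == 0:
        p_prop = 1.0
    else:
        z = (p1 - p2) / se
        p_prop = float(2 * stats.norm.sf(abs(z)))
    p_hyper = float(
        stats.hypergeom.sf(
            n_overlap_nonredundant - 1, background_size, term_size, n_qtls_nonredundant
        )
    )
    return p_prop, p_hyper


def mesh_overlap_score(
    qtl_ids, disease_snps: pd.DataFrame
) -> list[MeshScore]:
    """Per-MeSH-term overlap enrichment score.

    score = (#QTLs that are disease SNPs of the term)
            / (total QTLs × total term disease SNPs).
    Terms with zero SNPs are omitted.
    """
    ids = set(qtl_ids)
    total = len(list(qtl_ids))
    out = []
    for term, sub in disease_snps.groupby("mesh_class"):
        term_snps = set(sub.snp_id)
        if not term_snps:
            continue
        overlap = len(ids & term_snps)
        out.append(
            MeshScore(
                term=str(term),
                overlap=overlap,
                total_qtls=total,
                total_term_snps=len(term_snps),
                score=overlap / (total * len(term_snps)),
            )
        )
    return sorted(out, key=lambda m: -m.score)


def factor_ranking(
    qtl_positions: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
    top_k: int = 20,
) -> pd.DataFrame:
    """Rank interval-track factors by QTLs per base pair of (merged) track,
    with a binomial de-enrichment test.

    A variant counts once per factor regardless of how many of the factor's
    peaks contain it. The de-enrichment test asks, among QTLs falling in any
    track, whether a factor's share of those QTLs is below its share of the
    total track length (one-sided binomial).
    """
    rows = []
    merged_lengths = {}
    in_factor = {}
    for name, track in tracks.items():
        merged = _merge_track(track)
        length = sum(e - s for ivs in merged.values() for s, e in ivs)
        if length == 0:
            continue
        merged_lengths[name] = length
        in_factor[name] = positions_in_track(qtl_positions, track)
    total_len = sum(merged_lengths.values())
    any_track = (
        np.column_stack(list(in_factor.values())).any(axis=1)
        if in_factor
        else np.zeros(len(qtl_positions), dtype=bool)
    )
    n_in_any = int(any_track.sum())
    for name, length in merged_lengths.items():
        k = int(in_factor[name].sum())
        bp_share = length / total_len
        if n_in_any > 0:
            test = stats.binomtest(k, n_in_any, bp_share, alternative="less")
            p_deenrich = float(test.pvalue)
        else:
            p_deenrich = float("nan")
        rows.append(
            {
                "factor": name,
                "n_qtls": k,
                "track_bp": length,
                "rate_per_bp": k / length,
                "bp_share": bp_share,
                "qtl_share": k / n_in_any if n_in_any else np.nan,
                "p_deenrichment": p_deenrich,
            }
        )
    out = pd.DataFrame(rows).sort_values("rate_per_bp", ascending=False, ignore_index=True)
    out["top_k"] = out.index < top_k
    return out
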