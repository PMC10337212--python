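"""Cross-tissue NMD-QTL signature similarity and sharing summaries.

The directed score compares the odds of observing tissue j's QTLs in
tissue i against the odds of observing them among all nonredundant QTLs:

    s_ij = [ n_ij / (n_i − n_ij) ] / [ n_j / (n − n_j) ]

and the symmetric signature score is s* = (s_ij + s_ji) / 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityScore",
    "similarity",
    "similarity_matrix",
    "edge_category",
    "sharing_and_sign_consistency",
]


@dataclass
class SimilarityScore:
    n_ij: int
    n_i: int
    n_j: int
    n_total: int
    s_ij: float
    s_ji: float
    s_star: float


def _directed(n_ij: int, n_i: int, n_j: int, n_total: int) -> float:
    if n_ij == 0:
        return 0.0
    if n_ij == n_i or n_j == n_total:
        warnings.warn("degenerate denominator in similarity; +inf sentinel")
        return math.inf
    return (n_ij / (n_i - n_ij)) / (n_j / (n_total - n_j))


def similarity(n_ij: int, n_i: int, n_j: int, n_total: int) -> SimilarityScore:
    """Similarity of two tissues' QTL sets from their overlap counts."""
    if not (0 <= n_ij <= min(n_i, n_j) <= n_total):
        raise ValueError("count invariants violated")
    s_ij = _directed(n_ij, n_i, n_j, n_total)
    s_ji = _directed(n_ij, n_j, n_i, n_total)
    return SimilarityScore(
        n_ij=n_ij, n_i=n_i, n_j=n_j, n_total=n_total,
        s_ij=s_ij, s_ji=s_ji, s_star=(s_ij + s_ji) / 2.0,
    )


def edge_category(s_star: float) -> str:
    """Similarity-network edge bins: none < 10 ≤ black < 20 ≤ orange < 30 ≤ red."""
    if s_star < 0:
        raise ValueError("s_star must be >= 0")
    if s_star < 10:
        return "none"
    if s_star < 20:
        return "black"
    if s_star < 30:
        return "orange"
    return "red"


def _qtl_keys(calls: pd.DataFrame, variant_only: bool) -> pd.Series:
    if variant_only:
        return calls.variant_id.astype(str)
    return (
        calls.variant_id.astype(str)
        + "|" + calls.gene_id.astype(str)
        + "|" + calls.label.astype(str)
    )


def similarity_matrix(
    calls: pd.DataFrame, variant_only: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue × tissue s* matrix and an edge list.

    ``calls``: concatenated call table with a ``tissue`` column. QTL identity
    defaults to the (variant, gene, label) triple; ``variant_only`` relaxes
    it to the variant alone.
    """
    keys = _qtl_keys(calls, variant_only)
    per_tissue = {t: set(keys[calls.tissue == t]) for t in calls.tissue.unique()}
    n_total = len(set().union(*per_tissue.values()))
    tissues = sorted(per_tissue)
    mat = pd.DataFrame(np.nan, index=tissues, columns=tissues)
    edges = []
    for i, ti in enumerate(tissues):
        mat.loc[ti, ti] = math.inf
        for tj in tissues[i + 1:]:
            sc = similarity(
                len(per_tissue[ti] & per_tissue[tj]),
                len(per_tissue[ti]),
                len(per_tissue[tj]),
                n_total,
            )
            mat.loc[ti, tj] = mat.loc[tj, ti] = sc.s_star
            edges.append(
                {
                    "tissue_i": ti,
                    "tissue_j": tj,
                    "n_ij": sc.n_ij,
                    "s_star": sc.s_star,
                    "edge": edge_category(sc.s_star) if np.isfinite(sc.s_star) else "red",
                }
            )
    return mat, pd.DataFrame(edges)


def sharing_and_sign_consistency(
    calls: pd.DataFrame,
    group_map: dict[str, str] | None = None,
    min_tissues: int = 20,
    variant_only: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-QTL tissue-sharing counts and effect-sign consistency.

    ``group_map`` optionally collapses tissue labels (e.g. all brain
    sub-regions to one pseudo-tissue) before counting. A QTL is
    sign-consistent when every tissue it is detected in agrees on the sign
    of the NMD-channel slope. The summary fraction is restricted to QTLs
    detected in more than ``min_tissues`` (grouped) tissues.
    """
    if calls.tissue.nunique() < 2:
        raise ValueError("need calls from >= 2 tissues")
    df = calls.copy()
    if group_map:
        df["tissue"] = df.tissue.map(lambda t: group_map.get(t, t))
    df["qtl_key"] = _qtl_keys(df, variant_only)
    per = df.groupby("qtl_key").agg(
        n_tissues=("tissue", "nunique"),
        sign_consistent=("beta_nmd", lambda b: (b > 0).all() or (b < 0).all()),
    ).reset_index()
    wide = per[per.n_tissues > min_tissues]
    summary = {
        "n_qtls": int(len(per)),
        "min_tissues": min_tissues,
        "n_widely_shared": int(len(wide)),
        "frac_sign_consistent_all": float(per.sign_consistent.mean()) if len(per) else float("nan"),
        "frac_sign_consistent_widely_shared": (
            float(wide.sign_consistent.mean()) if len(wide) else float("nan")
        ),
    }
    return per, summary
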