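"""Two-channel expression preparation.

Per NMD gene (a gene with both NMD-tagged and untagged isoforms), transcript
TPMs are summed into an NMD channel and a non-NMD channel; channel matrices
are then depth-normalized with median-of-ratios size factors and each gene
row is mapped to normal scores with a rank-based inverse normal transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "group_transcript_tpm",
    "compute_size_factors",
    "inverse_normal_transform",
    "prepare_channels",
]


def group_transcript_tpm(
    tpm: pd.DataFrame, genes
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum transcript TPM into per-gene NMD and non-NMD channels.

    Parameters
    ----------
    tpm : transcript × sample table (index = transcript IDs).
    genes : iterable of GeneModel.

    Genes whose isoforms are all NMD-tagged or all untagged are excluded.
    Transcripts in the table but absent from the annotation raise an error
    listing the offending IDs.

    Returns (nmd, non) gene × sample DataFrames with identical indexes.
    """
    tx_to_gene: dict[str, str] = {}
    tx_flag: dict[str, bool] = {}
    gene_flags: dict[str, set[bool]] = {}
    for g in genes:
        for t in g.transcripts:
            tx_to_gene[t.transcript_id] = g.gene_id
            tx_flag[t.transcript_id] = t.nmd_flag
            gene_flags.setdefault(g.gene_id, set()).add(t.nmd_flag)

    missing = [tid for tid in tpm.index if tid not in tx_to_gene]
    if missing:
        raise KeyError(
            f"{len(missing)} transcripts absent from annotation: "
            + ", ".join(missing[:10])
        )

    keep = [gid for gid, flags in gene_flags.items() if flags == {True, False}]
    keep_set = set(keep)

    gene_ids = pd.Series({tid: tx_to_gene[tid] for tid in tpm.index})
    flags = pd.Series({tid: tx_flag[tid] for tid in tpm.index})
    in_scope = gene_ids.map(lambda g: g in keep_set)

    sub = tpm.loc[in_scope[in_scope].index]
    gsub = gene_ids.loc[sub.index]
    fsub = flags.loc[sub.index]

    nmd = sub[fsub].groupby(gsub[fsub]).sum()
    non = sub[~fsub].groupby(gsub[~fsub]).sum()
    idx = sorted(set(nmd.index) & set(non.index))
    nmd = nmd.loc[idx]
    non = non.loc[idx]
    nmd.index.name = non.index.name = "gene_id"
    return nmd, non


def compute_size_factors(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample/column).

    Per gene, the geometric mean across samples is the pseudo-reference
    (genes containing any zero are excluded); each sample's factor is the
    median over genes of value / pseudo-reference. Dividing a sample's
    column by its factor normalizes sequencing depth.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a genes × samples matrix with >= 2 samples")
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    allpos = (X > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with all-positive values; cannot normalize")
    L = np.log(X[allpos])
    geomean = L.mean(axis=1, keepdims=True)
    return np.exp(np.median(L - geomean, axis=0))


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform: Φ⁻¹((rank − 0.5) / n).

    Ties get average ranks; a constant vector maps to all zeros.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or np.sum(np.isfinite(v)) < 3:
        raise ValueError("need >= 3 finite values in a 1-d vector")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / v.size)


def prepare_channels(
    nmd: pd.DataFrame, non: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Normalize both channels with one shared set of size factors (both
    channels come from the same library) and inverse-normal transform each
    gene row per channel.

    Returns (nmd_int, non_int, size_factors).
    """
    if list(nmd.columns) != list(non.columns):
        raise ValueError("channel sample columns differ")
    stacked = pd.concat([nmd, non], axis=0)
    factors = compute_size_factors(stacked)
    nmd_n = nmd / factors
    non_n = non / factors
    nmd_int = nmd_n.apply(lambda row: inverse_normal_transform(row), axis=1, result_type="expand")
    non_int = non_n.apply(lambda row: inverse_normal_transform(row), axis=1, result_type="expand")
    nmd_int.columns = nmd.columns
    non_int.columns = non.columns
    return nmd_int, non_int, factors
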