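"""Splicing-QTL mapping from cassette-exon inclusion ratios and overlap
statistics with NMD-QTLs (AS-NMD coupling).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import CassetteExon, GeneModel, as_nmd_direct_coupling, find_cassette_exons
from .enrich import OverlapTable, fisher_odds_ratio
from .mapping import CollinearGenotypeError, compute_qvalues, fit_nominal
from .prep import inverse_normal_transform

__all__ = [
    "inclusion_ratio",
    "inclusion_ratio_matrix",
    "map_splicing_qtls",
    "overlap_with_nmdqtls",
    "coupling_contingency",
]


def inclusion_ratio(tpm_inc: np.ndarray, tpm_exc: np.ndarray) -> np.ndarray:
    """Per-sample cassette-exon inclusion ratio.

    ΣTPM(including isoforms) / (ΣTPM(including) + ΣTPM(excluding)); NaN when
    both sums are zero (the sample is dropped from mapping).
    """
    inc = np.atleast_2d(np.asarray(tpm_inc, dtype=float))
    exc = np.atleast_2d(np.asarray(tpm_exc, dtype=float))
    if (inc < 0).any() or (exc < 0).any():
        raise ValueError("negative TPM")
    si = inc.sum(axis=0)
    se = exc.sum(axis=0)
    denom = si + se
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, si / denom, np.nan)
    return ratio


def inclusion_ratio_matrix(
    tpm: pd.DataFrame, cassettes: list[CassetteExon]
) -> pd.DataFrame:
    """Cassette × sample inclusion-ratio table from transcript TPM."""
    rows = {}
    for ce in cassettes:
        inc_ids = [t for t in ce.inc_transcripts if t in tpm.index]
        exc_ids = [t for t in ce.exc_transcripts if t in tpm.index]
        if not inc_ids or not exc_ids:
            continue
        key = f"{ce.gene_id}:{ce.interval[0]}-{ce.interval[1]}"
        rows[key] = inclusion_ratio(
            tpm.loc[inc_ids].to_numpy(), tpm.loc[exc_ids].to_numpy()
        )
    return pd.DataFrame(rows, index=tpm.columns).T


def map_splicing_qtls(
    ratios: pd.DataFrame,
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    genes,
    covariates: pd.DataFrame | None = None,
    window: int = 1_000_000,
    min_nonmissing: float = 0.7,
) -> pd.DataFrame:
    """Cis scan of inclusion ratios (channel = "splicing").

    Ratios are inverse-normal transformed; samples with missing ratios are
    dropped listwise per cassette exon (from phenotype and genotype alike).
    Cassette phenotypes with fewer than ``min_nonmissing`` non-missing
    samples or no variance are skipped. q-values are computed across all
    tested pairs.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for key in ratios.index:
        gid = key.split(":")[0]
        g = gene_by_id.get(gid)
        if g is None:
            continue
        y_raw = ratios.loc[key]
        ok = y_raw.notna()
        if ok.mean() < min_nonmissing:
            continue
        y = y_raw[ok]
        if np.allclose(y, y.iloc[0]):
            continue
        y_int = inverse_normal_transform(y.to_numpy())
        samples = list(y.index)
        sub_vars = variants[
            (variants.chrom == g.chrom) & ((variants.pos - g.tss).abs() <= window)
        ]
        cov = covariates.loc[samples].to_numpy() if covariates is not None else None
        for v in sub_vars.itertuples():
            if v.variant_id not in genotypes.index:
                continue
            dose = genotypes.loc[v.variant_id, samples].to_numpy(dtype=float)
            try:
                beta, se, p = fit_nominal(y_int, dose, cov)
            except CollinearGenotypeError:
                continue
            rows.append(
                {
                    "variant_id": v.variant_id,
                    "gene_id": gid,
                    "cassette": key,
                    "channel": "splicing",
                    "beta": beta,
                    "se": se,
                    "p_nominal": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = compute_qvalues(out.p_nominal.to_numpy())
    return out


def overlap_with_nmdqtls(
    splicing_calls: pd.DataFrame,
    nmd_calls: pd.DataFrame,
    eqtl_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Odds of NMD-QTLs (vs eQTLs) also being splicing-QTLs.

    One Fisher 2×2 per NMD-QTL class: rows {class QTLs, eQTLs}, columns
    {overlaps a splicing-QTL variant, does not}. Classes with no calls are
    omitted with a warning.
    """
    import warnings

    spl = set(splicing_calls.variant_id)
    eq = set(eqtl_calls.variant_id)
    rows = []
    for cls in ("pNMD", "dNMD"):
        ids = set(nmd_calls[nmd_calls.label == cls].variant_id)
        if not ids:
            warnings.warn(f"no {cls} calls; class omitted")
            continue
        a = len(ids & spl)
        b = len(ids - spl)
        c = len(eq & spl)
        d = len(eq - spl)
        oratio, p, corrected = fisher_odds_ratio(OverlapTable(a, b, c, d))
        rows.append(
            {
                "comparison": f"{cls} vs eQTL",
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": oratio,
                "p_fisher": p,
                "haldane_corrected": corrected,
            }
        )
    return pd.DataFrame(rows)


def coupling_contingency(
    genes: list[GeneModel],
    genes_with_overlap: set[str],
) -> tuple[OverlapTable, float, float]:
    """Gene-level 2×2 of {direct AS-NMD coupling} × {has a class-QTL that
    overlaps a splicing-QTL}, among NMD genes.

    Returns (table, odds ratio, Fisher p). Direct coupling means some
    cassette exon perfectly separates the gene's NMD from non-NMD isoforms.
    """
    nmd_genes = [g for g in genes if g.is_nmd_gene]
    coupled = set()
    for g in nmd_genes:
        for ce in find_cassette_exons(g):
            flags = {t.transcript_id: t.nmd_flag for t in g.transcripts}
            in_scope = {True, False} <= {
                flags[t] for t in (ce.inc_transcripts | ce.exc_transcripts)
            }
            if in_scope and as_nmd_direct_coupling(g, ce):
                coupled.add(g.gene_id)
                break
    a = sum(1 for g in nmd_genes if g.gene_id in coupled and g.gene_id in genes_with_overlap)
    b = sum(1 for g in nmd_genes if g.gene_id in coupled and g.gene_id not in genes_with_overlap)
    c = sum(1 for g in nmd_genes if g.gene_id not in coupled and g.gene_id in genes_with_overlap)
    d = sum(1 for g in nmd_genes if g.gene_id not in coupled and g.gene_id not in genes_with_overlap)
    table = OverlapTable(a, b, c, d)
    oratio, p, _ = fisher_odds_ratio(table)
    return table, oratio, p
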