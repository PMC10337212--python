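"""Decision rules labeling variants as pNMD-QTLs or dNMD-QTLs, plus the
quantile-regression confirmation step and effect-sign interpretation.

A pNMD-QTL shifts the fraction α of a gene's transcription that is
NMD-targeted: the two channels move in opposite directions. A dNMD-QTL
shifts the decay efficiency 1−θ: only the NMD channel moves, the non-NMD
channel stays null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "NmdQtlCall",
    "classify_from_qvalues",
    "classify_table",
    "quantile_confirm",
    "median_regression",
    "interpret_sign",
]

Q_SIG = 0.05          # significance gate on q-values
Q_NULL = 0.8          # null gate on the non-NMD channel (dNMD rule)
QR_SIG = 0.05         # quantile-regression significance gate
QR_NULL = 0.95        # quantile-regression null gate (dNMD rule)


@dataclass
class NmdQtlCall:
    variant_id: str
    gene_id: str
    tissue: str
    label: str  # "pNMD" | "dNMD"
    beta_nmd: float
    beta_non: float
    confirmed: bool = False

    @property
    def sign_nmd(self) -> str:
        return "+" if self.beta_nmd > 0 else "-"


def classify_from_qvalues(
    q_nmd: float, q_non: float, beta_nmd: float, beta_non: float
) -> str:
    """Candidate label from per-channel q-values and slopes.

    * pNMD-candidate: both channels significant (q ≤ 0.05) with
      opposite-signed slopes;
    * dNMD-candidate: NMD channel significant, non-NMD channel clearly null
      (q > 0.8);
    * otherwise "none" (including the 0.05 < q_non ≤ 0.8 gap zone).
    """
    for v in (q_nmd, q_non, beta_nmd, beta_non):
        if not np.isfinite(v):
            return "none"
    if q_nmd > Q_SIG:
        return "none"
    if beta_nmd == 0.0:
        logger.warning("q_nmd significant but beta_nmd == 0; sign undefined")
        return "none"
    if q_non <= Q_SIG:
        if beta_non == 0.0:
            logger.warning("q_non significant but beta_non == 0; sign undefined")
            return "none"
        if np.sign(beta_nmd) != np.sign(beta_non):
            return "pNMD-candidate"
        return "none"
    if q_non > Q_NULL:
        return "dNMD-candidate"
    return "none"


def classify_table(
    nmd_results: pd.DataFrame, non_results: pd.DataFrame, tissue: str = ""
) -> pd.DataFrame:
    """Apply the rules across merged per-pair result tables.

    Inputs are qtl-mapping outputs for the two channels (columns variant_id,
    gene_id, beta, q). Returns candidates with both channels' betas and
    q-values.
    """
    merged = nmd_results.merge(
        non_results,
        on=["variant_id", "gene_id"],
        suffixes=("_nmd", "_non"),
    )
    labels = [
        classify_from_qvalues(r.q_nmd, r.q_non, r.beta_nmd, r.beta_non)
        for r in merged.itertuples()
    ]
    merged = merged.assign(candidate=labels, tissue=tissue)
    out = merged[merged.candidate != "none"].copy()
    out["label"] = out.candidate.str.replace("-candidate", "", regex=False)
    return out


def median_regression(y, g, covariates=None):
    """Median (τ = 0.5) regression of y on dosage with optional covariates.

    Returns (slope, p-value) for the dosage term, using statsmodels'
    asymptotic (kernel-based) covariance.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    X = g[:, None] if covariates is None else np.column_stack([g, covariates])
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.QuantReg(y, X).fit(q=0.5)
    return float(fit.params[1]), float(fit.pvalues[1])


def quantile_confirm(
    tpm_nmd,
    tpm_non,
    g,
    covariates=None,
    label: str = "pNMD",
) -> bool:
    """Confirm a candidate with median regression on untransformed TPM.

    pNMD: both channel slopes significant (p ≤ 0.05), opposite signs, and
    the NMD-channel slope smaller in magnitude (the targeting fraction only
    redistributes part of the transcription between channels, and the
    NMD-channel share is further shrunk by decay).

    dNMD: NMD channel significant (p ≤ 0.05) and the non-NMD channel clearly
    null (p > 0.95).
    """
    tpm_nmd = np.asarray(tpm_nmd, dtype=float)
    tpm_non = np.asarray(tpm_non, dtype=float)
    if np.allclose(tpm_nmd, tpm_nmd[0]) or np.allclose(tpm_non, tpm_non[0]):
        logger.warning("degenerate phenotype; candidate not confirmed")
        return False
    b_nmd, p_nmd = median_regression(tpm_nmd, g, covariates)
    b_non, p_non = median_regression(tpm_non, g, covariates)
    if label.startswith("pNMD"):
        return (
            p_nmd <= QR_SIG
            and p_non <= QR_SIG
            and np.sign(b_nmd) != np.sign(b_non)
            and abs(b_nmd) < abs(b_non)
        )
    if label.startswith("dNMD"):
        return p_nmd <= QR_SIG and p_non > QR_NULL
    raise ValueError(f"unknown candidate label {label!r}")


def interpret_sign(label: str, beta_nmd: float) -> str:
    """Mechanistic reading of the NMD-channel effect sign.

    For a pNMD-QTL a positive slope means the alternate allele targets a
    larger fraction to NMD (α_alt > α_ref). For a dNMD-QTL a positive slope
    means more NMD-targeted transcripts survive, i.e. the alternate allele
    decays them less efficiently (1−θ_alt < 1−θ_ref).
    """
    if beta_nmd == 0:
        raise ValueError("sign undefined for beta_nmd == 0")
    pos = beta_nmd > 0
    if label == "pNMD":
        return "promotes_NMD_targeting" if pos else "inhibits_NMD_targeting"
    if label == "dNMD":
        return "inhibits_decay" if pos else "promotes_decay"
    raise ValueError(f"unknown label {label!r}")
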