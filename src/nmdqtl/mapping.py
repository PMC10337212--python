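"""Generic cis-QTL engine.

Per (variant, gene) pair: ordinary least squares of the phenotype on the
genotype dosage after residualizing both on covariates (Frisch–Waugh), a
two-sided t-test on the slope, a per-gene adaptive permutation p-value on
the minimum nominal p across the gene's cis variants, and Storey q-values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CisWindow",
    "QtlResult",
    "enumerate_cis_pairs",
    "fit_nominal",
    "fit_nominal_many",
    "permutation_pvalue",
    "compute_qvalues",
    "map_cis",
    "CollinearGenotypeError",
]


class CollinearGenotypeError(ValueError):
    """Genotype is constant or collinear with the covariates."""


@dataclass
class CisWindow:
    gene_id: str
    tss: int
    window: int = 1_000_000

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")


@dataclass
class QtlResult:
    variant_id: str
    gene_id: str
    channel: str
    beta: float
    se: float
    p_nominal: float
    p_perm: float | None = None
    q: float | None = None


def enumerate_cis_pairs(
    variants: pd.DataFrame, genes, window: int = 1_000_000
) -> pd.DataFrame:
    """All (variant, gene) pairs with |pos − TSS| ≤ window on the same
    chromosome.

    ``variants`` needs columns variant_id, chrom, pos.
    """
    rows = []
    for g in genes:
        sub = variants[variants.chrom == g.chrom]
        close = sub[(sub.pos - g.tss).abs() <= window]
        for vid in close.variant_id:
            rows.append({"variant_id": vid, "gene_id": g.gene_id})
    return pd.DataFrame(rows, columns=["variant_id", "gene_id"])


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of y on [1, covariates]."""
    n = y.shape[0]
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        Z = np.column_stack([np.ones(n), C])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta


def fit_nominal(
    y, g, covariates=None
) -> tuple[float, float, float]:
    """OLS slope of y on dosage g after residualizing both on covariates.

    Returns (beta, se, two-sided p). Degrees of freedom account for the
    covariate projection. Raises :class:`CollinearGenotypeError` when the
    residual genotype has no variance.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n = y.size
    k = 0 if covariates is None else np.atleast_2d(np.asarray(covariates)).reshape(n, -1).shape[1]
    ry = _residualize(y, covariates)
    rg = _residualize(g, covariates)
    sxx = float(rg @ rg)
    if sxx <= 1e-12 * max(float(g @ g), 1.0):
        raise CollinearGenotypeError("genotype constant or collinear with covariates")
    beta = float(rg @ ry) / sxx
    resid = ry - beta * rg
    dof = n - k - 2
    if dof <= 0:
        raise ValueError("not enough samples for the model")
    s2 = float(resid @ resid) / dof
    se = math.sqrt(s2 / sxx)
    if se == 0.0:
        # exact fit: a nonzero slope is unambiguous, a zero slope is null
        return beta, 0.0, (0.0 if beta != 0.0 else 1.0)
    tstat = beta / se
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    return beta, se, float(p)


def fit_nominal_many(
    Y: np.ndarray, G: np.ndarray, covariates=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`fit_nominal` over rows.

    ``Y`` and ``G`` are (m, n) matrices of phenotypes and dosages, one test
    per row. Returns (beta, se, p) arrays of length m. Rows with a constant
    residual genotype get NaN.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    m, n = Y.shape
    k = 0
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
        P = Z @ np.linalg.pinv(Z)
        RY = Y - Y @ P.T
        RG = G - G @ P.T
    else:
        RY = Y - Y.mean(axis=1, keepdims=True)
        RG = G - G.mean(axis=1, keepdims=True)
    sxx = (RG * RG).sum(axis=1)
    ok = sxx > 1e-12 * np.maximum((G * G).sum(axis=1), 1.0)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    dof = n - k - 2
    b = (RG[ok] * RY[ok]).sum(axis=1) / sxx[ok]
    resid = RY[ok] - b[:, None] * RG[ok]
    s2 = (resid * resid).sum(axis=1) / dof
    se_ok = np.sqrt(s2 / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        # exact fits: nonzero slope -> p=0; exactly zero slope -> p=1
        tstat = np.where(se_ok > 0, b / se_ok, np.where(b != 0, np.inf, 0.0))
    beta[ok] = b
    se[ok] = se_ok
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return beta, se, p


def permutation_pvalue(
    y,
    G,
    covariates=None,
    n_min: int = 1000,
    n_max: int = 10_000,
    n_hits_stop: int = 15,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> tuple[float, np.ndarray]:
    """Per-gene permutation p-value on the min nominal p over cis variants.

    The phenotype (residualized on covariates, as are the dosages) is
    permuted across samples; the per-gene statistic is the minimum nominal p
    across the gene's cis variants. Adaptive scheme: at least ``n_min``
    permutations, stopping once ``n_hits_stop`` permuted statistics beat the
    observed one, never exceeding ``n_max``. p_perm = (1 + hits)/(1 + B).

    With ``exhaustive=True`` all n! sample permutations are enumerated
    (guarded to n ≤ 8) and p_perm = (#permutations with statistic ≤
    observed) / n!, counting the identity.

    Returns (p_perm, per-variant empirical p over the permutations run).
    """
    y = np.asarray(y, dtype=float)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n = y.size
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    ry = _residualize(y, covariates)
    RG = np.vstack([_residualize(G[i], covariates) for i in range(G.shape[0])])

    def min_p(yvec: np.ndarray) -> tuple[float, np.ndarray]:
        Y = np.broadcast_to(yvec, RG.shape)
        _b, _se, p = fit_nominal_many(Y, RG)
        p = np.where(np.isnan(p), 1.0, p)
        return float(np.min(p)), p

    obs, obs_per_variant = min_p(ry)
    # tolerance for statistics tied with the observed one up to float error
    eps = 1e-12 * max(1.0, abs(obs))
    obs_tol = obs + eps
    obs_per_variant_tol = obs_per_variant + eps

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        total = 0
        hits = 0
        variant_hits = np.zeros(RG.shape[0])
        for perm in itertools.permutations(range(n)):
            stat, per_var = min_p(ry[list(perm)])
            total += 1
            hits += stat <= obs_tol
            variant_hits += per_var <= obs_per_variant_tol
        return hits / total, variant_hits / total

    hits = 0
    done = 0
    variant_hits = np.zeros(RG.shape[0])
    batch = 100
    while done < n_max:
        b = min(batch, n_max - done)
        for _ in range(b):
            stat, per_var = min_p(rng.permutation(ry))
            hits += stat <= obs_tol
            variant_hits += per_var <= obs_per_variant_tol
        done += b
        if done >= n_min and hits >= n_hits_stop:
            break
    p_perm = (1 + hits) / (1 + done)
    return p_perm, (1 + variant_hits) / (1 + done)


def compute_qvalues(p, lambdas=None, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    π̂₀ is estimated on a λ grid (default 0.05…0.95 step 0.05) with a cubic
    polynomial smoother evaluated at the largest λ, clipped to (0, 1]. With
    few tests (< 100) the estimate is unstable and π̂₀ = 1 is used, which
    reduces to Benjamini–Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.96, 0.05) if lambdas is None else np.asarray(lambdas)
            pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
            coef = np.polyfit(lam, pi0_lam, 3)
            pi0 = float(np.clip(np.polyval(coef, lam.max()), 1.0 / m, 1.0))
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pi0 * m * p[i] / rank)
        q[i] = val
        prev = val
    return q


def map_cis(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    variants: pd.DataFrame,
    genes,
    covariates: pd.DataFrame | None = None,
    channel: str = "nmd",
    window: int = 1_000_000,
    permute: tuple[int, int] | None = (1000, 10_000),
    seed: int = 0,
) -> pd.DataFrame:
    """Full cis scan of one phenotype channel.

    ``phenotypes``: gene × sample matrix (already normalized/transformed);
    ``genotypes``: variant × sample dosages; ``variants``: variant_id,
    chrom, pos. Returns a per-pair table with beta, se, p_nominal, the
    per-gene p_perm (repeated on the gene's pairs) and channel-wide q-values
    computed on nominal p-values across all tested pairs.
    """
    samples = list(phenotypes.columns)
    if list(genotypes.columns) != samples:
        genotypes = genotypes[samples]
    cov = covariates.loc[samples].to_numpy() if covariates is not None else None
    pairs = enumerate_cis_pairs(variants, genes, window)
    gene_map = {g.gene_id: g for g in genes}

    rows = []
    rng = np.random.default_rng(seed)
    for gid, sub in pairs.groupby("gene_id", sort=True):
        if gid not in phenotypes.index:
            continue
        y = phenotypes.loc[gid].to_numpy()
        vids = [v for v in sub.variant_id if v in genotypes.index]
        if not vids:
            continue
        Gm = genotypes.loc[vids].to_numpy(dtype=float)
        betas, ses, ps = [], [], []
        kept = []
        for vid, grow in zip(vids, Gm):
            try:
                b, se, pn = fit_nominal(y, grow, cov)
            except CollinearGenotypeError:
                warnings.warn(f"variant {vid} skipped for gene {gid} (collinear)")
                continue
            betas.append(b)
            ses.append(se)
            ps.append(pn)
            kept.append(vid)
        if not kept:
            continue
        p_perm = None
        if permute is not None:
            Gk = genotypes.loc[kept].to_numpy(dtype=float)
            p_perm, _ = permutation_pvalue(
                y, Gk, cov, n_min=permute[0], n_max=permute[1],
                seed=rng.integers(2**31 - 1),
            )
        for vid, b, se, pn in zip(kept, betas, ses, ps):
            rows.append(
                {
                    "variant_id": vid,
                    "gene_id": gid,
                    "channel": channel,
                    "beta": b,
                    "se": se,
                    "p_nominal": pn,
                    "p_perm": p_perm,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = compute_qvalues(out.p_nominal.to_numpy())
    return out
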