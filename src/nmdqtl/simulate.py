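"""Synthetic-data generators.

Two-channel expression is generated from the allele-level decomposition
``observed NMD-channel = t · α · θ`` per allele copy, where ``t`` is the
amount transcribed, ``α`` the fraction of transcripts targeted by NMD, and
``θ`` the fraction of NMD-targeted transcripts that survive decay. Under an
additive genetic model the NMD channel of an individual is the sum of
``t·α·θ`` over its two allele copies and the non-NMD channel the sum of
``t·(1−α)``.

Variant classes:

* pNMD — alleles differ in α (targeting fraction), t and θ equal;
* dNMD — alleles differ in θ (decay efficiency 1−θ), t and α equal;
* null — α and θ equal; half the nulls are ordinary eQTLs (alleles differ
  in t), half have no genetic effect at all.

Defaults (per-allele t=100, α=0.3, θ=0.5, Gaussian noise σ=7.5, n=500
samples, MAF 0.05, 10,000 variants split 5%/5%/90%) are the study
conditions used throughout the analysis scripts and tests; see
docs/methods.md for the rationale behind the noise scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AllelicNmdParams",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "expected_channel_means",
    "simulate_expression",
    "generate_null_regrouping",
    "generate_toy_resources",
    "simulate_tissue_tpm",
    "ToyResources",
]


@dataclass
class AllelicNmdParams:
    """Per-allele transcription / NMD parameters for one biallelic variant.

    ``_ref`` is the reference allele, ``_alt`` the alternate; genotype
    dosage counts copies of the alternate allele.
    """

    t_ref: float
    t_alt: float
    alpha_ref: float
    alpha_alt: float
    theta_ref: float
    theta_alt: float

    def __post_init__(self) -> None:
        for name in ("alpha_ref", "alpha_alt", "theta_ref", "theta_alt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.t_ref < 0 or self.t_alt < 0:
            raise ValueError("transcription amounts must be >= 0")


@dataclass
class SimulationConfig:
    n_samples: int = 500
    maf: float = 0.05
    n_variants: int = 10_000
    class_proportions: tuple[float, float, float] = (0.05, 0.05, 0.90)
    effect_range: tuple[float, float] = (0.10, 0.15)
    t: float = 100.0
    alpha: float = 0.30
    theta: float = 0.50
    noise_sd: float = 7.5
    # eQTL-type nulls draw |t_ref - t_alt| uniform in this fraction-of-t band
    null_t_effect_range: tuple[float, float] = (0.10, 0.30)
    null_eqtl_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        lo, hi = self.effect_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("effect_range must be within [0, 1]")
        # effects are applied in either direction (fair coin per variant)
        for base, name in ((self.alpha, "alpha"), (self.theta, "theta")):
            if base + hi > 1.0 or base - hi < 0.0:
                raise ValueError(
                    f"effect_range {self.effect_range} pushes {name} "
                    f"(baseline {base}) outside [0, 1]"
                )


@dataclass
class SimulatedDataset:
    genotypes: np.ndarray  # (n_variants, n_samples) dosages in {0,1,2}
    y_nmd: np.ndarray  # observed NMD-channel expression
    y_non: np.ndarray  # observed non-NMD-channel expression
    truth: pd.DataFrame  # per-variant class label and allelic parameters
    config: SimulationConfig

    def __post_init__(self) -> None:
        if not (
            self.genotypes.shape == self.y_nmd.shape == self.y_non.shape
        ):
            raise ValueError("matrix dimensions inconsistent")


def simulate_genotypes(
    n_variants: int, n_samples: int, maf: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Independent biallelic dosages: binomial(2, maf) per entry."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf={maf} outside (0, 0.5]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.binomial(2, maf, size=(n_variants, n_samples)).astype(np.int8)


def expected_channel_means(
    params: AllelicNmdParams, dosage: int
) -> tuple[float, float]:
    """Noise-free channel means for an individual with the given dosage.

    Sums t·α·θ (NMD channel) and t·(1−α) (non-NMD channel) over the two
    allele copies; dosage counts alternate-allele copies.
    """
    if dosage not in (0, 1, 2):
        raise ValueError("dosage must be 0, 1 or 2")
    n_alt = dosage
    n_ref = 2 - dosage
    nmd = (
        n_ref * params.t_ref * params.alpha_ref * params.theta_ref
        + n_alt * params.t_alt * params.alpha_alt * params.theta_alt
    )
    non = n_ref * params.t_ref * (1 - params.alpha_ref) + n_alt * params.t_alt * (
        1 - params.alpha_alt
    )
    return nmd, non


def _truth_param_arrays(config: SimulationConfig, rng: np.random.Generator):
    nv = config.n_variants
    labels = rng.choice(
        np.array(["pNMD", "dNMD", "null"]),
        size=nv,
        p=list(config.class_proportions),
    )
    effect = rng.uniform(*config.effect_range, size=nv)
    sign = rng.choice([-1.0, 1.0], size=nv)

    alpha_ref = np.full(nv, config.alpha)
    alpha_alt = alpha_ref.copy()
    theta_ref = np.full(nv, config.theta)
    theta_alt = theta_ref.copy()
    t_ref = np.full(nv, config.t)
    t_alt = t_ref.copy()

    is_p = labels == "pNMD"
    is_d = labels == "dNMD"
    is_null = labels == "null"

    alpha_alt[is_p] = alpha_ref[is_p] + sign[is_p] * effect[is_p]
    theta_alt[is_d] = theta_ref[is_d] + sign[is_d] * effect[is_d]
    if (
        alpha_alt.min() < 0 or alpha_alt.max() > 1
        or theta_alt.min() < 0 or theta_alt.max() > 1
    ):
        raise ValueError("effect_range pushes α or θ outside [0, 1]")

    # nulls: a coin decides ordinary-eQTL vs no-effect
    is_eqtl = is_null & (rng.random(nv) < config.null_eqtl_fraction)
    lo, hi = config.null_t_effect_range
    t_alt[is_eqtl] = t_ref[is_eqtl] + rng.choice([-1.0, 1.0], is_eqtl.sum()) * (
        rng.uniform(lo, hi, is_eqtl.sum()) * config.t
    )

    truth = pd.DataFrame(
        {
            "variant_id": [f"var{i}" for i in range(nv)],
            "label": labels,
            "is_eqtl_null": is_eqtl,
            "t_ref": t_ref,
            "t_alt": t_alt,
            "alpha_ref": alpha_ref,
            "alpha_alt": alpha_alt,
            "theta_ref": theta_ref,
            "theta_alt": theta_alt,
        }
    )
    return truth


def simulate_expression(
    config: SimulationConfig,
    genotypes: np.ndarray | None = None,
    seed: int | None = None,
) -> SimulatedDataset:
    """Draw per-variant classes and two-channel observations.

    Observations are the noise-free channel means plus Gaussian noise of
    scale ``config.noise_sd``, truncated at 0 (expression is non-negative).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if genotypes is None:
        genotypes = simulate_genotypes(
            config.n_variants, config.n_samples, config.maf, rng
        )
    if genotypes.shape != (config.n_variants, config.n_samples):
        raise ValueError("genotype matrix does not match config dimensions")

    truth = _truth_param_arrays(config, rng)
    n_alt = genotypes.astype(float)
    n_ref = 2.0 - n_alt

    tat_ref = (truth.t_ref * truth.alpha_ref * truth.theta_ref).to_numpy()
    tat_alt = (truth.t_alt * truth.alpha_alt * truth.theta_alt).to_numpy()
    tna_ref = (truth.t_ref * (1 - truth.alpha_ref)).to_numpy()
    tna_alt = (truth.t_alt * (1 - truth.alpha_alt)).to_numpy()

    mu_nmd = n_ref * tat_ref[:, None] + n_alt * tat_alt[:, None]
    mu_non = n_ref * tna_ref[:, None] + n_alt * tna_alt[:, None]

    y_nmd = mu_nmd + rng.normal(0.0, config.noise_sd, mu_nmd.shape)
    y_non = mu_non + rng.normal(0.0, config.noise_sd, mu_non.shape)
    np.clip(y_nmd, 0.0, None, out=y_nmd)
    np.clip(y_non, 0.0, None, out=y_non)

    return SimulatedDataset(
        genotypes=genotypes, y_nmd=y_nmd, y_non=y_non, truth=truth, config=config
    )


def generate_null_regrouping(
    tpm: pd.DataFrame,
    transcript_gene: pd.Series,
    n_genes: int,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random-regrouping control: split each gene's isoforms into two
    non-empty pseudo-channels, mimicking NMD/non-NMD grouping on genes with
    no real NMD structure.

    Parameters
    ----------
    tpm : transcript × sample TPM table (index = transcript IDs).
    transcript_gene : transcript ID → gene ID mapping.
    n_genes : number of genes to sample; if fewer eligible genes exist, all
        are used with a warning.

    Returns (pseudo_nmd, pseudo_non) gene × sample matrices.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    groups = transcript_gene.loc[tpm.index].groupby(transcript_gene).groups
    eligible = sorted(g for g, idx in groups.items() if len(idx) >= 2)
    skipped = sorted(set(groups) - set(eligible))
    if skipped:
        warnings.warn(
            f"{len(skipped)} genes with <2 transcripts skipped from regrouping"
        )
    if n_genes > len(eligible):
        warnings.warn(
            f"requested {n_genes} genes but only {len(eligible)} eligible; using all"
        )
        chosen = eligible
    else:
        chosen = list(rng.choice(eligible, size=n_genes, replace=False))

    rows_a, rows_b = {}, {}
    for g in chosen:
        tids = list(groups[g])
        # uniform over non-empty labeled bipartitions
        while True:
            mask = rng.random(len(tids)) < 0.5
            if 0 < mask.sum() < len(tids):
                break
        sub = tpm.loc[tids]
        rows_a[g] = sub[mask].sum(axis=0)
        rows_b[g] = sub[~mask].sum(axis=0)
    pseudo_nmd = pd.DataFrame(rows_a).T
    pseudo_non = pd.DataFrame(rows_b).T
    pseudo_nmd.index.name = pseudo_non.index.name = "gene_id"
    return pseudo_nmd, pseudo_non


# ---------------------------------------------------------------------------
# Toy genome resources for end-to-end runs
# ---------------------------------------------------------------------------


@dataclass
class ToyResources:
    gtf_text: str
    bed_tracks: dict[str, pd.DataFrame]  # factor name -> (chrom,start,end)
    disease_snps: pd.DataFrame  # snp_id, disease_id, mesh_class
    covariates: pd.DataFrame  # samples × covariates
    variant_positions: pd.DataFrame = field(default=None)  # variant_id, chrom, pos


def _toy_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    with_poison_exon: bool,
) -> list[str]:
    """Emit GTF lines for one toy gene.

    Layout (plus-strand logic; coordinates are genomic either way):
    four 200-bp exons separated by 800-bp introns. The non-NMD isoform skips
    exon 2; the NMD isoform includes it ("poison" cassette exon) and stops
    inside it, > 50 nt upstream of the last junction. Without a poison exon
    both isoforms share the structure and only tags and stops differ is not
    valid NMD structure, so those genes get one coding isoform plus a
    second isoform with a long 3'UTR PTC.
    """
    e = [(start + i * 1000, start + i * 1000 + 200) for i in range(4)]
    lines = []

    def rec(feature, s, end, tid, tag=False):
        attrs = f'gene_id "{gene_id}"; transcript_id "{tid}";'
        if tag:
            attrs += ' tag "nonsense_mediated_decay";'
        lines.append(
            f"{chrom}\tnmdqtl_toy\t{feature}\t{s + 1}\t{end}\t.\t{strand}\t.\t{attrs}"
        )

    t_non = f"{gene_id}.T1"
    t_nmd = f"{gene_id}.T2"
    if with_poison_exon:
        # non-NMD isoform: exons 0,2,3 (skips exon 1); stop in exon 3
        rec("transcript", e[0][0], e[3][1], t_non)
        for iv in (e[0], e[2], e[3]):
            rec("exon", iv[0], iv[1], t_non)
        if strand == "+":
            rec("stop_codon", e[3][0] + 100, e[3][0] + 103, t_non)
        else:
            rec("stop_codon", e[0][0] + 97, e[0][0] + 100, t_non)
        # NMD isoform: all four exons; PTC early in the poison exon (e[1])
        rec("transcript", e[0][0], e[3][1], t_nmd, tag=True)
        for iv in e:
            rec("exon", iv[0], iv[1], t_nmd, tag=True)
        if strand == "+":
            rec("stop_codon", e[1][0] + 20, e[1][0] + 23, t_nmd, tag=True)
        else:
            rec("stop_codon", e[2][1] - 23, e[2][1] - 20, t_nmd, tag=True)
    else:
        # both isoforms use exons 0..3; NMD isoform has a PTC in exon 1
        rec("transcript", e[0][0], e[3][1], t_non)
        for iv in e:
            rec("exon", iv[0], iv[1], t_non)
        if strand == "+":
            rec("stop_codon", e[3][0] + 100, e[3][0] + 103, t_non)
        else:
            rec("stop_codon", e[0][0] + 97, e[0][0] + 100, t_non)
        rec("transcript", e[0][0], e[3][1], t_nmd, tag=True)
        for iv in e:
            rec("exon", iv[0], iv[1], t_nmd, tag=True)
        if strand == "+":
            rec("stop_codon", e[1][0] + 50, e[1][0] + 53, t_nmd, tag=True)
        else:
            rec("stop_codon", e[2][1] - 53, e[2][1] - 50, t_nmd, tag=True)
    return lines


def generate_toy_resources(seed: int = 0, n_genes: int = 10) -> ToyResources:
    """A small self-consistent genome: ~10 two-isoform NMD genes (half with a
    poison cassette exon giving direct AS-NMD coupling), BED feature tracks,
    a DisGeNET-style disease-SNP table, and a covariate table.
    """
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    gene_meta = []
    for i in range(n_genes):
        chrom = "chr1" if i < (n_genes + 1) // 2 else "chr2"
        strand = "+" if i % 2 == 0 else "-"
        start = 100_000 + (i % ((n_genes + 1) // 2)) * 50_000
        poison = i % 2 == 0
        lines += _toy_gene(f"G{i}", chrom, strand, start, poison)
        gene_meta.append((f"G{i}", chrom, start, strand, poison))
    gtf_text = "\n".join(lines) + "\n"

    # variants: a cis candidate set around each gene's TSS
    var_rows = []
    k = 0
    for gid, chrom, start, strand, _poison in gene_meta:
        for _ in range(6):
            pos = int(start + rng.integers(-20_000, 24_000))
            var_rows.append({"variant_id": f"rs{k}", "chrom": chrom, "pos": pos})
            k += 1
    variants = pd.DataFrame(var_rows)

    # BED tracks for three pseudo-factors (sorted, non-negative)
    tracks = {}
    for name in ("miR-toy-1", "RBP-toy-A", "RBP-toy-B"):
        starts = np.sort(rng.integers(90_000, 400_000, size=8))
        tracks[name] = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], size=8),
                "start": starts,
                "end": starts + rng.integers(50, 400, size=8),
            }
        ).sort_values(["chrom", "start"], ignore_index=True)

    # disease-SNP table with MeSH-like classes
    mesh = [f"C{c:02d}" for c in range(1, 9)] + ["F01", "F02"]
    snp_ids = rng.choice(variants.variant_id, size=20, replace=False)
    disease = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "disease_id": [f"D{j:03d}" for j in range(20)],
            "mesh_class": rng.choice(mesh, size=20),
        }
    )

    n_samples = 80
    covariates = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n_samples).astype(float),
            "pc1": rng.normal(size=n_samples),
        },
        index=[f"S{j}" for j in range(n_samples)],
    )
    return ToyResources(
        gtf_text=gtf_text,
        bed_tracks=tracks,
        disease_snps=disease,
        covariates=covariates,
        variant_positions=variants,
    )


def simulate_tissue_tpm(
    genes,
    variants: pd.DataFrame,
    n_samples: int,
    seed: int,
    maf: float = 0.25,
    noise_sd: float = 4.0,
    t: float = 100.0,
    alpha: float = 0.3,
    theta: float = 0.5,
    effect: float = 0.25,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray, pd.DataFrame]:
    """Transcript-level TPM for a toy tissue, driven by planted NMD-QTLs.

    Each gene gets one causal cis variant (its first candidate variant),
    alternating pNMD / dNMD effects across genes; channel totals follow the
    allelic t·α·θ model and are spread across that channel's isoforms.

    Returns (tpm transcripts × samples, transcript→gene map, genotype matrix
    aligned to `variants`, truth table).
    """
    rng = np.random.default_rng(seed)
    X = simulate_genotypes(len(variants), n_samples, maf, rng)
    sample_ids = [f"S{j}" for j in range(n_samples)]

    tpm_rows = {}
    tx_gene = {}
    truth_rows = []
    for gi, gene in enumerate(genes):
        cand = variants.index[variants.chrom == gene.chrom]
        near = [
            i for i in cand if abs(variants.pos[i] - gene.tss) <= 1_000_000
        ]
        causal = near[gi % max(len(near), 1)] if near else None
        label = ("pNMD", "dNMD", "null")[gi % 3]
        p = dict(t_ref=t, t_alt=t, alpha_ref=alpha, alpha_alt=alpha,
                 theta_ref=theta, theta_alt=theta)
        if causal is not None and label == "pNMD":
            p["alpha_alt"] = alpha + effect
        elif causal is not None and label == "dNMD":
            p["theta_alt"] = theta + effect
        params = AllelicNmdParams(**p)
        dos = X[causal] if causal is not None else np.zeros(n_samples, dtype=int)
        mu = np.array([expected_channel_means(params, int(d)) for d in dos])
        y_nmd = np.clip(mu[:, 0] + rng.normal(0, noise_sd, n_samples), 0, None)
        y_non = np.clip(mu[:, 1] + rng.normal(0, noise_sd, n_samples), 0, None)

        nmd_tx = [x.transcript_id for x in gene.nmd_transcripts()]
        non_tx = [x.transcript_id for x in gene.non_nmd_transcripts()]
        for tid in nmd_tx:
            tpm_rows[tid] = y_nmd / len(nmd_tx)
            tx_gene[tid] = gene.gene_id
        for tid in non_tx:
            tpm_rows[tid] = y_non / len(non_tx)
            tx_gene[tid] = gene.gene_id
        truth_rows.append(
            {
                "gene_id": gene.gene_id,
                "label": label,
                "causal_variant": variants.variant_id[causal] if causal is not None else None,
            }
        )

    tpm = pd.DataFrame(tpm_rows, index=sample_ids).T
    return tpm, pd.Series(tx_gene), X, pd.DataFrame(truth_rows)
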