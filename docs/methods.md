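# Methods

## 1. Model

For a biallelic variant near a gene with both NMD-targeted and non-targeted
isoforms, each allele copy contributes independently to two observable
expression channels:

* NMD channel: `t · α · θ` — transcription `t`, fraction `α` routed to
  NMD-targeted isoforms, fraction `θ` of those surviving decay;
* non-NMD channel: `t · (1 − α)`.

An individual's channel means are the sums over their two allele copies;
genotype dosage counts alternate-allele copies. The three variant classes
are parameter contrasts between alleles: pNMD (α differs), dNMD (θ differs),
eQTL/null (t differs or nothing differs). The qualitative signatures used
throughout are: pNMD moves the channels in opposite directions, dNMD moves
only the NMD channel, eQTL moves both in the same direction.

## 2. Pipeline

1. **Annotation** (`annotation`): GTF records are parsed into transcript and
   gene models (internally 0-based half-open; GTF I/O is 1-based closed).
   NMD susceptibility uses the 50-nt rule: the stop codon must end more than
   50 nt (strictly) upstream of the last exon–exon junction in spliced
   coordinates. Genes carrying both tagged and untagged isoforms are "NMD
   genes". Cassette exons require exact interval identity in the including
   isoforms and exons strictly on both sides with no overlap in the skipping
   isoforms; any partial overlap removes a transcript from both sets.
2. **Preparation** (`prep`): transcript TPM is summed into per-gene NMD and
   non-NMD channels; genes with isoforms in only one channel are dropped.
   Both channels are normalized with one shared set of median-of-ratios size
   factors (they come from the same library), then each gene row is
   rank-based inverse-normal transformed, Φ⁻¹((rank − 0.5)/n), average ranks
   on ties.
3. **Mapping** (`mapping`): per cis-window (±1 Mb of the TSS) variant–gene
   pair, the dosage slope is fit by OLS after residualizing phenotype and
   dosage on covariates (Frisch–Waugh), with degrees of freedom n − k − 2.
   Per-gene significance uses adaptive permutations of the phenotype
   (1,000–10,000, early stop after 15 hits) on the min-nominal-p statistic,
   p_perm = (1 + hits)/(1 + B); an exhaustive enumeration mode (n ≤ 8)
   exists for validation. q-values follow the Storey procedure (λ grid
   0.05–0.95, cubic-polynomial smoother for π0), falling back to π0 = 1
   (Benjamini–Hochberg) below 100 tests where the smoother is unstable.
4. **Classification** (`classify`): pNMD-QTL candidate iff q_nmd ≤ 0.05,
   q_non ≤ 0.05 and opposite slope signs; dNMD-QTL candidate iff
   q_nmd ≤ 0.05 and q_non > 0.8. The zone 0.05 < q_non ≤ 0.8 is deliberately
   unclassified. Candidates are confirmed by median (τ = 0.5) quantile
   regression on untransformed TPM: pNMD needs both slopes at p ≤ 0.05 with
   opposite signs and |β_nmd| < |β_non|; dNMD needs p_nmd ≤ 0.05 and
   p_non > 0.95. The dNMD confirmation gate is asymmetric by design (kept as
   specified): a truly null non-NMD channel passes it only ~5% of the time,
   making confirmation conservative.
5. **Evaluation** (`evaluate`): in simulations, classification sweeps a
   nominal-p threshold τ (160 points, log-spaced 1e-8 to 0.5): pNMD = both
   channels p < τ with opposite signs; dNMD = p_nmd < τ and p_non ≥ τ.
   Precision at recall 0.8 is linearly interpolated at the first upward
   crossing. Note dNMD recall is not monotone in τ (loosening τ also
   loosens the p_non ≥ τ null gate), so the first crossing is the defined
   operating point.
6. **Similarity / positions / enrichment / splicing** follow the formulas in
   the module docstrings: the directed similarity
   s_ij = [n_ij/(n_i − n_ij)] / [n_j/(n − n_j)] averaged with its transpose;
   edge bins none < 10 ≤ black < 20 ≤ orange < 30 ≤ red; ordinal ranks from
   both gene ends with rank5 + rank3 = k − 1; Fisher exact tests with the
   Haldane 0.5 correction applied to the odds ratio only when a cell is
   zero; cassette-exon inclusion ratio ΣTPM(inc)/(ΣTPM(inc)+ΣTPM(exc)) with
   NaN when both sums vanish; AS-NMD direct coupling = a cassette exon whose
   including/skipping isoform sets perfectly separate the gene's NMD flags.

## 3. Simulation study defaults and why

`SimulationConfig` defaults: 10,000 variants × 500 samples, MAF 0.05,
class mix 5% pNMD / 5% dNMD / 90% null, allelic effects |Δα| or |Δθ|
uniform in [0.10, 0.15] with a fair-coin sign, baselines t = 100 per allele,
α = 0.30, θ = 0.50. Half the nulls are eQTL-type with |Δt| uniform in
[0.10, 0.30]·t; observations add Gaussian noise and are truncated at zero.

**Noise scale σ = 7.5.** The dNMD signal is intrinsically small: a θ shift
of 0.10–0.15 changes the NMD channel by only 3.0–4.5 units per allele copy
(t·α·Δθ with t = 100, α = 0.3), while the pNMD signal also moves the much
larger non-NMD channel by 10–15 units. A closed-form power check (slope
standard error ≈ σ/√(n·2·maf(1−maf)) ≈ σ/5.2 at n = 500) shows that at
σ = 10 the dNMD class never reaches recall 0.8 at any threshold, making the
operating point undefined. σ = 7.5 was fixed once, from that power analysis
and before any acceptance test was written, as the largest round value
giving the dNMD class a well-defined recall-0.8 operating point. Measured
at the defaults (seeds 0–4): precision at recall 0.8 ≈ 1.00 (pNMD) and
≈ 0.84–0.88 (dNMD).

**Why pNMD precision saturates at 1.0.** False pNMD calls require both
channels significant with opposite signs. eQTL-type nulls move both channels
the same way, and pure nulls need two independent false positives with
opposite signs — so with a shared noise scale per channel the pNMD class is
essentially uncontaminated. Splitting the noise unevenly between channels
could pull pNMD precision below 1, but it floods the dNMD class with
eQTL-null false positives; the shared-σ model is kept.

## 4. Toy genome generator: scope

`generate_toy_resources` emits ~10 two-isoform genes (four 200-bp exons,
800-bp introns) on two chromosomes with alternating strands. Even-indexed
genes carry a poison cassette exon — the NMD isoform includes it with an
early PTC, the non-NMD isoform skips it — giving direct AS-NMD coupling;
odd-indexed genes share exon structure and differ only in stop position.
All tags are consistent with the 50-nt rule by construction. The generator
emulates: GENCODE-style tags, strand-aware coordinates, cassette exons,
cis-variant panels, pseudo-factor BED tracks, a disease-SNP table with
MeSH-like classes, and covariates. It does not emulate: overlapping genes,
multi-exon UTR structure, linkage disequilibrium, allele-specific reads,
realistic TPM distributions, or population structure.

## 5. Numerical choices

* Exact-fit convention: when the OLS residual variance is exactly zero the
  p-value is 0 for a nonzero slope and 1 for a zero slope (arises in
  noise-free simulations).
* Permutation ties: permuted statistics are compared to the observed one
  with a relative tolerance of 1e-12 so that float-level ties count as hits
  (matches exact enumeration).
* Degenerate similarity denominators (n_ij = n_i or n_j = n) return +inf
  with a warning; the edge is binned as "red".
* Quantile-regression p-values are the asymptotic ones from iteratively
  reweighted least squares at all sample sizes; no bootstrap fallback.
* The location model N_in = w0 + w1·N_out + w2·log2(length) always includes
  an explicit intercept column, even when a regressor is constant.

## 6. Limitations

* The simulator draws independent variants and independent Gaussian noise;
  precision/recall numbers carry a tolerance because the original noise
  parameters are not fully specified.
* dNMD recall is non-monotone in the threshold sweep (see §2.5); curves are
  reported as computed, without enforcing monotonicity.
* The dNMD quantile-confirmation gate (p_non > 0.95) is intentionally strict
  and will reject most true dNMD candidates whose non-NMD channel is merely
  noisy rather than precisely flat.
* Storey's π0 smoother needs a few hundred tests to be stable; small scans
  silently use Benjamini–Hochberg instead.
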