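"""Gene/transcript annotation: GTF I/O, collapsed gene models, the 50-nt NMD
rule, and cassette-exon detection.

Coordinates are 0-based half-open internally; GTF I/O converts from/to the
1-based closed convention. Exons are stored in genomic order; transcript
(5'→3') order is derived from the strand where it matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "CassetteExon",
    "GtfParseError",
    "parse_gtf",
    "write_gtf",
    "collapse_intervals",
    "collapse_gene_model",
    "classify_nmd_50nt",
    "find_cassette_exons",
    "as_nmd_direct_coupling",
    "write_collapsed_bed",
    "gene_summary_table",
]

Interval = tuple[int, int]

NMD_TAG = "nonsense_mediated_decay"


class GtfParseError(ValueError):
    """Raised for malformed GTF records, naming the offending line."""


@dataclass
class TranscriptModel:
    """One transcript isoform.

    ``cds_end`` is the genomic coordinate (0-based) of the first base of the
    translation stop codon — the PTC for NMD-targeted transcripts, the
    regular stop otherwise. ``None`` for non-coding records.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds_end: int | None = None
    nmd_flag: bool = False

    def __post_init__(self) -> None:
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    def exons_5to3(self) -> list[Interval]:
        """Exons in transcript orientation."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_position(self, pos: int) -> int | None:
        """Map a genomic position to spliced (transcript) coordinates.

        Returns ``None`` when the position falls in an intron or outside
        the transcript.
        """
        off = 0
        for s, e in self.exons_5to3():
            if s <= pos < e:
                if self.strand == "+":
                    return off + (pos - s)
                return off + (e - 1 - pos)
            off += e - s
        return None


@dataclass
class GeneModel:
    """A gene with its isoforms and the collapsed (union) exon model."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    tss: int = field(init=False)
    collapsed_exons: list[Interval] = field(init=False)
    collapsed_introns: list[Interval] = field(init=False)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        self.tss = min(starts) if self.strand == "+" else max(ends) - 1
        self.collapsed_exons, self.collapsed_introns = collapse_gene_model(self)

    @property
    def span(self) -> Interval:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def gene_length(self) -> int:
        s, e = self.span
        return e - s

    def nmd_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.nmd_flag]

    def non_nmd_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if not t.nmd_flag]

    @property
    def is_nmd_gene(self) -> bool:
        """True when the gene has both NMD-tagged and untagged isoforms."""
        flags = {t.nmd_flag for t in self.transcripts}
        return flags == {True, False}


@dataclass
class CassetteExon:
    gene_id: str
    interval: Interval
    inc_transcripts: frozenset[str]
    exc_transcripts: frozenset[str]

    def __post_init__(self) -> None:
        if self.inc_transcripts & self.exc_transcripts:
            raise ValueError("inclusion/exclusion sets overlap")
        if not self.inc_transcripts or not self.exc_transcripts:
            raise ValueError("inclusion and exclusion sets must be non-empty")


# ---------------------------------------------------------------------------
# GTF I/O (GENCODE attribute dialect, multi-valued "tag" keys)
# ---------------------------------------------------------------------------


def _parse_attributes(attr: str, lineno: int) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(" ", 1)
        if len(parts) != 2:
            raise GtfParseError(f"malformed attribute {chunk!r} at line {lineno}")
        key, val = parts
        out.setdefault(key, []).append(val.strip().strip('"'))
    return out


def parse_gtf(path_or_lines) -> list[GeneModel]:
    """Parse a GENCODE-dialect GTF into :class:`GeneModel` objects.

    The NMD flag of each transcript is read from the transcript record's
    ``tag "nonsense_mediated_decay"`` attribute. Transcripts without exon
    records are rejected with a warning. Accepts a path or an iterable of
    lines.
    """
    if isinstance(path_or_lines, (str, bytes)) and "\n" in str(path_or_lines):
        lines: Iterable[str] = str(path_or_lines).splitlines()
    elif isinstance(path_or_lines, (str, bytes)):
        lines = open(path_or_lines)
    else:
        lines = path_or_lines

    tx_meta: dict[str, dict] = {}
    tx_exons: dict[str, list[Interval]] = {}
    tx_cds: dict[str, list[Interval]] = {}
    tx_stop: dict[str, list[Interval]] = {}
    order: list[str] = []

    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GtfParseError(f"expected 9 columns at line {lineno}")
        chrom, _src, feature, start, end, _score, strand, _frame, attr = cols
        if feature not in {"transcript", "exon", "CDS", "stop_codon"}:
            continue
        attrs = _parse_attributes(attr, lineno)
        if "transcript_id" not in attrs:
            raise GtfParseError(f"missing transcript_id at line {lineno}")
        tid = attrs["transcript_id"][0]
        iv = (int(start) - 1, int(end))  # 1-based closed -> 0-based half-open
        if feature == "transcript":
            if "gene_id" not in attrs:
                raise GtfParseError(f"missing gene_id at line {lineno}")
            tx_meta[tid] = {
                "gene_id": attrs["gene_id"][0],
                "chrom": chrom,
                "strand": strand,
                "nmd": NMD_TAG in attrs.get("tag", []),
            }
            order.append(tid)
        elif feature == "exon":
            tx_exons.setdefault(tid, []).append(iv)
        elif feature == "CDS":
            tx_cds.setdefault(tid, []).append(iv)
        elif feature == "stop_codon":
            tx_stop.setdefault(tid, []).append(iv)

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in order:
        meta = tx_meta[tid]
        exons = tx_exons.get(tid)
        if not exons:
            warnings.warn(f"transcript {tid} has no exons; record skipped")
            continue
        # cds_end = genomic coordinate of the first base of the stop codon
        # (transcript orientation). stop_codon records take precedence; with
        # CDS only, GENCODE excludes the stop from the CDS, so the stop
        # starts one base past the CDS 3' end.
        cds_end = None
        stop = tx_stop.get(tid)
        cds = tx_cds.get(tid)
        if stop:
            if meta["strand"] == "+":
                cds_end = min(s for s, _e in stop)
            else:
                cds_end = max(e for _s, e in stop) - 1
        elif cds:
            if meta["strand"] == "+":
                cds_end = max(e for _s, e in cds)
            else:
                cds_end = min(s for s, _e in cds) - 1
        gid = meta["gene_id"]
        if gid not in genes:
            genes[gid] = []
            gene_order.append(gid)
        genes[gid].append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=meta["chrom"],
                strand=meta["strand"],
                exons=exons,
                cds_end=cds_end,
                nmd_flag=meta["nmd"],
            )
        )

    out = []
    for gid in gene_order:
        txs = genes[gid]
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=txs[0].chrom,
                strand=txs[0].strand,
                transcripts=txs,
            )
        )
    return out


def write_gtf(genes: Sequence[GeneModel], path=None) -> str:
    """Serialize gene models back to GENCODE-dialect GTF text."""
    lines = []
    for g in genes:
        for t in g.transcripts:
            s, e = t.span
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.nmd_flag:
                attrs += f' tag "{NMD_TAG}";'
            lines.append(
                f"{g.chrom}\tnmdqtl\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}"
            )
            for es, ee in t.exons:
                lines.append(
                    f"{g.chrom}\tnmdqtl\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{attrs}"
                )
            if t.cds_end is not None:
                if g.strand == "+":
                    cs, ce = t.cds_end, t.cds_end + 3
                else:
                    cs, ce = t.cds_end - 2, t.cds_end + 1
                lines.append(
                    f"{g.chrom}\tnmdqtl\tstop_codon\t{cs + 1}\t{ce}\t.\t{g.strand}\t.\t{attrs}"
                )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Collapsed gene model
# ---------------------------------------------------------------------------


def collapse_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Minimal union of a set of half-open intervals."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def collapse_gene_model(gene) -> tuple[list[Interval], list[Interval]]:
    """Union of all isoform exons plus the gaps (introns) between them."""
    exons = collapse_intervals(
        iv for t in gene.transcripts for iv in t.exons
    )
    introns = [(e1, s2) for (_s1, e1), (s2, _e2) in zip(exons, exons[1:])]
    return exons, introns


# ---------------------------------------------------------------------------
# The 50-nt rule
# ---------------------------------------------------------------------------


def classify_nmd_50nt(t: TranscriptModel, min_distance: int = 50) -> bool:
    """NMD susceptibility by the 50-nt rule.

    True iff the stop codon lies more than ``min_distance`` nt upstream of
    the last exon–exon junction, in spliced coordinates. The distance is
    counted from the first base after the stop codon to the junction, so a
    stop 51 nt upstream qualifies and one 50 nt upstream does not.
    Single-exon transcripts have no junction and return False.
    """
    if len(t.exons) < 2 or t.cds_end is None:
        return False
    stop_spliced = t.spliced_position(t.cds_end)
    if stop_spliced is None:
        return False
    # spliced coordinate of the first base of the last exon
    last_exon_len = (
        t.exons_5to3()[-1][1] - t.exons_5to3()[-1][0]
    )
    junction = t.spliced_length() - last_exon_len
    # stop codon occupies [stop, stop+3) in spliced coordinates
    distance = junction - (stop_spliced + 3)
    return distance > min_distance


# ---------------------------------------------------------------------------
# Cassette exons and AS-NMD coupling
# ---------------------------------------------------------------------------


def find_cassette_exons(gene: GeneModel) -> list[CassetteExon]:
    """Detect cassette exons: internal exons entirely included by some
    transcripts and entirely skipped by others.

    "Included" requires exact interval identity with one of the transcript's
    internal exons; any non-identical overlap makes a transcript partial and
    excludes it from both sets. "Skipped" requires the transcript to have
    exons strictly on both sides of the interval and no overlap with it.
    """
    candidates: set[Interval] = set()
    for t in gene.transcripts:
        for iv in t.exons[1:-1]:
            candidates.add(iv)

    out = []
    for iv in sorted(candidates):
        s, e = iv
        inc: set[str] = set()
        exc: set[str] = set()
        for t in gene.transcripts:
            overlapping = [x for x in t.exons if x[0] < e and s < x[1]]
            if overlapping:
                if overlapping == [iv] and iv in t.exons[1:-1]:
                    inc.add(t.transcript_id)
                elif overlapping == [iv]:
                    # identical exon but at the transcript boundary: the exon
                    # is still used entirely
                    inc.add(t.transcript_id)
                # otherwise: partial overlap, excluded from both sets
            else:
                has_left = any(x[1] <= s for x in t.exons)
                has_right = any(x[0] >= e for x in t.exons)
                if has_left and has_right:
                    exc.add(t.transcript_id)
        internal_somewhere = any(
            iv in t.exons[1:-1]
            for t in gene.transcripts
            if t.transcript_id in inc
        )
        if inc and exc and internal_somewhere:
            out.append(
                CassetteExon(
                    gene_id=gene.gene_id,
                    interval=iv,
                    inc_transcripts=frozenset(inc),
                    exc_transcripts=frozenset(exc),
                )
            )
    return out


def as_nmd_direct_coupling(gene: GeneModel, ce: CassetteExon) -> bool:
    """Direct AS-NMD coupling at a cassette exon.

    True iff the NMD flags perfectly separate the including from the
    skipping transcripts: all NMD-targeted isoforms include the exon and all
    non-NMD isoforms skip it, or conversely.
    """
    flags = {t.transcript_id: t.nmd_flag for t in gene.transcripts}
    inc_flags = {flags[tid] for tid in ce.inc_transcripts}
    exc_flags = {flags[tid] for tid in ce.exc_transcripts}
    seen = inc_flags | exc_flags
    if seen != {True, False}:
        return False
    return (inc_flags == {True} and exc_flags == {False}) or (
        inc_flags == {False} and exc_flags == {True}
    )


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------


def write_collapsed_bed(genes: Sequence[GeneModel], path=None) -> str:
    """BED6 of collapsed exons and introns (name = gene:exon_i / gene:intron_i)."""
    rows = []
    for g in genes:
        for i, (s, e) in enumerate(g.collapsed_exons):
            rows.append(f"{g.chrom}\t{s}\t{e}\t{g.gene_id}:exon_{i}\t0\t{g.strand}")
        for i, (s, e) in enumerate(g.collapsed_introns):
            rows.append(f"{g.chrom}\t{s}\t{e}\t{g.gene_id}:intron_{i}\t0\t{g.strand}")
    text = "\n".join(rows) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def gene_summary_table(genes: Sequence[GeneModel]):
    """Per-gene summary as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "gene_length": g.gene_length,
                "n_transcripts": len(g.transcripts),
                "n_nmd_transcripts": len(g.nmd_transcripts()),
                "is_nmd_gene": g.is_nmd_gene,
                "n_collapsed_exons": len(g.collapsed_exons),
            }
        )
    return pd.DataFrame(rows)
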