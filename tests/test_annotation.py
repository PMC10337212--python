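import pytest

from nmdqtl import annotation as ann


def make_tx(exons, strand="+", cds_end=None, tid="T", gid="G", nmd=False):
    return ann.TranscriptModel(
        transcript_id=tid, gene_id=gid, chrom="chr1", strand=strand,
        exons=exons, cds_end=cds_end, nmd_flag=nmd,
    )


class TestParseGtf:
    def test_toy_genome_parses(self, toy, toy_genes):
        assert len(toy_genes) == 10
        for g in toy_genes:
            assert len(g.transcripts) == 2
            assert g.is_nmd_gene

    def test_round_trip(self, toy_genes):
        text = ann.write_gtf(toy_genes)
        again = ann.parse_gtf(text.splitlines())
        for a, b in zip(toy_genes, again):
            assert a.gene_id == b.gene_id
            assert a.tss == b.tss
            assert a.span == b.span
            for ta, tb in zip(a.transcripts, b.transcripts):
                assert ta.exons == tb.exons
                assert ta.cds_end == tb.cds_end
                assert ta.nmd_flag == tb.nmd_flag

    def test_malformed_line_names_lineno(self):
        ok = 'chr1\tsrc\texon\t10\t20\t.\t+\t.\tgene_id "G"; transcript_id "T";'
        with pytest.raises(ann.GtfParseError, match="line 2"):
            ann.parse_gtf([ok, "bad line"])
        with pytest.raises(ann.GtfParseError, match="line 1"):
            ann.parse_gtf(['chr1\tsrc\texon\t10\t20\t.\t+\t.\tgene_id "G";'])

    def test_minus_strand_tss(self, toy_genes):
        for g in toy_genes:
            s, e = g.span
            assert g.tss == (s if g.strand == "+" else e - 1)


class TestSplicedCoordinates:
    def test_plus_strand(self):
        t = make_tx([(0, 100), (200, 300)])
        assert t.spliced_position(0) == 0
        assert t.spliced_position(99) == 99
        assert t.spliced_position(200) == 100
        assert t.spliced_position(150) is None  # intron

    def test_minus_strand(self):
        t = make_tx([(0, 100), (200, 300)], strand="-")
        assert t.spliced_position(299) == 0
        assert t.spliced_position(200) == 99
        assert t.spliced_position(99) == 100
        assert t.spliced_position(0) == 199

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            make_tx([(0, 100), (50, 200)])


class TestFiftyNtRule:
    def test_boundary(self):
        # junction at spliced 200; distance = 200 - (stop+3)
        exons = [(0, 200), (1000, 1100)]
        assert ann.classify_nmd_50nt(make_tx(exons, cds_end=146))  # 51 nt
        assert not ann.classify_nmd_50nt(make_tx(exons, cds_end=147))  # 50 nt

    def test_single_exon_and_noncoding(self):
        assert not ann.classify_nmd_50nt(make_tx([(0, 500)], cds_end=10))
        assert not ann.classify_nmd_50nt(make_tx([(0, 100), (200, 300)]))

    def test_toy_tags_consistent_with_rule(self, toy_genes):
        for g in toy_genes:
            for t in g.transcripts:
                assert ann.classify_nmd_50nt(t) == t.nmd_flag, t.transcript_id


class TestCollapse:
    def test_merge_overlapping_and_adjacent(self):
        assert ann.collapse_intervals([(0, 10), (5, 20), (20, 30), (40, 50)]) == [
            (0, 30),
            (40, 50),
        ]

    def test_gene_model_unions_and_gaps(self, toy_genes):
        for g in toy_genes:
            exons = g.collapsed_exons
            introns = g.collapsed_introns
            # alternating, complementary tiling of the span
            assert len(introns) == len(exons) - 1
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                assert e1 < s2
            for (es, ee), (is_, ie) in zip(exons, introns):
                assert is_ == ee
            total = sum(e - s for s, e in exons) + sum(e - s for s, e in introns)
            assert total == g.gene_length


class TestCassetteExons:
    def test_poison_gene_has_coupled_cassette(self, toy_genes):
        g0 = next(g for g in toy_genes if g.gene_id == "G0")
        ces = ann.find_cassette_exons(g0)
        assert len(ces) == 1
        assert ann.as_nmd_direct_coupling(g0, ces[0])

    def test_identical_isoform_gene_has_none(self, toy_genes):
        g1 = next(g for g in toy_genes if g.gene_id == "G1")
        assert ann.find_cassette_exons(g1) == []

    def test_partial_overlap_excludes_transcript(self):
        t_inc = make_tx([(0, 100), (200, 300), (400, 500)], tid="A")
        t_skip = make_tx([(0, 100), (400, 500)], tid="B")
        t_part = make_tx([(0, 100), (200, 350), (400, 500)], tid="C")
        g = ann.GeneModel("G", "chr1", "+", [t_inc, t_skip, t_part])
        ces = ann.find_cassette_exons(g)
        for ce in ces:
            if ce.interval == (200, 300):
                assert "C" not in ce.inc_transcripts | ce.exc_transcripts

    def test_cassette_validation(self):
        with pytest.raises(ValueError):
            ann.CassetteExon("G", (0, 10), frozenset(), frozenset({"B"}))
        with pytest.raises(ValueError):
            ann.CassetteExon("G", (0, 10), frozenset({"A"}), frozenset({"A"}))


class TestTabularOutputs:
    def test_collapsed_bed_schema(self, toy_genes):
        text = ann.write_collapsed_bed(toy_genes)
        for line in text.strip().splitlines():
            chrom, start, end, name = line.split("\t")[:4]
            assert int(start) < int(end)

    def test_gene_summary(self, toy_genes):
        tab = ann.gene_summary_table(toy_genes)
        assert len(tab) == len(toy_genes)
        assert tab.is_nmd_gene.all()
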