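"""Annotation parsing, P-site assignment, coverage and abundance."""

import numpy as np
import pysam
import pytest

from ribospec import annotation_coverage as ac


def write_gtf(tmp_path, text):
    p = tmp_path / "t.gtf"
    p.write_text(text)
    return str(p)


GTF_SINGLE = (
    'chr1\tsrc\texon\t101\t200\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1"; '
    'transcript_biotype "protein_coding";\n'
    'chr1\tsrc\tCDS\t131\t190\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1"; '
    'transcript_biotype "protein_coding";\n'
)


class TestParseAnnotation:
    def test_utr_cds_partition_plus_strand(self, tmp_path):
        """Exon [100,200) with CDS [130,190): 30 nt 5'UTR, 60 nt CDS, 10 nt 3'UTR."""
        models = ac.parse_annotation(write_gtf(tmp_path, GTF_SINGLE.format(strand="+")))
        (m,) = models
        assert m.exons == [(100, 200)] and m.cds == [(130, 190)]
        assert m.region_length("5UTR") == 30
        assert m.region_length("CDS") == 60
        assert m.region_length("3UTR") == 10
        assert m.region_length("full") == 100

    def test_utr_lengths_flip_on_minus_strand(self, tmp_path):
        """Same structure on '-' : the genomically-right 10 nt become the 5'UTR."""
        (m,) = ac.parse_annotation(write_gtf(tmp_path, GTF_SINGLE.format(strand="-")))
        assert m.region_length("5UTR") == 10
        assert m.region_length("3UTR") == 30
        # coordinate 0 is the 5' end: the highest genomic position
        assert m.region_coords("full")[0] == 199

    def test_two_transcripts_share_gene(self, tmp_path):
        text = GTF_SINGLE.format(strand="+") + (
            'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t2"; '
            'transcript_biotype "protein_coding";\n'
        )
        models = ac.parse_annotation(write_gtf(tmp_path, text))
        assert {m.transcript_id for m in models} == {"t1", "t2"}
        assert {m.gene_id for m in models} == {"g1"}

    def test_malformed_line_names_line_number(self, tmp_path):
        text = GTF_SINGLE.format(strand="+") + "chr1\tonly\tthree\n"
        with pytest.raises(ac.GtfParseError, match="line 3"):
            ac.parse_annotation(write_gtf(tmp_path, text))

    def test_zero_exon_transcript_skipped(self, tmp_path, caplog):
        text = GTF_SINGLE.format(strand="+") + (
            'chr1\tsrc\tCDS\t301\t400\t.\t+\t.\tgene_id "g2"; transcript_id "t3";\n'
        )
        with caplog.at_level("WARNING"):
            models = ac.parse_annotation(write_gtf(tmp_path, text))
        assert [m.transcript_id for m in models] == ["t1"]
        assert "t3" in caplog.text

    def test_biotype_filter(self, tmp_path):
        text = GTF_SINGLE.format(strand="+") + (
            'chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "g3"; transcript_id "t4"; '
            'transcript_type "lincRNA";\n'
        )
        models = ac.parse_annotation(
            write_gtf(tmp_path, text), biotype_filter={"lincRNA"}
        )
        assert [m.transcript_id for m in models] == ["t4"]


class TestPsiteAdjustment:
    def _read(self, start, length, reverse=False):
        header = pysam.AlignmentHeader.from_dict(
            {"SQ": [{"SN": "chr1", "LN": 10_000}]}
        )
        r = pysam.AlignedSegment(header)
        r.query_name = "r"
        r.reference_id = 0
        r.reference_start = start
        r.flag = 16 if reverse else 0
        r.cigarstring = f"{length}M"
        r.query_sequence = "A" * length
        return r

    def test_plus_strand_offset_from_five_prime(self):
        assert ac.adjust_to_psite(self._read(1000, 28), {28: 12}) == 1012

    def test_minus_strand_offset_from_high_coordinate(self):
        # read spans [1000, 1028); 5' end is 1027, P-site 1027 - 12 = 1015
        assert ac.adjust_to_psite(self._read(1000, 28, reverse=True), {28: 12}) == 1015

    def test_unknown_length_without_default_is_skipped(self):
        table = {n: 12 for n in range(28, 31)}
        assert ac.adjust_to_psite(self._read(1000, 35), table) is None
        assert ac.adjust_to_psite(self._read(1000, 35), table, default_offset=12) == 1012


def make_bam(tmp_path, reads, chrom="chr1", ln=10_000):
    """reads: list of (start, length, reverse)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": ln}]}
    sam = tmp_path / "r.sam"
    with pysam.AlignmentFile(sam, "wh", header=header) as out:
        for i, (start, length, reverse) in enumerate(sorted(reads)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.flag = 16 if reverse else 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{length}M"
            a.query_sequence = "A" * length
            out.write(a)
    bam = tmp_path / "r.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return str(bam)


class TestProfileExtraction:
    def model(self, tmp_path=None):
        return ac.TranscriptModel("t1", "g1", "chr1", "+", [(1000, 1010)])

    def test_tally_matches_psite_placement(self, tmp_path):
        # P-sites at region positions 0, 0, 5 (genomic 1000, 1000, 1005)
        bam = make_bam(
            tmp_path, [(988, 28, False), (988, 28, False), (993, 28, False)]
        )
        prof = ac.extract_psite_profile(bam, self.model(), "full")
        assert prof.counts.tolist() == [2, 0, 0, 0, 0, 1, 0, 0, 0, 0]
        assert prof.length_histogram == {28: 3}

    def test_psite_outside_region_not_counted(self, tmp_path):
        # P-site at genomic 1012, outside the 10-nt region
        bam = make_bam(tmp_path, [(1000, 28, False)])
        prof = ac.extract_psite_profile(bam, self.model(), "full")
        assert prof.total_reads == 0

    def test_strand_mismatch_not_counted(self, tmp_path):
        bam = make_bam(tmp_path, [(988, 28, True)])
        prof = ac.extract_psite_profile(bam, self.model(), "full")
        assert prof.total_reads == 0

    def test_missing_chromosome_gives_empty_profile(self, tmp_path, caplog):
        bam = make_bam(tmp_path, [(988, 28, False)])
        m = ac.TranscriptModel("t2", "g", "chrZ", "+", [(1000, 1010)])
        with caplog.at_level("WARNING"):
            prof = ac.extract_psite_profile(bam, m, "full")
        assert prof.total_reads == 0 and "chrZ" in caplog.text

    def test_generator_truth_recovered_exactly(self, small_transcriptome):
        """Coverage extraction reproduces the simulator's count vectors."""
        cfg, tr, truth, _, d = small_transcriptome
        with pysam.AlignmentFile(str(d / "f.bam")) as bam:
            for m in tr.models:
                region = "CDS" if m.cds else "full"
                prof = ac.extract_psite_profile(bam, m, region)
                assert np.array_equal(prof.counts, truth.counts_of(m.transcript_id)), (
                    m.transcript_id
                )


class TestFpkm:
    def prof(self, counts):
        return ac.PSiteProfile("t", "full", np.asarray(counts))

    def test_definition(self):
        rec = ac.compute_fpkm(self.prof([1] * 100 + [0] * 900), 1_000_000)
        assert rec.fpkm == pytest.approx(100.0)

    def test_zero_reads_zero_fpkm(self):
        assert ac.compute_fpkm(self.prof([0] * 100), 10).fpkm == 0.0

    def test_worked_example(self):
        rec = ac.compute_fpkm(self.prof([1] * 50 + [0] * 450), 2_000_000)
        assert rec.fpkm == pytest.approx(50.0)

    def test_invariant_under_uniform_duplication(self):
        counts = np.array([3, 0, 2, 5])
        a = ac.compute_fpkm(ac.PSiteProfile("t", "full", counts), 1_000)
        b = ac.compute_fpkm(ac.PSiteProfile("t", "full", counts * 2), 2_000)
        assert a.fpkm == b.fpkm

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            ac.compute_fpkm(self.prof([1]), 0)


class TestConflictFilter:
    def mk(self, tid, biotype, strand, start, end, chrom="chr1"):
        return ac.TranscriptModel(tid, tid, chrom, strand, [(start, end)], biotype=biotype)

    def test_antisense_cross_class_pair_removed(self):
        a = self.mk("a", "protein_coding", "+", 100, 200)
        b = self.mk("b", "lincRNA", "-", 100, 200)
        assert ac.filter_conflicting_transcripts([a, b]) == []

    def test_same_class_overlap_retained(self):
        a = self.mk("a", "protein_coding", "+", 100, 200)
        b = self.mk("b", "protein_coding", "+", 150, 250)
        assert len(ac.filter_conflicting_transcripts([a, b])) == 2

    def test_distant_cross_class_pair_retained(self):
        a = self.mk("a", "protein_coding", "+", 100, 200)
        b = self.mk("b", "lincRNA", "+", 10_200, 10_300)
        assert len(ac.filter_conflicting_transcripts([a, b], flank=0)) == 2

    def test_flank_extends_conflict_reach(self):
        a = self.mk("a", "protein_coding", "+", 100, 200)
        b = self.mk("b", "lincRNA", "+", 250, 350)
        assert len(ac.filter_conflicting_transcripts([a, b], flank=0)) == 2
        assert ac.filter_conflicting_transcripts([a, b], flank=100) == []


def test_region_partition_covers_transcript(small_transcriptome):
    """5UTR + CDS + 3UTR coordinate sets partition each coding transcript."""
    _, tr, _, _, _ = small_transcriptome
    for m in tr.models:
        if not m.cds:
            continue
        parts = [m.region_coords(r) for r in ("5UTR", "CDS", "3UTR")]
        joined = np.concatenate(parts)
        assert np.array_equal(joined, m.region_coords("full"))
        assert m.region_length("CDS") % 3 == 0
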