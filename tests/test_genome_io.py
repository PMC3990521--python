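import numpy as np
import pytest

from occupeak import genome_io as gio


@pytest.fixture
def layout():
    return gio.GenomeLayout([("chr1", 1000), ("chr2", 500)])


class TestChromSizes:
    def test_parse(self, tmp_path):
        p = tmp_path / "g.chrom.sizes"
        p.write_text("chr1\t1000\nchr2\t500\n")
        layout = gio.read_chrom_sizes(p)
        assert layout.names == ["chr1", "chr2"]
        assert layout.total_length == 1500

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty"
        p.write_text("")
        with pytest.raises(ValueError, match="no chromosomes"):
            gio.read_chrom_sizes(p)

    def test_nonpositive_length_rejected(self, tmp_path):
        p = tmp_path / "bad"
        p.write_text("chr1\t0\n")
        with pytest.raises(ValueError, match="non-positive"):
            gio.read_chrom_sizes(p)

    def test_duplicate_chrom_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gio.GenomeLayout([("chr1", 10), ("chr1", 20)])

    def test_roundtrip(self, tmp_path, layout):
        gio.write_chrom_sizes(layout, tmp_path / "out")
        assert gio.read_chrom_sizes(tmp_path / "out") == layout


class TestPeakTable:
    def make_set(self):
        peaks = [
            gio.Peak(gio.GenomicInterval("chr1", 10, 210), 100, 2.5),
            gio.Peak(gio.GenomicInterval("chr1", 300, 500), 400, 0.0),
            gio.Peak(gio.GenomicInterval("chr2", 0, 100), 10, 17.25),
        ]
        return gio.PeakSet("demo", peaks, total_mapped_reads=1_000_000)

    def test_roundtrip_identity(self, tmp_path, layout):
        ps = self.make_set()
        gio.write_peak_table(ps, tmp_path / "p.tsv")
        back = gio.read_peak_table(tmp_path / "p.tsv", layout, name="demo")
        assert len(back) == 3
        for a, b in zip(ps, back):
            assert a.interval == b.interval
            assert a.summit == b.summit
            assert a.rpm == pytest.approx(b.rpm)

    def test_inverted_interval_rejected(self, tmp_path, layout):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tstart\tend\tsummit\trpm\nchr1\t100\t100\t100\t1\n")
        with pytest.raises(ValueError):
            gio.read_peak_table(p, layout)

    def test_out_of_bounds_rejected(self, tmp_path, layout):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tstart\tend\tsummit\trpm\nchr2\t400\t600\t450\t1\n")
        with pytest.raises(ValueError, match="out of bounds"):
            gio.read_peak_table(p, layout)

    def test_unknown_chrom_rejected(self, tmp_path, layout):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tstart\tend\tsummit\trpm\nchrX\t0\t10\t5\t1\n")
        with pytest.raises(ValueError, match="unknown chromosome"):
            gio.read_peak_table(p, layout)

    def test_negative_rpm_rejected(self, tmp_path, layout):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tstart\tend\tsummit\trpm\nchr1\t0\t10\t5\t-1\n")
        with pytest.raises(ValueError, match="negative rpm"):
            gio.read_peak_table(p, layout)


class TestGeneModel:
    def test_single_exon_fully_coding_has_empty_utrs(self):
        g = gio.GeneModel("g", "chr1", "+", 100, 400, 100, 400, ((100, 400),))
        assert g.utr5_blocks() == []
        assert g.utr3_blocks() == []
        assert g.coding_exon_blocks() == [(100, 400)]

    def test_two_exon_plus_strand_utr5_spans_first_exon(self):
        # CDS starts inside exon 2: 5'UTR is exon 1 plus the exon-2 prefix
        g = gio.GeneModel(
            "g", "chr1", "+", 100, 1000, 700, 900,
            ((100, 400), (600, 1000)),
        )
        assert g.utr5_blocks() == [(100, 400), (600, 700)]
        assert g.utr3_blocks() == [(900, 1000)]
        assert g.coding_exon_blocks() == [(700, 900)]
        assert g.intron_blocks() == [(400, 600)]
        # independent per-base check: every base's label from first principles
        exonic = set(range(100, 400)) | set(range(600, 1000))
        utr5 = {b for b in exonic if b < 700}
        utr3 = {b for b in exonic if b >= 900}
        assert {b for s, e in g.utr5_blocks() for b in range(s, e)} == utr5
        assert {b for s, e in g.utr3_blocks() for b in range(s, e)} == utr3

    def test_minus_strand_utrs_swap(self):
        g = gio.GeneModel(
            "g", "chr1", "-", 100, 1000, 700, 900,
            ((100, 400), (600, 1000)),
        )
        assert g.utr5_blocks() == [(900, 1000)]
        assert g.utr3_blocks() == [(100, 400), (600, 700)]
        assert g.tss == 999
        assert g.promoter(1000) == (1000, 2000)

    def test_unsorted_exons_rejected(self):
        with pytest.raises(ValueError, match="unsorted"):
            gio.GeneModel("g", "chr1", "+", 0, 100, 0, 100, ((50, 80), (10, 40)))


class TestRefFlat:
    def test_roundtrip(self, tmp_path, layout):
        genes = [
            gio.GeneModel("a", "chr1", "+", 100, 900, 200, 800,
                          ((100, 400), (600, 900))),
            gio.GeneModel("b", "chr2", "-", 0, 300, 50, 250, ((0, 300),)),
        ]
        gio.write_gene_annotation(genes, tmp_path / "g.refflat")
        back = gio.read_gene_annotation(tmp_path / "g.refflat", layout)
        assert back == genes

    def test_exon_count_mismatch_rejected(self, tmp_path, layout):
        p = tmp_path / "bad"
        p.write_text("g\tchr1\t+\t0\t100\t0\t100\t2\t0,\t100,\n")
        with pytest.raises(ValueError, match="exonCount mismatch"):
            gio.read_gene_annotation(p, layout)

    def test_empty_annotation_warns(self, tmp_path, layout, caplog):
        p = tmp_path / "empty"
        p.write_text("")
        with caplog.at_level("WARNING"):
            genes = gio.read_gene_annotation(p, layout)
        assert genes == []
        assert "no genes" in caplog.text


class TestSegmentation:
    def test_single_label_fraction_one(self, layout):
        seg = gio.StateSegmentation(
            layout,
            {"chr1": [(0, 1000, "A")], "chr2": [(0, 500, "A")]},
            ["A"],
        )
        assert seg.label_fractions == {"A": 1.0}

    def test_two_segment_fractions(self):
        layout = gio.GenomeLayout([("chr1", 1000)])
        seg = gio.StateSegmentation(
            layout, {"chr1": [(0, 100, "A"), (100, 1000, "B")]}, ["A", "B"]
        )
        assert seg.label_fractions["A"] == pytest.approx(0.1)
        assert seg.label_fractions["B"] == pytest.approx(0.9)

    def test_overlap_rejected(self):
        layout = gio.GenomeLayout([("chr1", 1000)])
        with pytest.raises(ValueError, match="overlap"):
            gio.StateSegmentation(
                layout, {"chr1": [(0, 600, "A"), (500, 1000, "B")]}, ["A", "B"]
            )

    def test_gap_rejected(self):
        layout = gio.GenomeLayout([("chr1", 1000)])
        with pytest.raises(ValueError, match="gap"):
            gio.StateSegmentation(
                layout, {"chr1": [(0, 400, "A"), (500, 1000, "B")]}, ["A", "B"]
            )

    def test_unknown_label_rejected(self):
        layout = gio.GenomeLayout([("chr1", 1000)])
        with pytest.raises(ValueError, match="unknown state"):
            gio.StateSegmentation(layout, {"chr1": [(0, 1000, "Z")]}, ["A"])

    def test_fractions_sum_to_one(self, sim):
        assert sum(sim.segmentation.label_fractions.values()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_roundtrip(self, tmp_path, sim):
        gio.write_state_segmentation(sim.segmentation, tmp_path / "s.bed")
        back = gio.read_state_segmentation(
            tmp_path / "s.bed", sim.layout, sim.segmentation.labels
        )
        assert back.segments == sim.segmentation.segments


class TestFastaBedTrack:
    def test_fasta_ok_and_length_mismatch(self, tmp_path):
        layout = gio.GenomeLayout([("chr1", 4)])
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        assert gio.read_fasta(p, layout) == {"chr1": "ACGT"}
        bad = gio.GenomeLayout([("chr1", 5)])
        with pytest.raises(ValueError, match="length"):
            gio.read_fasta(p, bad)

    def test_fasta_roundtrip(self, tmp_path):
        seqs = {"chr1": "ACGTACGT", "chr2": "TTTT"}
        gio.write_fasta(seqs, tmp_path / "g.fa")
        assert gio.read_fasta(tmp_path / "g.fa") == seqs

    def test_bed_roundtrip(self, tmp_path):
        ivs = [gio.GenomicInterval("chr1", 0, 10), gio.GenomicInterval("chr2", 5, 9)]
        gio.write_bed(ivs, tmp_path / "x.bed")
        assert gio.read_bed(tmp_path / "x.bed") == ivs

    def test_track_roundtrip(self, tmp_path):
        layout = gio.GenomeLayout([("chr1", 100)])
        t = gio.SignalTrack(layout, library_size=1000)
        t.add_reads("chr1", np.array([5, 5, 99]))
        gio.write_track(t, tmp_path / "t.tsv")
        back = gio.read_track(tmp_path / "t.tsv", layout)
        assert back.library_size == 1000
        assert np.array_equal(back.counts["chr1"], t.counts["chr1"])
        assert back.rpm_in("chr1", 0, 10) == pytest.approx(2000.0)


class TestGeneList:
    def test_roundtrip_and_resolution(self, tmp_path):
        gl = gio.GeneList("up", {"g1", "g2", "gX"})
        gio.write_gene_list(gl, tmp_path / "up.txt")
        back = gio.read_gene_list(tmp_path / "up.txt")
        assert back.gene_ids == gl.gene_ids
        genes = [
            gio.GeneModel("g1", "chr1", "+", 0, 100, 0, 100, ((0, 100),)),
            gio.GeneModel("g2", "chr1", "+", 200, 300, 200, 300, ((200, 300),)),
        ]
        resolved, unresolved = back.resolve(genes)
        assert resolved == {"g1", "g2"}
        assert unresolved == {"gX"}

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gio.GeneList("none", set())
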