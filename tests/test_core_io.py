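"""Parsers, serializers and coordinate conventions."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tuberkit.core import (CytosineRecord, FeatureRecord, FormatError,
                           GenomeSequence, union_length)
from tuberkit.io import (parse_atcgmap, parse_cgmap, parse_fasta,
                         parse_features, parse_transcript_gtf,
                         serialize_cgmap, serialize_tracks, write_fasta,
                         write_gff3)


# ---------------------------------------------------------------------------
# FASTA

class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGT\n")
        recs = parse_fasta(p)
        assert len(recs) == 1
        assert recs[0].contig_id == "c1"
        assert recs[0].sequence == "ACGT"
        assert recs[0].length == 4

    def test_case_folding_and_multi_line(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nac\ngt\n>c2\nNNN\n")
        recs = parse_fasta(p)
        assert [(r.contig_id, r.sequence) for r in recs] == [
            ("c1", "ACGT"), ("c2", "NNN")]

    @pytest.mark.parametrize("content,reason", [
        (">c1\nACXT\n", "illegal character"),
        (">c1\nAC\n>c1\nGT\n", "duplicate contig id"),
        ("", "empty file"),
    ])
    def test_invalid_inputs_rejected(self, tmp_path, content, reason):
        p = tmp_path / "g.fa"
        p.write_text(content)
        with pytest.raises(FormatError):
            parse_fasta(p)

    def test_round_trip(self, tmp_path, small_genome):
        genome, _ = small_genome
        p = tmp_path / "g.fa"
        write_fasta(genome, p)
        back = parse_fasta(p)
        assert [(g.contig_id, g.sequence) for g in back] == \
            [(g.contig_id, g.sequence) for g in genome]


# ---------------------------------------------------------------------------
# Features (GFF3 / BED)

class TestFeatures:
    def test_gff3_coordinates_become_half_open(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("c1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        (rec,) = parse_features(p, "GFF3")
        assert (rec.start, rec.end) == (100, 200)
        assert rec.feature_class == "gene"

    def test_bed_coordinates_passthrough(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("c1\t100\t200\tte1\n")
        (rec,) = parse_features(p, "BED")
        assert (rec.start, rec.end) == (100, 200)
        assert rec.feature_id == "te1"

    def test_exons_grouped_and_union_length(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(
            "c1\tsrc\tgene\t101\t300\t.\t+\t.\tID=g1\n"
            "c1\tsrc\texon\t101\t200\t.\t+\t.\tID=g1.e1;Parent=g1\n"
            "c1\tsrc\texon\t151\t300\t.\t+\t.\tID=g1.e2;Parent=g1\n")
        (rec,) = parse_features(p, "GFF3")
        # exons [100,200) and [150,300): union covers [100,300) = 200 bp
        assert rec.exon_intervals == [(100, 200), (150, 300)]
        assert rec.union_exon_length == 200

    def test_degenerate_interval_rejected(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("c1\tsrc\tgene\t200\t100\t.\t+\t.\tID=g1\n")
        with pytest.raises(FormatError):
            parse_features(p, "GFF3")

    def test_gff3_round_trip(self, tmp_path, small_genome):
        _, features = small_genome
        p = tmp_path / "f.gff3"
        write_gff3(features, p)
        back = parse_features(p, "GFF3")
        assert [(f.feature_id, f.contig_id, f.start, f.end, f.strand,
                 f.feature_class) for f in back] == \
            [(f.feature_id, f.contig_id, f.start, f.end, f.strand,
              f.feature_class) for f in features]


@given(st.lists(
    st.tuples(st.integers(0, 500), st.integers(1, 100)).map(
        lambda t: (t[0], t[0] + t[1])),
    min_size=0, max_size=15))
@settings(deadline=None, max_examples=200)
def test_union_length_matches_position_set_oracle(intervals):
    """Interval-union length equals the size of the union of position sets."""
    expected = len(set().union(*[set(range(s, e)) for s, e in intervals])) \
        if intervals else 0
    assert union_length(intervals) == expected


# ---------------------------------------------------------------------------
# CGmap / ATCGmap

class TestCgmap:
    def test_plus_strand_record(self, tmp_path):
        p = tmp_path / "x.cgmap"
        p.write_text("c1\tC\t3\tCG\tCG\t0.75\t6\t8\n")
        (r,) = parse_cgmap(p)
        assert (r.strand, r.position, r.context) == ("+", 3, "CG")
        assert (r.mc_count, r.t_count) == (6, 2)
        assert r.level == 0.75

    def test_minus_strand_convention(self, tmp_path):
        p = tmp_path / "x.cgmap"
        p.write_text("c1\tG\t4\tCG\tCG\t0.0\t0\t5\n")
        (r,) = parse_cgmap(p)
        assert r.strand == "-"
        assert r.level == 0.0

    @pytest.mark.parametrize("line", [
        "c1\tC\t3\tCG\tCG\t0.9\t6\t8",     # level inconsistent with counts
        "c1\tC\t3\tCG\tCG\t0.75\t9\t8",    # mc > coverage
        "c1\tC\t3\tBAD\tCG\t0.75\t6\t8",   # unknown context token
        "c1\tX\t3\tCG\tCG\t0.75\t6\t8",    # bad nucleotide column
    ])
    def test_malformed_lines_abort_with_line_number(self, tmp_path, line):
        p = tmp_path / "x.cgmap"
        p.write_text(line + "\n")
        with pytest.raises(FormatError, match="line 1"):
            parse_cgmap(p)

    def test_empty_list_serializes_to_empty_file(self, tmp_path):
        p = tmp_path / "x.cgmap"
        serialize_cgmap([], p)
        assert p.read_text() == ""

    def test_unknown_context_skipped_with_warning(self, tmp_path, caplog):
        rec = CytosineRecord("c1", 5, "+", "unknown", "CN", 1, 1)
        p = tmp_path / "x.cgmap"
        with caplog.at_level("WARNING"):
            serialize_cgmap([rec], p)
        assert p.read_text() == ""
        assert "skipped 1" in caplog.text


@given(st.lists(st.tuples(
    st.integers(1, 10_000),                     # position
    st.sampled_from("CG"),                      # strand nucleotide
    st.sampled_from(["CG", "CHG", "CHH"]),
    st.integers(0, 60), st.integers(0, 60)),    # mc, t
    min_size=0, max_size=50, unique_by=lambda t: (t[0], t[1])))
@settings(deadline=None, max_examples=100)
def test_cgmap_round_trip_property(tmp_path_factory, rows):
    """parse(serialize(x)) reproduces every representable record exactly."""
    records = [
        CytosineRecord("c1", pos, "+" if nuc == "C" else "-", ctx,
                       "CG" if ctx == "CG" else "CA", mc, t)
        for pos, nuc, ctx, mc, t in rows]
    p = tmp_path_factory.mktemp("cgmap") / "x.cgmap"
    serialize_cgmap(records, p)
    back = parse_cgmap(p)
    assert [(r.contig_id, r.position, r.strand, r.context, r.mc_count,
             r.t_count) for r in back] == \
        [(r.contig_id, r.position, r.strand, r.context, r.mc_count,
          r.t_count) for r in records]


def test_atcgmap_strand_resolved_counts(tmp_path):
    """Watson C/T columns feed plus-strand sites, Crick G/A minus-strand."""
    p = tmp_path / "x.atcgmap"
    p.write_text(
        # contig nuc pos ctx dinuc  WA WT WC WG  CA CT CC CG
        "c1\tC\t3\tCG\tCG\t0\t2\t6\t0\t0\t0\t0\t0\n"
        "c1\tG\t4\tCG\tCG\t0\t0\t0\t0\t3\t0\t0\t7\n")
    plus, minus = parse_atcgmap(p)
    assert (plus.strand, plus.mc_count, plus.t_count) == ("+", 6, 2)
    assert (minus.strand, minus.mc_count, minus.t_count) == ("-", 7, 3)


# ---------------------------------------------------------------------------
# Transcript GTF

class TestTranscriptGtf:
    GTF = ('c1\tasm\ttranscript\t101\t600\t.\t+\t.\t'
           'gene_id "x"; transcript_id "t1"; class_code "u"; FPKM "5.0"; '
           'conf_lo "4.0"; conf_hi "6.0";\n'
           'c1\tasm\ttranscript\t700\t900\t.\t+\t.\t'
           'gene_id "y"; transcript_id "t2"; class_code "=";\n')

    def test_attributes_parsed(self, tmp_path):
        p = tmp_path / "t.gtf"
        p.write_text(self.GTF)
        t1, t2 = parse_transcript_gtf(p)
        assert (t1.class_code, t1.fpkm, t1.fpkm_conf_lo) == ("u", 5.0, 4.0)
        assert (t1.start, t1.end) == (100, 600)
        assert t2.class_code == "="
        assert not t2.has_confidence_interval  # flagged: no FPKM attributes

    def test_confidence_interval_invariant_enforced(self, tmp_path):
        p = tmp_path / "t.gtf"
        p.write_text('c1\tasm\ttranscript\t1\t100\t.\t+\t.\t'
                     'transcript_id "t1"; class_code "u"; FPKM "3.0"; '
                     'conf_lo "4.0"; conf_hi "6.0";\n')
        with pytest.raises(FormatError):
            parse_transcript_gtf(p)


# ---------------------------------------------------------------------------
# Tracks

class TestTracks:
    def test_wiggle_variable_step(self, tmp_path):
        rec = CytosineRecord("c1", 3, "+", "CG", "CG", 6, 2)
        p = tmp_path / "x.wig"
        serialize_tracks([rec], p, "wiggle")
        lines = p.read_text().splitlines()
        assert lines[1] == "variableStep chrom=c1"
        assert lines[2] == "3\t0.75"

    def test_empty_input_gives_header_only(self, tmp_path):
        p = tmp_path / "x.wig"
        serialize_tracks([], p, "wiggle")
        assert len(p.read_text().splitlines()) == 1

    def test_unsorted_input_names_offender(self, tmp_path):
        recs = [CytosineRecord("c1", 9, "+", "CG", "CG", 1, 1),
                CytosineRecord("c1", 3, "+", "CG", "CG", 1, 1)]
        with pytest.raises(ValueError, match="index 1"):
            serialize_tracks(recs, tmp_path / "x.wig", "wiggle")

    def test_bed_interval_output(self, tmp_path):
        feat = FeatureRecord("w1", "c1", 200_000, 300_000)
        p = tmp_path / "x.bed"
        serialize_tracks([feat], p, "BED")
        assert p.read_text().splitlines()[1].startswith(
            "c1\t200000\t300000")
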