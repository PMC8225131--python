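"""Domain types, circular arithmetic, and format round-trips."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from mitochar import (AnnotationSet, GeneFeature, MitogenomeRecord,
                      extract_sequence, feature_length, read_fasta,
                      read_feature_table, read_genbank, reverse_complement,
                      validate_annotation, write_fasta, write_feature_table)
from mitochar.core import FeatureTableError


def make_feature(start, end, strand="J", wraps=False, name="g", category="PCG"):
    return GeneFeature(name=name, category=category, strand=strand,
                       start=start, end=end, wraps=wraps)


class TestFeatureLength:
    @pytest.mark.parametrize("start,end,L,expected", [
        (1, 69, 15147, 69),        # trnM-sized feature
        (15000, 100, 15100, 201),  # wraps the origin
        (5, 5, 100, 1),
    ])
    def test_lengths(self, start, end, L, expected):
        f = make_feature(start, end, wraps=end < start)
        assert feature_length(f, L) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            feature_length(make_feature(5, 50), 40)

    def test_partition_of_circle_sums_to_genome_length(self):
        rng = random.Random(42)
        for _ in range(50):
            L = rng.randint(20, 500)
            ncuts = rng.randint(1, 8)
            cuts = sorted(rng.sample(range(1, L + 1), ncuts))
            feats = []
            for a, b in zip(cuts, cuts[1:]):
                feats.append(make_feature(a, b - 1))
            # the closing feature runs from the last cut around to cut[0]-1,
            # crossing the origin unless the first cut sits at position 1
            if cuts[0] > 1:
                feats.append(make_feature(cuts[-1], cuts[0] - 1, wraps=True))
            else:
                feats.append(make_feature(cuts[-1], L))
            total = sum(feature_length(f, L) for f in feats)
            assert total == L


class TestExtractSequence:
    def test_j_strand_interval(self):
        rec = MitogenomeRecord(id="x", sequence="ATGCC")
        assert extract_sequence(rec, make_feature(1, 3)) == "ATG"

    def test_n_strand_is_reverse_complement(self):
        rec = MitogenomeRecord(id="x", sequence="ATGCC")
        assert extract_sequence(rec, make_feature(1, 3, strand="N")) == "CAT"

    def test_wrapping_concatenates_suffix_and_prefix(self):
        rec = MitogenomeRecord(id="x", sequence="ATGCC")
        assert extract_sequence(rec, make_feature(4, 2, wraps=True)) == "CCAT"

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=60),
           st.data())
    def test_strand_antisymmetry(self, seq, data):
        rec = MitogenomeRecord(id="x", sequence=seq)
        a = data.draw(st.integers(1, len(seq)))
        b = data.draw(st.integers(a, len(seq)))
        j = extract_sequence(rec, make_feature(a, b, strand="J"))
        n = extract_sequence(rec, make_feature(a, b, strand="N"))
        assert n == reverse_complement(j)
        assert len(j) == feature_length(make_feature(a, b), len(seq))


class TestFasta:
    def test_parse_and_uppercase(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nacGT\n")
        (rec,) = read_fasta(p)
        assert (rec.id, rec.sequence) == ("x", "ACGT")

    def test_round_trip_identity(self, tmp_path):
        recs = [MitogenomeRecord(id=f"r{i}", sequence="ACGTAC" * (i + 1))
                for i in range(3)]
        p = tmp_path / "multi.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.sequence) for r in back] == \
            [(r.id, r.sequence) for r in recs]

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">x\nAC\n>x\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)


class TestFeatureTable:
    HEADER = ("record_id\tgene\tcategory\tstrand\tstart\tend\tanticodon"
              "\tgenome_length\n")

    def test_single_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER +
                     "NW732137\ttrnM\ttRNA\tJ\t1\t69\tCAT\t15147\n")
        (ann,) = read_feature_table(p)
        f = ann.features[0]
        assert feature_length(f, ann.genome_length) == 69
        assert f.anticodon == "CAT"

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER)
        assert read_feature_table(p) == []

    def test_bad_strand_names_row(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER + "r1\ttrnM\ttRNA\t+\t1\t69\tCAT\t15147\n")
        with pytest.raises(FeatureTableError, match="row 2"):
            read_feature_table(p)

    def test_non_integer_coordinate_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER + "r1\ttrnM\ttRNA\tJ\tone\t69\tCAT\t15147\n")
        with pytest.raises(FeatureTableError, match="non-integer"):
            read_feature_table(p)

    def test_duplicate_unsuffixed_trna_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER
                     + "r1\ttrnL\ttRNA\tJ\t1\t60\tTAA\t15147\n"
                     + "r1\ttrnL\ttRNA\tN\t100\t160\tTAG\t15147\n")
        with pytest.raises(FeatureTableError, match="unsuffixed tRNA"):
            read_feature_table(p)

    def test_round_trip_lossless(self, tmp_path, study_annotations):
        p = tmp_path / "rt.tsv"
        write_feature_table(study_annotations, p)
        back = read_feature_table(p)
        assert len(back) == len(study_annotations)
        for a, b in zip(study_annotations, back):
            assert a.record_id == b.record_id
            assert a.genome_length == b.genome_length
            assert [f.__dict__ for f in a.features] == \
                [f.__dict__ for f in b.features]


class TestValidation:
    def test_study_control_region_rows_flagged(self, study_annotations):
        # the printed A+T-rich-region coordinates extend past the stated
        # genome sizes in all three genomes; they are flagged, not corrected
        for ann in study_annotations:
            report = validate_annotation(None, ann)
            assert not report.ok
            assert any("CR" in v for v in report.coordinate_violations)
            others = [v for v in report.coordinate_violations
                      if not v.startswith("CR")]
            assert others == []

    def test_feature_past_genome_end_flagged(self):
        ann = AnnotationSet("r", [make_feature(1, 101)], 100)
        report = validate_annotation(None, ann)
        assert len(report.coordinate_violations) == 1

    def test_trna_without_anticodon_warned(self):
        ann = AnnotationSet(
            "r", [GeneFeature("trnM", "tRNA", "J", 1, 66)], 100)
        report = validate_annotation(None, ann)
        assert report.ok
        assert any("anticodon" in w for w in report.warnings)

    def test_large_same_strand_pcg_overlap_flagged(self):
        ann = AnnotationSet("r", [make_feature(1, 60, name="a"),
                                  make_feature(30, 90, name="b")], 100)
        report = validate_annotation(None, ann)
        assert any("overlap of 31" in v for v in report.overlap_violations)


GENBANK = """LOCUS       synth                 40 bp    DNA     circular INV
FEATURES             Location/Qualifiers
     CDS             3..11
                     /gene="ND2"
     tRNA            complement(14..20)
                     /gene="trnQ"
                     /anticodon="uug"
     rRNA            join(35..40,1..2)
                     /gene="rrnS"
ORIGIN
        1 atgaaatagc catgcatgca tgcatgcatg catgcatgca
//
"""


class TestGenBank:
    def test_limited_flat_file_subset(self, tmp_path):
        p = tmp_path / "g.gb"
        p.write_text(GENBANK)
        ((rec, ann),) = read_genbank(p)
        assert len(rec) == 40
        by = {f.name: f for f in ann.features}
        assert (by["ND2"].category, by["ND2"].strand) == ("PCG", "J")
        assert (by["trnQ"].strand, by["trnQ"].anticodon) == ("N", "TTG")
        assert by["rrnS"].wraps and (by["rrnS"].start, by["rrnS"].end) == (35, 2)
        assert feature_length(by["rrnS"], 40) == 8
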