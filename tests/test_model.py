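"""Gene-model types, GFF3 round-tripping and structural derivations."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annodiff.model import (
    AnnotationSet,
    GenomicInterval,
    Gff3ParseError,
    IntronKey,
    TranscriptModel,
    ValidationError,
    gc_content,
    introns_of,
    merge_intervals,
    parse_gff3,
    reverse_complement,
    translate_cds,
    write_gff3,
)
from conftest import make_gene


class TestParsing:
    def test_tiny_file_builds_expected_hierarchy(self, tiny_gff3):
        annot = parse_gff3(tiny_gff3)
        assert len(annot) == 1
        g = annot.genes["geneA"]
        assert len(g.transcripts) == 1
        t = g.transcripts[0]
        assert [(e.start, e.end) for e in t.exons] == [(101, 200), (301, 400)]
        assert len(t.cds_segments) == 2
        assert not t.utr5 and not t.utr3  # fully coding -> no derived UTRs

    def test_round_trip_is_identity(self, tiny_gff3, tmp_path):
        annot = parse_gff3(tiny_gff3)
        out = tmp_path / "rt.gff3"
        write_gff3(annot, str(out))
        again = parse_gff3(str(out))
        assert again == annot
        # and a second round trip is byte-stable
        out2 = tmp_path / "rt2.gff3"
        write_gff3(again, str(out2))
        assert out.read_text() == out2.read_text()

    def test_cds_outside_exon_is_rejected(self, tmp_path):
        bad = tmp_path / "bad.gff3"
        bad.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t100\t600\t.\t+\t.\tID=g\n"
            "chr1\tt\tmRNA\t100\t600\t.\t+\t.\tID=g.t1;Parent=g\n"
            "chr1\tt\texon\t100\t200\t.\t+\t.\tID=e;Parent=g.t1\n"
            "chr1\tt\tCDS\t500\t600\t.\t+\t0\tID=c;Parent=g.t1\n"
        )
        with pytest.raises(ValidationError, match="g.t1"):
            parse_gff3(str(bad))

    def test_malformed_line_reports_line_number(self, tmp_path):
        bad = tmp_path / "mal.gff3"
        bad.write_text("##gff-version 3\nchr1\tonly\tthree\n")
        with pytest.raises(Gff3ParseError, match="line 2"):
            parse_gff3(str(bad))

    def test_utrs_derived_as_exon_minus_cds(self, tmp_path):
        p = tmp_path / "utr.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tt\tgene\t100\t400\t.\t-\t.\tID=g\n"
            "chr1\tt\tmRNA\t100\t400\t.\t-\t.\tID=g.t1;Parent=g\n"
            "chr1\tt\texon\t100\t200\t.\t-\t.\tID=e1;Parent=g.t1\n"
            "chr1\tt\texon\t300\t400\t.\t-\t.\tID=e2;Parent=g.t1\n"
            "chr1\tt\tCDS\t150\t200\t.\t-\t.\tID=c;Parent=g.t1\n"
            "chr1\tt\tCDS\t300\t350\t.\t-\t.\tID=c;Parent=g.t1\n"
        )
        t = parse_gff3(str(p)).genes["g"].transcripts[0]
        # minus strand: 5' UTR is genomically rightmost
        assert [(u.start, u.end) for u in t.utr5] == [(351, 400)]
        assert [(u.start, u.end) for u in t.utr3] == [(100, 149)]

    def test_empty_set_writes_header_only(self, tmp_path):
        out = tmp_path / "empty.gff3"
        write_gff3(AnnotationSet("empty", []), str(out))
        lines = out.read_text().splitlines()
        assert all(line.startswith("#") for line in lines)
        assert len(parse_gff3(str(out))) == 0


class TestIntrons:
    @pytest.mark.parametrize(
        "exons,expected",
        [
            ([(101, 200), (301, 400)], [(201, 300)]),
            ([(101, 200)], []),
            ([(101, 200), (301, 400), (501, 700)], [(201, 300), (401, 500)]),
        ],
    )
    def test_intron_keys_span_gaps(self, exons, expected):
        g = make_gene("g", exons)
        keys = introns_of(g.transcripts[0], basis="exon")
        assert [(k.first, k.last) for k in keys] == expected

    def test_cds_basis_uses_cds_chain(self):
        g = make_gene("g", [(1, 300)], cds=[(50, 100), (201, 250)])
        keys = introns_of(g.transcripts[0], basis="cds")
        assert [(k.first, k.last) for k in keys] == [(101, 200)]

    @given(
        st.lists(
            st.tuples(st.integers(1, 10_000), st.integers(1, 300)),
            min_size=1, max_size=12,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_intron_count_is_exon_count_minus_one(self, raw):
        # build disjoint exons separated by >= 2 bp from (gap, length) pairs
        exons, pos = [], 0
        for gap, length in raw:
            start = pos + gap + 2
            exons.append((start, start + length))
            pos = start + length
        g = make_gene("g", exons)
        assert len(introns_of(g.transcripts[0])) == len(exons) - 1

    def test_intron_key_rejects_inverted_coordinates(self):
        with pytest.raises(ValidationError):
            IntronKey("chr1", "+", 10, 5)


class TestTranslation:
    def test_forward_cds(self):
        genome = {"chr1": "NN" + "ATGAAATAG" + "NN"}
        g = make_gene("g", [(3, 11)])
        tr = translate_cds(g.transcripts[0], genome)
        assert (tr.protein, tr.has_start, tr.has_stop) == ("MK", True, True)

    def test_missing_start_detected(self):
        genome = {"chr1": "AAAAAATAG"}
        g = make_gene("g", [(1, 9)])
        tr = translate_cds(g.transcripts[0], genome)
        assert not tr.has_start and tr.has_stop

    def test_minus_strand_symmetry(self):
        # genome holds the reverse complement of ATGAAATAG
        genome = {"chr1": reverse_complement("ATGAAATAG")}
        g = make_gene("g", [(1, 9)], strand="-")
        tr = translate_cds(g.transcripts[0], genome)
        assert (tr.protein, tr.has_start, tr.has_stop) == ("MK", True, True)

    def test_spliced_minus_strand_cds(self):
        # CDS ATGAAATAG split 5/4 across two exons on the minus strand
        s = reverse_complement("ATGAAATAG")
        genome = {"chr1": s[:4] + "CCCCC" + s[4:]}
        g = make_gene("g", [(1, 4), (10, 14)], strand="-")
        tr = translate_cds(g.transcripts[0], genome)
        assert tr.protein == "MK" and tr.has_start and tr.has_stop

    def test_frameshifted_cds_flagged(self):
        genome = {"chr1": "ATGAAAT"}
        g = make_gene("g", [(1, 7)])
        tr = translate_cds(g.transcripts[0], genome)
        assert tr.incomplete_codon and tr.protein == "MK"


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 0.5), ("AAAA", 0.0), ("GGCC", 1.0)]
    )
    def test_known_fractions(self, seq, expected):
        assert gc_content(seq) == expected

    def test_n_excluded_and_all_n_undefined(self):
        assert gc_content("GCNN") == 1.0
        assert gc_content("NNNN") is None
        assert gc_content("") is None

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    @settings(max_examples=100, derandomize=True)
    def test_reverse_complement_invariance(self, seq):
        assert gc_content(seq) == gc_content(reverse_complement(seq))


class TestIntervalIndex:
    def test_index_matches_brute_force(self):
        import numpy as np

        rng = np.random.default_rng(42)
        genes = []
        for i in range(100):
            s = int(rng.integers(1, 5000))
            e = s + int(rng.integers(10, 400))
            genes.append(make_gene(f"g{i:03d}", [(s, e)], seq_id="chr1"))
        annot = AnnotationSet("x", genes)
        for _ in range(200):
            qs = int(rng.integers(1, 5200))
            qe = qs + int(rng.integers(1, 300))
            got = {g.id for g in annot.query("chr1", qs, qe)}
            expected = {
                g.id
                for g in genes
                for s, e in g.cds_union
                if s <= qe and qs <= e
            }
            assert got == expected

    def test_query_unknown_sequence_is_empty(self):
        annot = AnnotationSet("x", [make_gene("g", [(1, 10)])])
        assert annot.query("chrZ", 1, 100) == []


def test_merge_intervals_unions_overlapping_and_abutting():
    # abutting closed intervals form one contiguous per-base union
    assert merge_intervals([(5, 10), (1, 6), (11, 13)]) == [(1, 13)]
    assert merge_intervals([(1, 10), (12, 14)]) == [(1, 10), (12, 14)]
    assert merge_intervals([]) == []
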