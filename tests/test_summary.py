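"""Summary panel, derived ratios, ORF scan and gene-set filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annodiff.model import AnnotationSet, reverse_complement
from annodiff.summary import (
    derive_ratios,
    filter_gene_models,
    filter_short_transcripts,
    find_complete_orfs,
    longest_complete_orf,
    percent,
    round_report,
    summarize,
)
from conftest import make_gene

STOPS = {"TAA", "TAG", "TGA"}


class TestSummarize:
    def test_empty_annotation(self):
        panel = summarize(AnnotationSet("x", []), {"chr1": "A" * 1000})
        assert panel.genome_size == 1000
        assert panel.n_genes == panel.n_exons == panel.n_introns == 0
        assert panel.mean_gene_length is None
        assert panel.gene_density is None

    def test_two_gene_hand_tally(self):
        # one 2-exon plus-strand gene, one 1-exon minus-strand gene
        genome = {"chr1": "ACGT" * 250}
        g1 = make_gene("g1", [(11, 40), (61, 90)])
        g2 = make_gene("g2", [(201, 260)], strand="-")
        panel = summarize(AnnotationSet("x", [g1, g2]), genome)
        assert panel.n_genes == 2
        assert (panel.n_genes_plus, panel.n_genes_minus) == (1, 1)
        assert panel.n_exons == 3
        assert panel.n_introns == 1
        assert panel.pct_transcripts_with_introns == 0.5
        assert panel.mean_intron_length == 20
        assert panel.total_exon_length == 30 + 30 + 60
        assert panel.mean_gene_length == (80 + 60) / 2
        # CDS union = exon bases here: (30+30+60)/1000
        assert panel.pct_coding == pytest.approx(0.12)

    def test_overlapping_isoform_cds_not_double_counted(self):
        genome = {"chr1": "ACGT" * 100}
        g = make_gene("g", [(1, 60)], isoforms=[[(1, 30)]])
        panel = summarize(AnnotationSet("x", [g]), genome)
        assert panel.pct_coding == pytest.approx(60 / 400)
        assert 0 <= panel.pct_coding <= 1

    def test_missing_sequence_reported(self):
        with pytest.raises(Exception, match="chr9"):
            summarize(
                AnnotationSet("x", [make_gene("g", [(1, 9)], seq_id="chr9")]),
                {"chr1": "ACGT"},
            )

    def test_intron_identity_on_simulated_data(self, small_sim):
        from pyfaidx import Fasta

        from annodiff.model import parse_gff3

        annot = parse_gff3(small_sim.v2_gff3)
        panel = summarize(annot, Fasta(small_sim.genome_fa))
        assert panel.n_introns == panel.n_exons - panel.n_transcripts
        assert panel.n_genes_plus + panel.n_genes_minus == panel.n_genes
        assert 0 <= panel.pct_coding <= 1


class TestDeriveRatios:
    def test_per_transcript_means_from_published_totals(self):
        r = derive_ratios({"n_exons": 136008, "n_transcripts": 25600})
        assert round_report(r["mean_exons_per_transcript"], 2) == 5.31
        assert r["implied_introns"] == 110408

    def test_gene_density_from_published_totals(self):
        r = derive_ratios({"genome_size": 197271687, "n_genes": 23248})
        assert round_report(r["gene_density"], 1) == 8.5

    def test_single_exon_single_transcript(self):
        r = derive_ratios({"n_exons": 1, "n_transcripts": 1})
        assert round_report(r["mean_exons_per_transcript"], 2) == 1.0
        assert r["implied_introns"] == 0

    def test_zero_denominators_are_missing(self):
        r = derive_ratios({"genome_size": 100, "n_genes": 0,
                           "n_exons": 0, "n_transcripts": 0})
        assert r["gene_density"] is None
        assert r["mean_exons_per_transcript"] is None


class TestRounding:
    def test_half_up_versus_truncate(self):
        assert round_report(87.57, 1, "half-up") == 87.6
        assert round_report(87.57, 1, "truncate") == 87.5
        assert round_report(2.5, 0, "half-up") == 3
        assert percent(1, 0) is None


def _orf_oracle(seq):
    """Every ATG..first-in-frame-stop ORF, as (strand, start, end) 1-based."""
    orfs = set()
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        n = len(s)
        for i in range(n - 5):
            if s[i : i + 3] != "ATG":
                continue
            for j in range(i + 3, n - 2, 3):
                if s[j : j + 3] in STOPS:
                    if strand == "+":
                        orfs.add((strand, i + 1, j + 3))
                    else:
                        orfs.add((strand, n - (j + 3) + 1, n - i))
                    break
    return orfs


class TestOrfScan:
    def test_simple_complete_orf(self):
        records, complete = find_complete_orfs({"t": "ATGAAATAA"}, min_nt=6)
        assert complete["t"]
        best = longest_complete_orf(records)["t"]
        assert (best.start, best.end, best.length) == (1, 9, 9)
        assert best.complete and best.length % 3 == 0

    def test_no_orf_without_start_or_stop(self):
        _, complete = find_complete_orfs({"t": "CCCAAACCC"}, min_nt=6)
        assert not complete["t"]

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            records, complete = find_complete_orfs({"t": seq}, min_nt=30)
            oracle = _orf_oracle(seq)
            # flag parity: any complete ORF >= 30 nt
            assert complete["t"] == any(e - s + 1 >= 30 for _, s, e in oracle)
            if oracle:
                best = longest_complete_orf(records)["t"]
                assert best.length == max(e - s + 1 for _, s, e in oracle)
            # every reported ORF is real
            for r in records:
                assert (r.strand, r.start, r.end) in oracle

    @given(st.text(alphabet="ACGT", min_size=9, max_size=120))
    @settings(max_examples=60, derandomize=True)
    def test_strand_symmetry(self, seq):
        _, fwd = find_complete_orfs({"t": seq}, min_nt=9)
        _, rev = find_complete_orfs({"t": reverse_complement(seq)}, min_nt=9)
        assert fwd["t"] == rev["t"]


def _coding_gene(gene_id, n_aa, start=True, stop=True):
    """A single-exon gene encoding n_aa residues, plus its genome."""
    first = "ATG" if start else "CTG"
    body = "GCT" * (n_aa - 1)
    last = "TAA" if stop else "GCA"
    seq = first + body + last
    g = make_gene(gene_id, [(1, len(seq))], seq_id=gene_id)
    return g, {gene_id: seq}


class TestFilters:
    @pytest.mark.parametrize(
        "n_aa,start,stop,kept",
        [
            (49, True, True, False),   # below the length threshold
            (50, True, True, True),    # exactly at the threshold
            (80, True, False, False),  # missing stop codon
            (80, False, True, False),  # missing start codon
        ],
    )
    def test_protein_filter_boundaries(self, n_aa, start, stop, kept):
        g, genome = _coding_gene("g", n_aa, start, stop)
        result, removed = filter_gene_models(
            AnnotationSet("x", [g]), genome, min_aa=50
        )
        assert (len(result) == 1) is kept
        assert (len(removed) == 0) is kept

    def test_gene_survives_through_any_passing_isoform(self):
        seq = "ATG" + "GCT" * 59 + "TAA"
        g = make_gene("g", [(1, len(seq))], seq_id="c",
                      isoforms=[[(1, 30)]])  # second isoform is too short
        result, removed = filter_gene_models(
            AnnotationSet("x", [g]), {"c": seq}, min_aa=50
        )
        assert len(result) == 1 and not removed

    def test_filter_is_idempotent(self):
        genes, genome = [], {}
        for i, n_aa in enumerate((20, 50, 49, 120)):
            g, gen = _coding_gene(f"g{i}", n_aa)
            genes.append(g)
            genome.update(gen)
        once, _ = filter_gene_models(AnnotationSet("x", genes), genome)
        twice, removed2 = filter_gene_models(once, genome)
        assert [g.id for g in twice] == [g.id for g in once]
        assert not removed2

    @pytest.mark.parametrize(
        "length,kept", [(149, False), (150, True), (151, True)]
    )
    def test_transcript_length_boundary(self, length, kept):
        seqs = {"t": "A" * length}
        result, removed = filter_short_transcripts(seqs, min_len=150)
        assert ("t" in result) is kept
        assert (removed == []) is kept

    def test_empty_transcript_set(self):
        assert filter_short_transcripts({}) == ({}, [])
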