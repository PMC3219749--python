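import pytest

from annodiff import simulate as sim
from annodiff.model import GeneModel, GenomicInterval, TranscriptModel

TINY_GFF3 = """\
##gff-version 3
chr1\ttest\tgene\t101\t400\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttest\texon\t101\t200\t.\t+\t.\tID=geneA.t1.e1;Parent=geneA.t1
chr1\ttest\texon\t301\t400\t.\t+\t.\tID=geneA.t1.e2;Parent=geneA.t1
chr1\ttest\tCDS\t101\t200\t.\t+\t0\tID=geneA.t1.cds;Parent=geneA.t1
chr1\ttest\tCDS\t301\t400\t.\t+\t2\tID=geneA.t1.cds;Parent=geneA.t1
"""


@pytest.fixture
def tiny_gff3(tmp_path):
    p = tmp_path / "tiny.gff3"
    p.write_text(TINY_GFF3)
    return str(p)


def make_gene(gene_id, exons, strand="+", seq_id="chr1", cds=None, isoforms=None):
    """Build a single- or multi-isoform gene from (start, end) pairs.

    ``isoforms`` is a list of exon-pair lists for extra transcripts; CDS
    defaults to the exon coordinates (fully coding gene).
    """
    def tx(tid, pairs, cds_pairs):
        ivs = [GenomicInterval(seq_id, s, e, strand) for s, e in pairs]
        cvs = [GenomicInterval(seq_id, s, e, strand) for s, e in cds_pairs]
        return TranscriptModel(tid, gene_id, ivs, cvs)

    transcripts = [tx(f"{gene_id}.t1", exons, cds if cds is not None else exons)]
    for i, pairs in enumerate(isoforms or [], start=2):
        transcripts.append(tx(f"{gene_id}.t{i}", pairs, pairs))
    return GeneModel(gene_id, seq_id, strand, transcripts)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A quick simulation exercising every planted event kind."""
    cfg = sim.SimConfig(
        seed=7, n_genes=120, n_merge=5, n_split=5, n_shift=10,
        n_specific_v1=5, n_specific_v2=5, n_seqs=3, seq_length=200_000,
        fraction_multi_isoform=0.1,
    )
    return sim.generate(cfg, str(tmp_path_factory.mktemp("small_sim")))


@pytest.fixture(scope="session")
def scale_sim(tmp_path_factory):
    """The full-scale study-condition simulation: 2,000 genes with 30
    merges, 30 splits, 100 boundary shifts and 50+50 version-specific
    genes."""
    cfg = sim.SimConfig(
        seed=5, n_genes=2000, n_merge=30, n_split=30, n_shift=100,
        n_specific_v1=50, n_specific_v2=50, n_seqs=8, seq_length=600_000,
    )
    return sim.generate(cfg, str(tmp_path_factory.mktemp("scale_sim")))
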