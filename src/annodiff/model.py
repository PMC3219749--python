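"""Core gene-model data types and GFF3/FASTA plumbing.

The object hierarchy mirrors the GFF3 gene/mRNA/exon/CDS convention:
an :class:`AnnotationSet` holds :class:`GeneModel` records, each of which
holds one or more :class:`TranscriptModel` isoforms.  All coordinates are
1-based inclusive genome coordinates, as on disk.  Intron identity is exact
coordinate equality of ``(seq_id, strand, first, last)`` — an intron is
"the same" only when both splice boundaries agree to the base.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "IntronKey",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "TranslationResult",
    "Gff3ParseError",
    "ValidationError",
    "parse_gff3",
    "write_gff3",
    "introns_of",
    "translate_cds",
    "gc_content",
    "merge_intervals",
    "reverse_complement",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


class Gff3ParseError(ValueError):
    """Raised for unparseable GFF3 input (carries the offending line number)."""


class ValidationError(ValueError):
    """Raised when a parsed feature hierarchy violates gene-model invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed 1-based interval on one strand of one sequence."""

    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, order=True)
class IntronKey:
    """Exact-coordinate identity of one intron.

    ``first``/``last`` are the first and last intronic bases (1-based,
    inclusive), i.e. the gap between two consecutive exons or CDS segments.
    """

    seq_id: str
    strand: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValidationError(f"intron first {self.first} > last {self.last}")

    @property
    def length(self) -> int:
        return self.last - self.first + 1


def _check_segments(segs: list[GenomicInterval], what: str, tid: str) -> None:
    for a, b in zip(segs, segs[1:]):
        if b.start <= a.end:
            raise ValidationError(f"{what} of transcript {tid} overlap or are unsorted")
    if segs:
        seqs = {s.seq_id for s in segs}
        strands = {s.strand for s in segs}
        if len(seqs) > 1 or len(strands) > 1:
            raise ValidationError(
                f"{what} of transcript {tid} span multiple sequences/strands"
            )


@dataclass
class TranscriptModel:
    """One isoform: ordered exons, CDS segments and (derived) UTR intervals."""

    id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds_segments: list[GenomicInterval]
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda x: x.start)
        self.cds_segments = sorted(self.cds_segments, key=lambda x: x.start)
        if not self.exons:
            raise ValidationError(f"transcript {self.id} has no exons")
        _check_segments(self.exons, "exons", self.id)
        _check_segments(self.cds_segments, "CDS segments", self.id)
        for c in self.cds_segments:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValidationError(
                    f"CDS segment {c.start}-{c.end} of transcript {self.id} "
                    "is not contained in any exon"
                )
        all_segs = self.exons + self.cds_segments
        if {s.seq_id for s in all_segs} != {self.exons[0].seq_id} or {
            s.strand for s in all_segs
        } != {self.exons[0].strand}:
            raise ValidationError(
                f"transcript {self.id} mixes sequence ids or strands"
            )

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds_segments)

    @property
    def exon_length(self) -> int:
        return sum(e.length for e in self.exons)

    def cds_chain(self) -> tuple[tuple[int, int], ...]:
        """The ordered CDS coordinate list used for structural identity."""
        return tuple((c.start, c.end) for c in self.cds_segments)

    def derive_utrs(self) -> None:
        """Fill utr5/utr3 as exon-minus-CDS, oriented by strand.

        Used when the input annotation carries no explicit UTR features.
        """
        if not self.cds_segments:
            return
        cds_lo = self.cds_segments[0].start
        cds_hi = self.cds_segments[-1].end
        left: list[GenomicInterval] = []
        right: list[GenomicInterval] = []
        for e in self.exons:
            if e.start < cds_lo:
                left.append(
                    GenomicInterval(e.seq_id, e.start, min(e.end, cds_lo - 1), e.strand)
                )
            if e.end > cds_hi:
                right.append(
                    GenomicInterval(e.seq_id, max(e.start, cds_hi + 1), e.end, e.strand)
                )
        if self.strand == "+":
            self.utr5, self.utr3 = left, right
        else:
            self.utr5, self.utr3 = right, left


@dataclass
class GeneModel:
    """A gene locus with >= 1 transcript isoform on one strand."""

    id: str
    seq_id: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.id} has no transcripts")
        for t in self.transcripts:
            if t.seq_id != self.seq_id or t.strand != self.strand:
                raise ValidationError(
                    f"transcript {t.id} disagrees with gene {self.id} on "
                    "sequence id or strand"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
            self.strand,
        )

    @property
    def cds_union(self) -> list[tuple[int, int]]:
        """Merged per-base union of CDS segments across all isoforms."""
        pieces = [
            (c.start, c.end) for t in self.transcripts for c in t.cds_segments
        ]
        return merge_intervals(pieces)

    @property
    def cds_span(self) -> GenomicInterval | None:
        u = self.cds_union
        if not u:
            return None
        return GenomicInterval(self.seq_id, u[0][0], u[-1][1], self.strand)

    @property
    def multi_exon(self) -> bool:
        return any(len(t.exons) >= 2 for t in self.transcripts)

    @property
    def multi_isoform(self) -> bool:
        return len(self.transcripts) >= 2

    def representative_isoform(self) -> TranscriptModel:
        """Longest-CDS isoform (ties broken by transcript id)."""
        return max(self.transcripts, key=lambda t: (t.cds_length, t.id))


class AnnotationSet:
    """One annotation version, indexed for CDS-overlap interval queries."""

    def __init__(self, version_label: str, genes: list[GeneModel]):
        self.version_label = version_label
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.id in self.genes:
                raise ValidationError(f"duplicate gene id {g.id}")
            self.genes[g.id] = g
        self._index: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return (
            self.version_label == other.version_label and self.genes == other.genes
        )

    def _build_index(self) -> dict[str, IntervalTree]:
        if self._index is None:
            trees: dict[str, IntervalTree] = {}
            for g in self:
                tree = trees.setdefault(g.seq_id, IntervalTree())
                for s, e in g.cds_union:
                    tree.addi(s, e + 1, g)  # half-open for intervaltree
            self._index = trees
        return self._index

    def query(self, seq_id: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose CDS union overlaps [start, end] (1-based inclusive)."""
        tree = self._build_index().get(seq_id)
        if tree is None:
            return []
        hits = {iv.data.id: iv.data for iv in tree.overlap(start, end + 1)}
        return [hits[k] for k in sorted(hits)]

    def sorted_genes(self) -> list[GeneModel]:
        return sorted(self, key=lambda g: (g.seq_id, g.span.start, g.id))


# ---------------------------------------------------------------------------
# structural derivations


def merge_intervals(pieces: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge closed integer intervals that overlap or abut into a sorted union."""
    if not pieces:
        return []
    pieces = sorted(pieces)
    out = [list(pieces[0])]
    for s, e in pieces[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(p) for p in out]


def introns_of(t: TranscriptModel, basis: str = "exon") -> list[IntronKey]:
    """Ordered introns of a transcript from its exon or CDS chain.

    Keys are in ascending genomic order regardless of strand; each key spans
    ``segment_i.end + 1 .. segment_{i+1}.start - 1``.
    """
    if basis == "exon":
        segs = t.exons
    elif basis == "cds":
        segs = t.cds_segments
    else:
        raise ValueError(f"basis must be 'exon' or 'cds', got {basis!r}")
    keys = []
    for a, b in zip(segs, segs[1:]):
        if b.start - a.end < 2:
            raise ValidationError(
                f"abutting segments in transcript {t.id} leave no intron"
            )
        keys.append(IntronKey(t.seq_id, t.strand, a.end + 1, b.start - 1))
    return keys


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranslationResult:
    transcript_id: str
    protein: str  # trailing stop not included
    has_start: bool
    has_stop: bool
    incomplete_codon: bool  # CDS length not divisible by 3

    @property
    def n_aa(self) -> int:
        return len(self.protein)


def _fetch(genome, seq_id: str, start: int, end: int) -> str:
    """1-based inclusive slice from a pyfaidx.Fasta or a plain mapping."""
    rec = genome[seq_id]
    piece = rec[start - 1 : end]
    return str(piece).upper()


def cds_sequence(t: TranscriptModel, genome) -> str:
    """Spliced CDS sequence in translation (5'->3') order."""
    if not t.cds_segments:
        return ""
    parts = [_fetch(genome, c.seq_id, c.start, c.end) for c in t.cds_segments]
    seq = "".join(parts)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


def translate_cds(t: TranscriptModel, genome) -> TranslationResult:
    """Translate a transcript's CDS with the standard genetic code.

    The trailing stop is stripped from the reported protein; a CDS whose
    length is not a multiple of 3 is flagged and translated to the floor.
    """
    seq = cds_sequence(t, genome)
    if not seq:
        raise ValidationError(f"transcript {t.id} has no CDS to translate")
    incomplete = len(seq) % 3 != 0
    usable = seq[: len(seq) - len(seq) % 3]
    prot = str(Seq(usable).translate())
    has_start = usable[:3] == "ATG"
    has_stop = usable[-3:] in STOP_CODONS
    if prot.endswith("*"):
        prot = prot[:-1]
    return TranslationResult(t.id, prot, has_start, has_stop, incomplete)


def gc_content(seqs) -> float | None:
    """GC fraction over A/C/G/T bases; N is excluded from the denominator.

    Accepts one sequence string or an iterable of them; an empty or all-N
    input yields ``None`` (undefined).
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    gc = at = 0
    for s in seqs:
        s = s.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    total = gc + at
    if total == 0:
        return None
    return gc / total


# ---------------------------------------------------------------------------
# GFF3 I/O

_VERSION_DIRECTIVE = "##annotation-version"


def _prevalidate_gff3(path: str) -> str | None:
    """Cheap syntactic pass so parse errors can name a line number.

    Returns the version label from the ``##annotation-version`` directive
    when present.
    """
    label = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith(_VERSION_DIRECTIVE):
                    label = line[len(_VERSION_DIRECTIVE) :].strip()
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise Gff3ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"found {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise Gff3ParseError(
                    f"{path}: line {lineno}: non-integer start/end"
                ) from None
            if start < 1 or end < start:
                raise Gff3ParseError(
                    f"{path}: line {lineno}: bad coordinates {start}-{end}"
                )
    return label


def _feature_interval(f) -> GenomicInterval:
    return GenomicInterval(f.seqid, f.start, f.end, f.strand)


def parse_gff3(path: str, version_label: str | None = None) -> AnnotationSet:
    """Read a gene/mRNA/exon/CDS GFF3 file into an :class:`AnnotationSet`.

    UTR features are honoured when present and otherwise derived as
    exon-minus-CDS.  Hierarchy is linked through ID/Parent attributes.
    """
    directive_label = _prevalidate_gff3(path)
    if version_label is None:
        version_label = directive_label or os.path.splitext(
            os.path.basename(path)
        )[0]
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            sort_attribute_values=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return AnnotationSet(version_label, [])
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        transcripts: list[TranscriptModel] = []
        for tf in db.children(gf, featuretype=("mRNA", "transcript"), level=1):
            exons = [
                _feature_interval(f)
                for f in db.children(tf, featuretype="exon", level=1)
            ]
            cds = [
                _feature_interval(f)
                for f in db.children(tf, featuretype="CDS", level=1)
            ]
            utr5 = [
                _feature_interval(f)
                for f in db.children(tf, featuretype="five_prime_UTR", level=1)
            ]
            utr3 = [
                _feature_interval(f)
                for f in db.children(tf, featuretype="three_prime_UTR", level=1)
            ]
            t = TranscriptModel(
                tf.id, gf.id, exons, cds, sorted(utr5), sorted(utr3)
            )
            if not utr5 and not utr3:
                t.derive_utrs()
            transcripts.append(t)
        if not transcripts:
            raise ValidationError(f"gene {gf.id} has no mRNA children")
        genes.append(GeneModel(gf.id, gf.seqid, gf.strand, transcripts))
    return AnnotationSet(version_label, genes)


def _phases(t: TranscriptModel) -> list[int]:
    """GFF3 phase column for the CDS segments, in genomic order."""
    segs = t.cds_segments if t.strand == "+" else t.cds_segments[::-1]
    phases, cum = [], 0
    for c in segs:
        phases.append((3 - cum % 3) % 3)
        cum += c.length
    return phases if t.strand == "+" else phases[::-1]


def write_gff3(annot: AnnotationSet, path: str) -> None:
    """Write an annotation set as canonical, re-parseable GFF3.

    Features are ordered by (seq_id, start, gene id); IDs are preserved
    verbatim so that parse -> write -> parse is an identity.
    """

    def line(seq, ftype, start, end, strand, attrs, phase="."):
        return (
            f"{seq}\tannodiff\t{ftype}\t{start}\t{end}\t.\t{strand}\t{phase}"
            f"\t{attrs}\n"
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"{_VERSION_DIRECTIVE} {annot.version_label}\n")
        for g in annot.sorted_genes():
            sp = g.span
            fh.write(line(g.seq_id, "gene", sp.start, sp.end, g.strand, f"ID={g.id}"))
            for t in sorted(g.transcripts, key=lambda t: t.id):
                ts = t.span
                fh.write(
                    line(
                        g.seq_id, "mRNA", ts.start, ts.end, g.strand,
                        f"ID={t.id};Parent={g.id}",
                    )
                )
                for i, e in enumerate(t.exons, 1):
                    fh.write(
                        line(
                            e.seq_id, "exon", e.start, e.end, e.strand,
                            f"ID={t.id}.exon{i};Parent={t.id}",
                        )
                    )
                for c, ph in zip(t.cds_segments, _phases(t)):
                    fh.write(
                        line(
                            c.seq_id, "CDS", c.start, c.end, c.strand,
                            f"ID={t.id}.cds;Parent={t.id}", phase=str(ph),
                        )
                    )
                for u in t.utr5:
                    fh.write(
                        line(
                            u.seq_id, "five_prime_UTR", u.start, u.end, u.strand,
                            f"ID={t.id}.utr5.{u.start};Parent={t.id}",
                        )
                    )
                for u in t.utr3:
                    fh.write(
                        line(
                            u.seq_id, "three_prime_UTR", u.start, u.end, u.strand,
                            f"ID={t.id}.utr3.{u.start};Parent={t.id}",
                        )
                    )
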