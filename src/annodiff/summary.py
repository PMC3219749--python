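"""Annotation-wide summary statistics, ORF detection and gene-model filters.

`summarize` produces the usual genome-annotation report panel (gene /
transcript / exon / intron / UTR counts, lengths and GC, percent coding),
`find_complete_orfs` runs a six-frame complete-ORF scan over transcript
sequences, and the two filters implement the conventional quality gates for
predicted gene sets: a minimum protein length with required start and stop
codons, and a minimum reconstructed-transcript length.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

from . import model
from .model import (
    AnnotationSet,
    TranscriptModel,
    ValidationError,
    gc_content,
    introns_of,
    merge_intervals,
    reverse_complement,
)

__all__ = [
    "AnnotationSummary",
    "OrfRecord",
    "summarize",
    "derive_ratios",
    "find_complete_orfs",
    "filter_gene_models",
    "filter_short_transcripts",
    "round_report",
    "percent",
]


def round_report(x: float | None, decimals: int = 1, mode: str = "half-up"):
    """Round a reported number; ``mode`` is ``half-up`` or ``truncate``.

    Published annotation tables are not always consistent about rounding
    versus truncation, so the mode is explicit.
    """
    if x is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    rounding = ROUND_HALF_UP if mode == "half-up" else ROUND_DOWN
    val = float(Decimal(repr(float(x))).quantize(q, rounding=rounding))
    return int(val) if decimals == 0 else val


def percent(num: float, den: float, decimals: int = 1, mode: str = "half-up"):
    """num/den as a percentage, rounded for reporting; None when den == 0."""
    if den == 0:
        return None
    return round_report(100.0 * num / den, decimals, mode)


@dataclass
class AnnotationSummary:
    """The raw (unrounded) summary panel for one annotation version."""

    version_label: str
    genome_size: int
    gc_genome: float | None
    n_genes: int
    n_genes_plus: int
    n_genes_minus: int
    mean_gene_length: float | None
    gene_density: float | None  # Kb per gene
    n_transcripts: int
    pct_transcripts_with_introns: float | None
    mean_transcript_length: float | None
    mean_cds_length: float | None
    pct_coding: float | None
    n_exons: int
    mean_exons_per_transcript: float | None
    gc_exons: float | None
    mean_exon_length: float | None
    total_exon_length: int
    n_introns: int
    mean_introns_per_transcript: float | None
    gc_introns: float | None
    mean_intron_length: float | None
    total_intron_length: int
    n_genes_with_utr: int
    mean_utr_length: float | None
    n_utr5: int
    mean_utr5_length: float | None
    n_utr3: int
    mean_utr3_length: float | None

    def as_rows(self, mode: str = "half-up") -> list[tuple[str, object]]:
        """Two-column report rows with conventional precision."""
        rows = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith("pct_") or f.name.startswith("gc_"):
                v = round_report(None if v is None else 100 * v, 2, mode)
            elif f.name == "gene_density":
                v = round_report(v, 1, mode)
            elif f.name in ("mean_exons_per_transcript", "mean_introns_per_transcript"):
                v = round_report(v, 2, mode)
            elif f.name.startswith("mean_"):
                v = round_report(v, 0, mode)
            rows.append((f.name, v))
        return rows


def _mean(total: float, n: int) -> float | None:
    return total / n if n else None


def summarize(annot: AnnotationSet, genome) -> AnnotationSummary:
    """Compute the full summary panel of an annotation against its genome.

    ``genome`` is a ``pyfaidx.Fasta`` (or mapping of id -> sequence).
    Percent coding uses the per-base union of CDS over all genes, so
    overlapping isoforms are never double-counted.
    """
    genome_ids = set(genome.keys())
    missing = sorted({g.seq_id for g in annot} - genome_ids)
    if missing:
        raise ValidationError(
            "sequence ids missing from genome: " + ", ".join(missing)
        )

    seqs = {sid: str(genome[sid][:]) for sid in genome_ids}
    genome_size = sum(len(s) for s in seqs.values())
    gc_genome = gc_content(seqs.values())

    n_genes = len(annot)
    n_plus = sum(1 for g in annot if g.strand == "+")
    gene_len_total = sum(g.span.length for g in annot)

    n_transcripts = 0
    n_with_introns = 0
    transcript_len_total = 0
    cds_len_total = 0
    n_exons = 0
    exon_len_total = 0
    n_introns = 0
    intron_len_total = 0
    exon_seqs: list[str] = []
    intron_seqs: list[str] = []
    utr_lens: list[int] = []
    utr5_lens: list[int] = []
    utr3_lens: list[int] = []
    n_genes_with_utr = 0
    cds_pieces: dict[str, list[tuple[int, int]]] = {}

    for g in annot:
        if any(t.utr5 or t.utr3 for t in g.transcripts):
            n_genes_with_utr += 1
        for t in g.transcripts:
            n_transcripts += 1
            transcript_len_total += t.span.length
            cds_len_total += t.cds_length
            n_exons += len(t.exons)
            exon_len_total += t.exon_length
            if len(t.exons) >= 2:
                n_with_introns += 1
            for e in t.exons:
                exon_seqs.append(seqs[e.seq_id][e.start - 1 : e.end])
            for k in introns_of(t, basis="exon"):
                n_introns += 1
                intron_len_total += k.length
                intron_seqs.append(seqs[k.seq_id][k.first - 1 : k.last])
            for c in t.cds_segments:
                cds_pieces.setdefault(c.seq_id, []).append((c.start, c.end))
            for u in t.utr5:
                utr5_lens.append(u.length)
                utr_lens.append(u.length)
            for u in t.utr3:
                utr3_lens.append(u.length)
                utr_lens.append(u.length)

    coding_bases = sum(
        e - s + 1 for pieces in cds_pieces.values() for s, e in merge_intervals(pieces)
    )

    return AnnotationSummary(
        version_label=annot.version_label,
        genome_size=genome_size,
        gc_genome=gc_genome,
        n_genes=n_genes,
        n_genes_plus=n_plus,
        n_genes_minus=n_genes - n_plus,
        mean_gene_length=_mean(gene_len_total, n_genes),
        gene_density=(genome_size / n_genes / 1000.0) if n_genes else None,
        n_transcripts=n_transcripts,
        pct_transcripts_with_introns=_mean(n_with_introns, n_transcripts),
        mean_transcript_length=_mean(transcript_len_total, n_transcripts),
        mean_cds_length=_mean(cds_len_total, n_transcripts),
        pct_coding=(coding_bases / genome_size) if genome_size else None,
        n_exons=n_exons,
        mean_exons_per_transcript=_mean(n_exons, n_transcripts),
        gc_exons=gc_content(exon_seqs) if exon_seqs else None,
        mean_exon_length=_mean(exon_len_total, n_exons),
        total_exon_length=exon_len_total,
        n_introns=n_introns,
        mean_introns_per_transcript=_mean(n_introns, n_transcripts),
        gc_introns=gc_content(intron_seqs) if intron_seqs else None,
        mean_intron_length=_mean(intron_len_total, n_introns),
        total_intron_length=intron_len_total,
        n_genes_with_utr=n_genes_with_utr,
        mean_utr_length=_mean(sum(utr_lens), len(utr_lens)),
        n_utr5=len(utr5_lens),
        mean_utr5_length=_mean(sum(utr5_lens), len(utr5_lens)),
        n_utr3=len(utr3_lens),
        mean_utr3_length=_mean(sum(utr3_lens), len(utr3_lens)),
    )


def derive_ratios(totals: dict) -> dict:
    """Ratios implied by a summary panel's raw totals.

    Expects any of ``genome_size, n_genes, n_transcripts, n_exons`` and
    returns ``gene_density`` (Kb/gene), ``mean_exons_per_transcript``,
    ``implied_introns`` (= n_exons - n_transcripts, the intron count forced
    by the exon and transcript counts) and ``mean_introns_per_transcript``.
    Zero denominators yield ``None``.
    """
    out: dict[str, float | int | None] = {}
    n_genes = totals.get("n_genes", 0)
    n_tr = totals.get("n_transcripts", 0)
    n_ex = totals.get("n_exons")
    genome_size = totals.get("genome_size")
    out["gene_density"] = (
        genome_size / n_genes / 1000.0 if genome_size and n_genes else None
    )
    if n_ex is not None:
        out["implied_introns"] = n_ex - n_tr
        out["mean_exons_per_transcript"] = n_ex / n_tr if n_tr else None
        out["mean_introns_per_transcript"] = (
            (n_ex - n_tr) / n_tr if n_tr else None
        )
    return out


# ---------------------------------------------------------------------------
# six-frame complete-ORF scan


@dataclass(frozen=True)
class OrfRecord:
    """One complete open reading frame (ATG .. in-frame stop, inclusive)."""

    transcript_id: str
    strand: str
    frame: int  # 0..2 offset within the scanned strand
    start: int  # 1-based, in the coordinates of the input (forward) sequence
    end: int
    has_start: bool
    has_stop: bool

    @property
    def complete(self) -> bool:
        return self.has_start and self.has_stop

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _scan_frames(seq: str):
    """Yield (frame, atg_offset, stop_end_offset) for complete ORFs, 0-based."""
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in model.STOP_CODONS:
                if start is not None:
                    yield frame, start, i + 3
                    start = None
            elif codon == "ATG" and start is None:
                start = i
        # an ATG with no downstream in-frame stop is not a complete ORF


def find_complete_orfs(
    seqs: dict[str, str], min_nt: int = 30
) -> tuple[list[OrfRecord], dict[str, bool]]:
    """Six-frame scan for complete ORFs in transcript sequences.

    For each transcript the longest complete ORF per frame is collected and
    the per-transcript flag says whether any complete ORF of at least
    ``min_nt`` nucleotides (stop codon included) exists.  ORFs run from an
    ATG to the first in-frame stop; nested ATGs inside an open ORF are not
    reported separately.
    """
    records: list[OrfRecord] = []
    complete: dict[str, bool] = {}
    for tid, seq in seqs.items():
        seq = seq.upper()
        n = len(seq)
        found: list[OrfRecord] = []
        for frame, s, e in _scan_frames(seq):
            found.append(OrfRecord(tid, "+", frame, s + 1, e, True, True))
        rc = reverse_complement(seq)
        for frame, s, e in _scan_frames(rc):
            # map back to forward coordinates
            found.append(OrfRecord(tid, "-", frame, n - e + 1, n - s, True, True))
        records.extend(found)
        complete[tid] = any(o.length >= min_nt for o in found)
    return records, complete


def longest_complete_orf(records: list[OrfRecord]) -> dict[str, OrfRecord]:
    """The longest complete ORF per transcript (ties: smallest start, + first)."""
    best: dict[str, OrfRecord] = {}
    for r in sorted(records, key=lambda r: (-r.length, r.start, r.strand)):
        best.setdefault(r.transcript_id, r)
    return best


# ---------------------------------------------------------------------------
# gene-set quality filters


@dataclass
class RemovalRecord:
    gene_id: str
    reason: str


def filter_gene_models(
    annot: AnnotationSet, genome, min_aa: int = 50
) -> tuple[AnnotationSet, list[RemovalRecord]]:
    """Drop genes whose every isoform encodes a short or incomplete protein.

    A gene survives when at least one isoform translates to >= ``min_aa``
    amino acids with both a start (ATG) and an in-frame terminal stop codon.
    """
    kept: list = []
    removed: list[RemovalRecord] = []
    for g in annot.sorted_genes():
        reasons = []
        ok = False
        for t in g.transcripts:
            tr = model.translate_cds(t, genome)
            if tr.n_aa < min_aa:
                reasons.append(f"{t.id}: protein {tr.n_aa} aa < {min_aa}")
            elif not tr.has_start:
                reasons.append(f"{t.id}: no start codon")
            elif not tr.has_stop:
                reasons.append(f"{t.id}: no stop codon")
            else:
                ok = True
        if ok:
            kept.append(g)
        else:
            removed.append(RemovalRecord(g.id, "; ".join(reasons)))
    return AnnotationSet(annot.version_label, kept), removed


def filter_short_transcripts(
    seqs: dict[str, str], min_len: int = 150
) -> tuple[dict[str, str], list[str]]:
    """Drop reconstructed transcripts shorter than ``min_len`` nt.

    Returns the surviving sequences and the ids of removed ones.
    """
    kept = {tid: s for tid, s in seqs.items() if len(s) >= min_len}
    removed = [tid for tid in seqs if tid not in kept]
    return kept, removed
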