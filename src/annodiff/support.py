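"""Intron-level evidence support for multi-exon genes.

Evidence (spliced transcript alignments, protein alignments, ab initio
predictions) arrives as multi-segment features; every gap between
consecutive segments of a chain is an intron key, and a gene's intron is
*supported* by an evidence class when its exact key occurs in the union of
that class's tracks.  A gene is *full-length supported* by a class when
every intron of its representative isoform is supported.  Region counts
over the classes give the usual support Venn diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    Gff3ParseError,
    IntronKey,
    introns_of,
)

__all__ = [
    "EvidenceTrack",
    "SupportProfile",
    "EVIDENCE_CLASSES",
    "build_track",
    "track_from_chains",
    "profile_gene",
    "profile_annotation",
    "venn",
]

EVIDENCE_CLASSES = ("transcript", "protein", "denovo")


@dataclass
class EvidenceTrack:
    """A named, class-labelled set of evidence intron keys."""

    name: str
    cls: str
    intron_keys: frozenset[IntronKey]

    def __post_init__(self) -> None:
        if self.cls not in EVIDENCE_CLASSES:
            raise ValueError(
                f"unknown evidence class {self.cls!r}; "
                f"expected one of {EVIDENCE_CLASSES}"
            )


def _chain_introns(segments: list[GenomicInterval]) -> list[IntronKey]:
    segments = sorted(segments, key=lambda s: s.start)
    keys = []
    for a, b in zip(segments, segments[1:]):
        if b.start - a.end >= 2:
            keys.append(IntronKey(a.seq_id, a.strand, a.end + 1, b.start - 1))
    return keys


def track_from_chains(
    chains: list[list[GenomicInterval]], name: str, cls: str
) -> EvidenceTrack:
    """Build a track from already-grouped multi-segment chains."""
    keys: set[IntronKey] = set()
    for segments in chains:
        keys.update(_chain_introns(segments))
    return EvidenceTrack(name, cls, frozenset(keys))


def _parse_gff3_chains(path: str) -> list[list[GenomicInterval]]:
    """Group GFF3 segment features into chains by Parent (else by ID)."""
    chains: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise Gff3ParseError(
                    f"{path}: line {lineno}: expected 9 columns"
                )
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            key = attrs.get("Parent") or attrs.get("ID")
            if key is None:
                continue  # ungrouped feature cannot form a chain
            if attrs.get("Parent") is None and cols[2] in ("match", "mRNA", "gene"):
                continue  # container line; its parts carry the segments
            strand = cols[6] if cols[6] in ("+", "-") else "+"
            chains.setdefault(key, []).append(
                GenomicInterval(cols[0], int(cols[3]), int(cols[4]), strand)
            )
    return list(chains.values())


def _parse_bed12_chains(path: str) -> list[list[GenomicInterval]]:
    """Expand BED12 blocks into per-feature segment chains."""
    chains = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 BED columns")
            chrom, chrom_start = cols[0], int(cols[1])
            strand = cols[5] if cols[5] in ("+", "-") else "+"
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}: line {lineno}: inconsistent blocks")
            chains.append(
                [
                    GenomicInterval(
                        chrom,
                        chrom_start + off + 1,  # BED is 0-based half-open
                        chrom_start + off + size,
                        strand,
                    )
                    for off, size in zip(starts, sizes)
                ]
            )
    return chains


def build_track(path: str, name: str, cls: str) -> EvidenceTrack:
    """Read a GFF3 (or BED12) evidence file into an :class:`EvidenceTrack`.

    Single-segment features contribute no introns; shared introns across
    features are counted once (set semantics).
    """
    if cls not in EVIDENCE_CLASSES:
        raise ValueError(
            f"unknown evidence class {cls!r}; expected one of {EVIDENCE_CLASSES}"
        )
    if path.endswith((".bed", ".bed12")):
        chains = _parse_bed12_chains(path)
    else:
        chains = _parse_gff3_chains(path)
    return track_from_chains(chains, name, cls)


@dataclass
class SupportProfile:
    """Per-gene evidence support of the representative isoform's introns."""

    gene_id: str
    n_introns: int
    by_class: dict[str, dict] = field(default_factory=dict)
    by_track: dict[str, int] = field(default_factory=dict)

    def supported(self, cls: str) -> bool:
        return self.by_class.get(cls, {}).get("supported", False)

    def full_length(self, cls: str) -> bool:
        return self.by_class.get(cls, {}).get("full_length", False)

    def support_set(self, mode: str, classes) -> frozenset[str]:
        test = self.full_length if mode == "full_length" else self.supported
        return frozenset(c for c in classes if test(c))


def profile_gene(g: GeneModel, tracks: list[EvidenceTrack]) -> SupportProfile:
    """Support profile of one multi-exon gene against evidence tracks.

    Introns come from the exon chain (CDS plus UTR) of the representative
    isoform, defined as the longest-CDS isoform.  Single-exon genes have no
    introns to support and are rejected.
    """
    rep = g.representative_isoform()
    introns = set(introns_of(rep, basis="exon"))
    if not introns:
        raise ValueError(
            f"gene {g.id} is single-exon; intron support is undefined"
        )
    prof = SupportProfile(g.id, len(introns))
    class_keys: dict[str, set[IntronKey]] = {c: set() for c in EVIDENCE_CLASSES}
    for tr in tracks:
        class_keys[tr.cls].update(tr.intron_keys)
        prof.by_track[tr.name] = len(introns & tr.intron_keys)
    for cls, keys in class_keys.items():
        n = len(introns & keys)
        prof.by_class[cls] = {
            "n_supported": n,
            "supported": n >= 1,
            "full_length": n == len(introns),
        }
    return prof


def profile_annotation(
    annot: AnnotationSet, tracks: list[EvidenceTrack]
) -> tuple[list[SupportProfile], list[str]]:
    """Profiles for every multi-exon gene; single-exon gene ids are
    returned separately as skipped."""
    profiles, skipped = [], []
    for g in annot.sorted_genes():
        if len(g.representative_isoform().exons) < 2:
            skipped.append(g.id)
        else:
            profiles.append(profile_gene(g, tracks))
    return profiles, skipped


def venn(
    profiles: list[SupportProfile],
    mode: str = "supported",
    classes=EVIDENCE_CLASSES,
) -> dict[str, int]:
    """Disjoint region counts of the n-set support Venn diagram.

    Region keys join class names with ``&`` (e.g. ``transcript&protein`` is
    the set supported by exactly those two classes); genes supported by no
    class are counted under ``none``.
    """
    if mode not in ("supported", "full_length"):
        raise ValueError(f"mode must be 'supported' or 'full_length', got {mode!r}")
    classes = tuple(classes)
    for p in profiles:
        missing = [c for c in classes if c not in p.by_class]
        if missing:
            raise ValueError(
                f"profile {p.gene_id} lacks classes {missing}; "
                "profiles must be computed against the requested classes"
            )
    regions: dict[str, int] = {}
    for r in range(1, len(classes) + 1):
        for combo in combinations(classes, r):
            regions["&".join(combo)] = 0
    regions["none"] = 0
    for p in profiles:
        s = p.support_set(mode, classes)
        key = "&".join(c for c in classes if c in s) if s else "none"
        regions[key] += 1
    return regions
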