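"""Locus-level structural comparison of two annotation versions.

Genes from both versions are clustered into shared loci: two genes occupy
the same locus when the per-base unions of their CDS segments share at
least one base pair (on the same strand by default), and loci are the
connected components of that overlap graph, taken across and within
versions.  Each locus is then classified from its member counts:

=============  ==========================================================
{1 v1, 0 v2}   specific_v1 (gene only in the older version)
{0 v1, 1 v2}   specific_v2
{1, 1}         identical when some isoform pair has the same CDS chain,
               otherwise modified_1to1
{m>=2, 1}      merged   (m older genes merged into one newer gene)
{1, n>=2}      split    (one older gene split into n newer genes)
{m>=2, n>=2}   complex  (reported separately, never forced into a class)
=============  ==========================================================
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import AnnotationSet, GeneModel

__all__ = [
    "LocusCluster",
    "ComparisonEvent",
    "ComparisonReport",
    "cluster_loci",
    "structures_equal",
    "classify",
    "exclude_multi_isoform",
    "EVENT_KINDS",
]

EVENT_KINDS = (
    "identical",
    "modified_1to1",
    "merged",
    "split",
    "specific_v1",
    "specific_v2",
    "complex",
)


@dataclass
class LocusCluster:
    cluster_id: str
    seq_id: str
    span: tuple[int, int]
    members_v1: list[str]
    members_v2: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.members_v1), len(self.members_v2))


@dataclass
class ComparisonEvent:
    cluster_id: str
    kind: str
    v1_gene_ids: list[str]
    v2_gene_ids: list[str]


@dataclass
class ComparisonReport:
    """Per-category tallies of loci and of genes in each version."""

    n_clusters: int = 0
    n_shared_loci: int = 0  # clusters with members from both versions
    events_by_kind: Counter = field(default_factory=Counter)
    v1_genes_by_kind: Counter = field(default_factory=Counter)
    v2_genes_by_kind: Counter = field(default_factory=Counter)


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        p = self.parent.setdefault(x, x)
        while p != x:
            self.parent[x] = p = self.parent[p]
            x, p = p, self.parent[p]
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_loci(
    a: AnnotationSet, b: AnnotationSet, stranded: bool = True
) -> list[LocusCluster]:
    """Connected components of CDS overlap between (and within) two versions.

    A single sorted sweep over the merged CDS pieces per (seq, strand)
    group finds every >= 1 bp overlap; genes contributing multiple pieces
    tie their components together, so the result equals the components of
    the full pairwise overlap graph.
    """
    pieces = []  # (group_key, start, end, node)
    spans: dict[tuple, list[tuple[int, int]]] = {}
    for version, annot in (("v1", a), ("v2", b)):
        for g in annot:
            node = (version, g.id)
            for s, e in g.cds_union:
                key = (g.seq_id, g.strand if stranded else ".")
                pieces.append((key, s, e, node))
                spans.setdefault(node, []).append((s, e))

    uf = _UnionFind()
    pieces.sort(key=lambda p: (p[0], p[1], p[2]))
    cur_key = None
    cur_end = -1
    anchor = None
    for key, s, e, node in pieces:
        uf.find(node)  # register singletons
        if key == cur_key and s <= cur_end:
            uf.union(anchor, node)
            cur_end = max(cur_end, e)
        else:
            cur_key, cur_end, anchor = key, e, node

    comps: dict = {}
    for key, s, e, node in pieces:
        comps.setdefault(uf.find(node), set()).add(node)
    # genes without any CDS still occupy (singleton) loci
    for version, annot in (("v1", a), ("v2", b)):
        for g in annot:
            node = (version, g.id)
            if node not in spans:
                spans[node] = [(g.span.start, g.span.end)]
                comps.setdefault(node, set()).add(node)

    clusters = []
    for members in comps.values():
        v1 = sorted(gid for ver, gid in members if ver == "v1")
        v2 = sorted(gid for ver, gid in members if ver == "v2")
        all_pieces = [p for m in members for p in spans[m]]
        seq_id = (a if next(iter(members))[0] == "v1" else b).genes[
            next(iter(members))[1]
        ].seq_id
        clusters.append(
            (
                seq_id,
                min(s for s, _ in all_pieces),
                max(e for _, e in all_pieces),
                v1,
                v2,
            )
        )
    clusters.sort(key=lambda c: (c[0], c[1], c[3], c[4]))
    return [
        LocusCluster(f"locus{i:06d}", seq, (lo, hi), v1, v2)
        for i, (seq, lo, hi, v1, v2) in enumerate(clusters, start=1)
    ]


def structures_equal(g1: GeneModel, g2: GeneModel) -> bool:
    """Do the two genes share at least one isoform with the same CDS chain?

    Only coding coordinates matter: UTRs are ignored, and a gene pair is
    "the same structure" as soon as any isoform of one exactly matches any
    isoform of the other (a pair differs only when *all* isoform
    combinations differ).
    """
    if g1.seq_id != g2.seq_id or g1.strand != g2.strand:
        return False
    chains1 = {t.cds_chain() for t in g1.transcripts if t.cds_segments}
    chains2 = {t.cds_chain() for t in g2.transcripts if t.cds_segments}
    return bool(chains1 & chains2)


def classify(
    clusters: list[LocusCluster], a: AnnotationSet, b: AnnotationSet
) -> tuple[list[ComparisonEvent], ComparisonReport]:
    """Assign every locus cluster to one comparison category."""
    events: list[ComparisonEvent] = []
    report = ComparisonReport(n_clusters=len(clusters))
    for c in clusters:
        m, n = c.shape
        if m >= 1 and n >= 1:
            report.n_shared_loci += 1
        if (m, n) == (1, 0):
            kind = "specific_v1"
        elif (m, n) == (0, 1):
            kind = "specific_v2"
        elif (m, n) == (1, 1):
            g1 = a.genes[c.members_v1[0]]
            g2 = b.genes[c.members_v2[0]]
            kind = "identical" if structures_equal(g1, g2) else "modified_1to1"
        elif m >= 2 and n == 1:
            kind = "merged"
        elif m == 1 and n >= 2:
            kind = "split"
        else:
            kind = "complex"
        events.append(
            ComparisonEvent(c.cluster_id, kind, c.members_v1, c.members_v2)
        )
        report.events_by_kind[kind] += 1
        report.v1_genes_by_kind[kind] += m
        report.v2_genes_by_kind[kind] += n
    return events, report


def exclude_multi_isoform(
    events: list[ComparisonEvent], a: AnnotationSet, b: AnnotationSet
) -> tuple[list[ComparisonEvent], list[tuple[str, list[str]]]]:
    """Drop events touching any gene with >= 2 isoforms.

    Alternative splicing makes merge/split and pairwise adjudication
    ambiguous, so such loci are set aside before downstream analyses.
    Returns the kept events and ``(cluster_id, offending gene ids)`` for
    each exclusion.
    """
    kept: list[ComparisonEvent] = []
    excluded: list[tuple[str, list[str]]] = []
    for ev in events:
        offenders = [
            gid for gid in ev.v1_gene_ids if a.genes[gid].multi_isoform
        ] + [gid for gid in ev.v2_gene_ids if b.genes[gid].multi_isoform]
        if offenders:
            excluded.append((ev.cluster_id, offenders))
        else:
            kept.append(ev)
    return kept, excluded
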