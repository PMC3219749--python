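"""Homology-based adjudication of annotation differences.

Two analyses consume externally produced homology tables:

* merge/split events — each locus groups one *merged* gene (the single gene
  on its side of the event) with the *split* counterparts in the other
  version.  Best-hit consistency against a protein database decides which
  structure is better: a group with no database hit at all is a false
  positive; split genes sharing the merged gene's best hit argue for the
  merged structure; split genes with two or more distinct best hits argue
  for the split structure; a lone split-side hit is inconclusive.

* modified 1-to-1 pairs — when both genes of a pair have the same best hit,
  each protein is globally aligned to the hit's sequence and the pair is
  compared per metric (identity, similarity, score, gaps; fewer gaps is
  better).  Pfam-style domain tables are tallied per version alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import AlignmentStats, global_align
from .compare import ComparisonEvent

__all__ = [
    "Hit",
    "HitTable",
    "load_hits",
    "load_domains",
    "AdjudicationVerdict",
    "adjudicate_merge_split",
    "PairVerdict",
    "compare_pair",
    "domain_summary",
    "composite_winner",
    "BLAST_COLUMNS",
]

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class Hit:
    subject: str
    evalue: float
    bitscore: float
    qstart: int
    qend: int
    sstart: int
    send: int


class HitTable:
    """Ranked homology hits per query (ascending E-value, then bitscore)."""

    def __init__(self, hits: dict[str, list[Hit]]):
        self._hits = {
            q: sorted(hs, key=lambda h: (h.evalue, -h.bitscore))
            for q, hs in hits.items()
            if hs
        }

    def hits(self, query: str) -> list[Hit]:
        return self._hits.get(query, [])

    def best_hit(self, query: str) -> Hit | None:
        hs = self._hits.get(query)
        return hs[0] if hs else None

    def queries(self) -> list[str]:
        return sorted(self._hits)

    def __len__(self) -> int:
        return len(self._hits)


def load_hits(path: str, evalue_cutoff: float = 1e-5) -> HitTable:
    """Read a 12-column tab-separated homology table (BLAST outfmt 6).

    Rows whose E-value exceeds ``evalue_cutoff`` are dropped.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", names=BLAST_COLUMNS, header=None, comment="#",
            dtype={"qseqid": str, "sseqid": str},
        )
    except pd.errors.EmptyDataError:
        return HitTable({})
    if df.shape[1] != len(BLAST_COLUMNS):
        raise ValueError(f"{path}: expected 12 tab-separated columns")
    for col in ("evalue", "bitscore", "qstart", "qend", "sstart", "send"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: row {row}: malformed value in {col!r}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 1
            raise ValueError(f"{path}: row {row}: missing value in {col!r}")
        df[col] = coerced
    df = df[df["evalue"] <= evalue_cutoff]
    hits: dict[str, list[Hit]] = {}
    for r in df.itertuples(index=False):
        hits.setdefault(r.qseqid, []).append(
            Hit(
                r.sseqid, float(r.evalue), float(r.bitscore),
                int(r.qstart), int(r.qend), int(r.sstart), int(r.send),
            )
        )
    return HitTable(hits)


def load_domains(path: str) -> pd.DataFrame:
    """Read a two-column (gene_id, domain_accession) tab-separated table."""
    try:
        df = pd.read_csv(
            path, sep="\t", names=["gene_id", "domain_accession"],
            header=None, comment="#", dtype=str,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["gene_id", "domain_accession"])
    return df


# ---------------------------------------------------------------------------
# merge/split adjudication


@dataclass
class AdjudicationVerdict:
    event_id: str
    verdict: str  # optimal_v1 | optimal_v2 | false_positive | ambiguous
    rationale: str


def adjudicate_merge_split(
    event: ComparisonEvent, hits: HitTable, min_shared: int = 2
) -> AdjudicationVerdict:
    """Decide a merge/split locus by best-hit consistency.

    Rule order: (1) no hit anywhere in the group -> false_positive;
    (2) at least ``min_shared`` split-side genes share the merged gene's
    best hit -> the merged structure wins; (3) split-side genes carry >= 2
    distinct best hits -> the split structure wins; (4) a single split-side
    hit, or anything else, is ambiguous.
    """
    if event.kind == "merged":
        merged_id, split_ids = event.v2_gene_ids[0], event.v1_gene_ids
        merged_version = "v2"
    elif event.kind == "split":
        merged_id, split_ids = event.v1_gene_ids[0], event.v2_gene_ids
        merged_version = "v1"
    else:
        raise ValueError(
            f"event {event.cluster_id} has kind {event.kind!r}; "
            "adjudication applies to merged/split events only"
        )
    split_version = "v1" if merged_version == "v2" else "v2"

    merged_best = hits.best_hit(merged_id)
    split_best = {gid: hits.best_hit(gid) for gid in split_ids}
    any_hit = merged_best is not None or any(
        h is not None for h in split_best.values()
    )
    if not any_hit:
        return AdjudicationVerdict(
            event.cluster_id, "false_positive", "no database hits in the group"
        )
    if merged_best is not None:
        n_shared = sum(
            1
            for h in split_best.values()
            if h is not None and h.subject == merged_best.subject
        )
        if n_shared >= min_shared:
            return AdjudicationVerdict(
                event.cluster_id,
                f"optimal_{merged_version}",
                f"{n_shared} split-side genes share the merged gene's best "
                f"hit {merged_best.subject}",
            )
    distinct = {h.subject for h in split_best.values() if h is not None}
    if len(distinct) >= 2:
        return AdjudicationVerdict(
            event.cluster_id,
            f"optimal_{split_version}",
            f"split-side genes have {len(distinct)} distinct best hits",
        )
    n_with_hit = sum(1 for h in split_best.values() if h is not None)
    if n_with_hit == 1:
        return AdjudicationVerdict(
            event.cluster_id,
            "ambiguous",
            "only one split-side gene has a hit",
        )
    return AdjudicationVerdict(
        event.cluster_id, "ambiguous", "best hits are inconclusive"
    )


# ---------------------------------------------------------------------------
# modified 1-to-1 pairs


METRICS = ("identity", "similarity", "score", "gaps")


@dataclass
class PairVerdict:
    pair_id: str
    comparable: bool
    reason: str = ""
    shared_subject: str | None = None
    stats_v1: AlignmentStats | None = None
    stats_v2: AlignmentStats | None = None
    outcome: dict[str, str] = field(default_factory=dict)


def _metric_outcome(s1: AlignmentStats, s2: AlignmentStats) -> dict[str, str]:
    out = {}
    for metric in METRICS:
        a, b = getattr(s1, metric), getattr(s2, metric)
        if metric == "gaps":  # fewer gaps is better
            a, b = -a, -b
        if a > b:
            out[metric] = "v1_better"
        elif b > a:
            out[metric] = "v2_better"
        else:
            out[metric] = "equal"
    return out


def compare_pair(
    pair_id: str,
    v1_gene_id: str,
    v2_gene_id: str,
    protein_v1: str,
    protein_v2: str,
    hits: HitTable,
    ref_proteins: dict[str, str],
    **align_kwargs,
) -> PairVerdict:
    """Compare a modified 1-to-1 gene pair through their shared best hit.

    Both proteins are aligned globally to the shared best hit's sequence
    from ``ref_proteins``; pairs without a shared best hit, or whose hit
    sequence is unavailable, are flagged not comparable.
    """
    b1 = hits.best_hit(v1_gene_id)
    b2 = hits.best_hit(v2_gene_id)
    if b1 is None or b2 is None or b1.subject != b2.subject:
        return PairVerdict(pair_id, False, reason="no shared best hit")
    subject = b1.subject
    ref = ref_proteins.get(subject)
    if ref is None:
        return PairVerdict(
            pair_id, False,
            reason=f"best-hit subject {subject} missing from reference",
            shared_subject=subject,
        )
    s1 = global_align(protein_v1, ref, **align_kwargs)
    s2 = global_align(protein_v2, ref, **align_kwargs)
    return PairVerdict(
        pair_id, True, shared_subject=subject,
        stats_v1=s1, stats_v2=s2, outcome=_metric_outcome(s1, s2),
    )


def composite_winner(verdict: PairVerdict) -> str:
    """Single-winner summary: lexicographic score > identity > similarity >
    fewer gaps; 'equal' when every metric ties."""
    if not verdict.comparable:
        return "not_comparable"
    for metric in ("score", "identity", "similarity", "gaps"):
        o = verdict.outcome[metric]
        if o != "equal":
            return o
    return "equal"


def domain_summary(
    domains: pd.DataFrame, gene_ids: list[str]
) -> dict[str, int]:
    """Domain tally over a gene set: genes with >= 1 domain and distinct
    domain accessions."""
    sub = domains[domains["gene_id"].isin(set(gene_ids))]
    return {
        "n_genes_with_domain": int(sub["gene_id"].nunique()),
        "n_distinct_domains": int(sub["domain_accession"].nunique()),
    }
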