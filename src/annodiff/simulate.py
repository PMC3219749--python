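"""Seeded synthetic genomes with paired annotation versions and truth ledger.

The generator emulates the study design behind annotation-version
comparison: a toy genome carries non-overlapping protein-coding genes with
complete ATG..stop CDSs (the "new" annotation, v2); a perturbed copy (the
"old" annotation, v1) plants a configured number of structural events —
merges (one multi-intron v2 gene cut into two v1 genes), splits (two
adjacent v2 genes fused into one v1 gene), frame-preserving boundary
shifts, and version-specific genes.  Evidence tracks emit each intron of a
multi-exon v2 gene independently per evidence class with a configured
probability, and homology/domain tables are constructed so that the
adjudication rules recover a planted label for every merge/split event.

Every random draw comes from one seeded generator, so a given config is
reproducible byte-for-byte, and the emitted truth ledger is sufficient to
recompute the expected output of every downstream analysis exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    write_gff3,
)

__all__ = ["SimConfig", "TruthLedger", "SimOutput", "generate", "expected_outputs"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def _codon_weights(gc: float) -> np.ndarray:
    """Per-codon probabilities matching the genome base composition,
    with stop codons excluded (they only ever terminate a CDS here)."""
    p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    w = np.array(
        [0.0 if c in _STOPS else p[c[0]] * p[c[1]] * p[c[2]]
         for c in _ALL_CODONS]
    )
    return w / w.sum()

ADJ_LABELS = ("optimal_merged", "optimal_split", "false_positive", "ambiguous")


@dataclass
class SimConfig:
    """Study-design parameters of one simulation."""

    seed: int = 0
    n_seqs: int = 4
    seq_length: int = 400_000
    gc: float = 0.32
    n_genes: int = 200
    exon_count_range: tuple[int, int] = (1, 8)
    protein_aa_range: tuple[int, int] = (60, 200)
    intron_length_range: tuple[int, int] = (60, 400)
    intergenic_gap_range: tuple[int, int] = (200, 800)
    min_exon_length: int = 30
    fraction_multi_isoform: float = 0.05
    n_merge: int = 5
    n_split: int = 5
    n_shift: int = 10
    n_specific_v1: int = 5
    n_specific_v2: int = 5
    shift_max_codons: int = 2
    p_transcript: float = 0.9
    p_protein: float = 0.6
    p_denovo: float = 0.75
    p_est: float = 0.3
    label_mix: dict = field(
        default_factory=lambda: {
            "optimal_merged": 0.5,
            "optimal_split": 0.3,
            "false_positive": 0.1,
            "ambiguous": 0.1,
        }
    )

    def __post_init__(self) -> None:
        for p in (
            self.p_transcript, self.p_protein, self.p_denovo, self.p_est,
            self.fraction_multi_isoform,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        consumed = (
            self.n_merge + 2 * self.n_split + self.n_shift + self.n_specific_v2
        )
        if consumed > self.n_genes:
            raise ValueError(
                f"planted events need {consumed} genes but n_genes={self.n_genes}"
            )
        if abs(sum(self.label_mix.values()) - 1.0) > 1e-9:
            raise ValueError("label_mix must sum to 1")
        if set(self.label_mix) - set(ADJ_LABELS):
            raise ValueError(f"label_mix keys must be among {ADJ_LABELS}")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("exon_count_range", "protein_aa_range",
                    "intron_length_range", "intergenic_gap_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthLedger:
    """Machine-readable record of what was planted, for recovery testing."""

    config: dict
    counts: dict
    events: list  # {event_id, kind, v1_ids, v2_ids, label?, subject?}
    evidence: dict  # v2 gene id -> {n_introns, transcript, protein, denovo}
    pairs: list  # modified 1-to-1 pairs: {pair_id, v1_id, v2_id, subject}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "TruthLedger":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**{k: d[k] for k in ("config", "counts", "events",
                                        "evidence", "pairs")})


@dataclass
class SimOutput:
    outdir: str
    genome_fa: str
    v1_gff3: str
    v2_gff3: str
    track_files: dict  # track name -> (path, class)
    hits_tsv: str
    domains_tsv: str
    ref_proteins_fa: str
    truth_json: str
    truth: TruthLedger


# ---------------------------------------------------------------------------
# blueprints


@dataclass
class _GeneBlueprint:
    exon_sizes: list[int]
    intron_sizes: list[int]
    cds_seq: str  # 5'->3' mRNA orientation, ATG..stop
    strand: str
    # filled at placement time:
    seq_id: str = ""
    exons: list = field(default_factory=list)

    @property
    def footprint(self) -> int:
        return sum(self.exon_sizes) + sum(self.intron_sizes)

    @property
    def protein(self) -> str:
        from Bio.Seq import Seq

        return str(Seq(self.cds_seq).translate())[:-1]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _make_cds(rng: np.random.Generator, n_aa: int, weights: np.ndarray) -> str:
    body = "".join(
        _ALL_CODONS[i] for i in rng.choice(64, size=n_aa - 1, p=weights)
    )
    return "ATG" + body + _STOPS[rng.integers(0, 3)]


def _partition(rng: np.random.Generator, total: int, parts: int, min_part: int):
    parts = max(1, min(parts, total // min_part))
    extra = total - parts * min_part
    if parts == 1:
        return [total]
    add = rng.multinomial(extra, [1.0 / parts] * parts)
    return [min_part + int(a) for a in add]


def _make_gene(
    rng: np.random.Generator, cfg: SimConfig, min_exons: int = 1,
    strand: str | None = None,
) -> _GeneBlueprint:
    lo, hi = cfg.exon_count_range
    n_exons = int(rng.integers(max(lo, min_exons), hi + 1))
    n_aa = int(rng.integers(*cfg.protein_aa_range))
    cds = _make_cds(rng, n_aa, _codon_weights(cfg.gc))
    exon_sizes = _partition(rng, len(cds), n_exons, cfg.min_exon_length)
    introns = [
        int(rng.integers(*cfg.intron_length_range))
        for _ in range(len(exon_sizes) - 1)
    ]
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    return _GeneBlueprint(exon_sizes, introns, cds, strand)


def _place(bp: _GeneBlueprint, seq_id: str, start: int) -> None:
    """Assign absolute exon intervals from a genomic start position."""
    bp.seq_id = seq_id
    bp.exons = []
    pos = start
    for i, size in enumerate(bp.exon_sizes):
        bp.exons.append((pos, pos + size - 1))
        pos += size
        if i < len(bp.intron_sizes):
            pos += bp.intron_sizes[i]


def _genomic_exon_chunks(bp: _GeneBlueprint) -> list[str]:
    """Plus-strand genomic content of each exon, ascending order."""
    s = bp.cds_seq if bp.strand == "+" else reverse_complement(bp.cds_seq)
    chunks, off = [], 0
    for size in bp.exon_sizes:
        chunks.append(s[off : off + size])
        off += size
    return chunks


def _gene_model(
    gene_id: str, bp: _GeneBlueprint, exon_subset=None, end_delta: dict | None = None,
    extra_isoform_skip: int | None = None,
) -> GeneModel:
    """Build a GeneModel from placed blueprint coordinates.

    ``exon_subset`` restricts to a slice of exon indices; ``end_delta`` maps
    exon index -> adjustment of that exon's end coordinate;
    ``extra_isoform_skip`` adds a second isoform skipping one exon.
    """
    idx = list(range(len(bp.exons))) if exon_subset is None else list(exon_subset)
    deltas = end_delta or {}
    ivs = [
        GenomicInterval(
            bp.seq_id, bp.exons[i][0], bp.exons[i][1] + deltas.get(i, 0), bp.strand
        )
        for i in idx
    ]
    transcripts = [
        TranscriptModel(f"{gene_id}.t1", gene_id, ivs, list(ivs))
    ]
    if extra_isoform_skip is not None and len(ivs) >= 3:
        ivs2 = [v for k, v in enumerate(ivs) if k != extra_isoform_skip]
        transcripts.append(
            TranscriptModel(f"{gene_id}.t2", gene_id, ivs2, list(ivs2))
        )
    return GeneModel(gene_id, bp.seq_id, bp.strand, transcripts)


# ---------------------------------------------------------------------------
# generation


def _write_fasta(path: str, records: list[tuple[str, str]], width: int = 80):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_track(path: str, chains: list[tuple[str, list[tuple]]], source: str):
    """chains: (chain_id, [(seq, start, end, strand), ...])"""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, segs in chains:
            seq, strand = segs[0][0], segs[0][3]
            lo = min(s for _, s, _, _ in segs)
            hi = max(e for _, _, e, _ in segs)
            fh.write(
                f"{seq}\t{source}\tmatch\t{lo}\t{hi}\t.\t{strand}\t.\tID={cid}\n"
            )
            for k, (sq, s, e, st) in enumerate(segs, 1):
                fh.write(
                    f"{sq}\t{source}\tmatch_part\t{s}\t{e}\t.\t{st}\t.\t"
                    f"ID={cid}.p{k};Parent={cid}\n"
                )


def _runs(indices: list[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers as (first, last) pairs."""
    runs = []
    for i in sorted(indices):
        if runs and i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    return [tuple(r) for r in runs]


def generate(cfg: SimConfig, outdir: str) -> SimOutput:
    """Generate the full synthetic dataset under ``outdir``.

    Writes ``genome.fa``, ``v1.gff3``, ``v2.gff3``, ``tracks/*.gff3``,
    ``hits.tsv``, ``domains.tsv``, ``ref_proteins.fa`` and ``truth.json``;
    the same config (including seed) always produces byte-identical files.
    """
    rng = np.random.default_rng(cfg.seed)

    # --- plan the unit sequence -------------------------------------------
    n_ident = cfg.n_genes - (
        cfg.n_merge + 2 * cfg.n_split + cfg.n_shift + cfg.n_specific_v2
    )
    units = (
        ["merge"] * cfg.n_merge
        + ["split"] * cfg.n_split
        + ["shift"] * cfg.n_shift
        + ["spec2"] * cfg.n_specific_v2
        + ["spec1"] * cfg.n_specific_v1
        + ["ident"] * n_ident
    )
    rng.shuffle(units)

    # --- build blueprints and place them on sequences ---------------------
    seq_names = [f"chr{i + 1}" for i in range(cfg.n_seqs)]
    cursor = {name: 0 for name in seq_names}
    seq_idx = 0
    placed: list[tuple[str, list[_GeneBlueprint], int | None]] = []
    for unit in units:
        if unit in ("merge", "shift"):
            bps = [_make_gene(rng, cfg, min_exons=2)]
        elif unit == "split":
            strand = "+" if rng.random() < 0.5 else "-"
            bps = [
                _make_gene(rng, cfg, strand=strand),
                _make_gene(rng, cfg, strand=strand),
            ]
        else:
            bps = [_make_gene(rng, cfg)]
        gaps = [int(rng.integers(*cfg.intergenic_gap_range)) for _ in bps]
        inner_gap = gaps[1] if len(bps) == 2 else None
        need = sum(b.footprint for b in bps) + sum(gaps)
        while seq_idx < len(seq_names) and (
            cursor[seq_names[seq_idx]] + need > cfg.seq_length
        ):
            seq_idx += 1
        if seq_idx >= len(seq_names):
            raise ValueError(
                "config infeasible: genes do not fit on "
                f"{cfg.n_seqs} x {cfg.seq_length} bp sequences"
            )
        seq = seq_names[seq_idx]
        pos = cursor[seq] + gaps[0]
        _place(bps[0], seq, pos + 1)  # 1-based
        if len(bps) == 2:
            pos2 = pos + bps[0].footprint + inner_gap
            _place(bps[1], seq, pos2 + 1)
            cursor[seq] = pos2 + bps[1].footprint
        else:
            cursor[seq] = pos + bps[0].footprint
        placed.append((unit, bps, inner_gap))

    # --- genome sequences --------------------------------------------------
    genome: dict[str, str] = {}
    per_seq_parts: dict[str, list[tuple[int, str]]] = {n: [] for n in seq_names}
    for unit, bps, _ in placed:
        for bp in bps:
            for (s, e), chunk in zip(bp.exons, _genomic_exon_chunks(bp)):
                per_seq_parts[bp.seq_id].append((s, chunk))
    for name in seq_names:
        arr = np.frombuffer(
            _random_seq(rng, cfg.seq_length, cfg.gc).encode(), dtype=np.uint8
        ).copy()
        for start, chunk in per_seq_parts[name]:
            arr[start - 1 : start - 1 + len(chunk)] = np.frombuffer(
                chunk.encode(), dtype=np.uint8
            )
        genome[name] = arr.tobytes().decode()

    # --- derive v1/v2 gene models and the event ledger ---------------------
    v1_genes: list[GeneModel] = []
    v2_genes: list[GeneModel] = []
    events: list[dict] = []
    pairs: list[dict] = []
    hit_rows: list[tuple] = []
    domain_rows: list[tuple[str, str]] = []
    ref_proteins: list[tuple[str, str]] = []
    counts = {k: 0 for k in (
        "identical", "modified_1to1", "merged", "split",
        "specific_v1", "specific_v2", "complex",
    )}
    gene_no = 0
    acc_no = 0
    ev_no = 0
    domain_pool = [f"PF{i:05d}" for i in range(1, 41)]

    def next_ids():
        nonlocal gene_no
        gene_no += 1
        return f"v1.g{gene_no:05d}", f"v2.g{gene_no:05d}"

    def next_acc():
        nonlocal acc_no
        acc_no += 1
        return f"UPSYN{acc_no:05d}"

    def next_ev():
        nonlocal ev_no
        ev_no += 1
        return f"ev{ev_no:05d}"

    def emit_hit(query: str, subject: str, evalue: float = 1e-80,
                 bitscore: float = 500.0):
        hit_rows.append(
            (query, subject, 98.0, 100, 2, 0, 1, 100, 1, 100, evalue, bitscore)
        )

    label_names = sorted(cfg.label_mix)
    label_probs = [cfg.label_mix[k] for k in label_names]

    for unit, bps, _ in placed:
        if unit == "ident":
            id1, id2 = next_ids()
            bp = bps[0]
            skip = None
            if (
                rng.random() < cfg.fraction_multi_isoform
                and len(bp.exon_sizes) >= 3
            ):
                skip = int(rng.integers(1, len(bp.exon_sizes) - 1))
            v1_genes.append(_gene_model(id1, bp))
            v2_genes.append(_gene_model(id2, bp, extra_isoform_skip=skip))
            counts["identical"] += 1
            events.append(
                {"event_id": next_ev(), "kind": "identical",
                 "v1_ids": [id1], "v2_ids": [id2]}
            )
        elif unit == "spec1":
            id1, _ = next_ids()
            v1_genes.append(_gene_model(id1, bps[0]))
            counts["specific_v1"] += 1
            events.append(
                {"event_id": next_ev(), "kind": "specific_v1",
                 "v1_ids": [id1], "v2_ids": []}
            )
        elif unit == "spec2":
            _, id2 = next_ids()
            v2_genes.append(_gene_model(id2, bps[0]))
            counts["specific_v2"] += 1
            events.append(
                {"event_id": next_ev(), "kind": "specific_v2",
                 "v1_ids": [], "v2_ids": [id2]}
            )
        elif unit == "shift":
            id1, id2 = next_ids()
            bp = bps[0]
            j = int(rng.integers(0, len(bp.exon_sizes) - 1))
            delta = 3 * int(rng.integers(1, cfg.shift_max_codons + 1))
            v1 = _gene_model(id1, bp, end_delta={j: delta})
            v2 = _gene_model(id2, bp)
            v1_genes.append(v1)
            v2_genes.append(v2)
            counts["modified_1to1"] += 1
            subject = next_acc()
            ref_proteins.append((subject, bp.protein))
            emit_hit(id1, subject)
            emit_hit(id2, subject)
            n_dom = int(rng.integers(1, 3))
            doms = [domain_pool[int(i)] for i in
                    rng.choice(len(domain_pool), size=n_dom, replace=False)]
            for d in doms:
                domain_rows.append((id2, d))
            for d in doms[: max(1, n_dom - 1)]:
                domain_rows.append((id1, d))
            pairs.append(
                {"pair_id": f"pair.{id2}", "v1_id": id1, "v2_id": id2,
                 "subject": subject}
            )
            events.append(
                {"event_id": next_ev(), "kind": "modified_1to1",
                 "v1_ids": [id1], "v2_ids": [id2]}
            )
        elif unit == "merge":
            # one multi-intron v2 gene cut into two v1 genes
            ida, _ = next_ids()
            idb, id2 = next_ids()
            bp = bps[0]
            cut = int(rng.integers(1, len(bp.exon_sizes)))
            v1a = _gene_model(ida, bp, exon_subset=range(0, cut))
            v1b = _gene_model(idb, bp, exon_subset=range(cut, len(bp.exon_sizes)))
            v1_genes.extend([v1a, v1b])
            v2_genes.append(_gene_model(id2, bp))
            counts["merged"] += 1
            label = label_names[
                int(rng.choice(len(label_names), p=label_probs))
            ]
            _plant_hits(label, id2, [ida, idb], next_acc, emit_hit)
            ref_proteins.append((f"grp.{id2}", bp.protein))
            events.append(
                {"event_id": next_ev(), "kind": "merged",
                 "v1_ids": [ida, idb], "v2_ids": [id2], "label": label}
            )
        elif unit == "split":
            # two adjacent same-strand v2 genes fused into one v1 gene
            id1, id2a = next_ids()
            _, id2b = next_ids()
            bpa, bpb = bps
            fused_exons = bpa.exons + bpb.exons
            ivs = [
                GenomicInterval(bpa.seq_id, s, e, bpa.strand)
                for s, e in fused_exons
            ]
            t = TranscriptModel(f"{id1}.t1", id1, ivs, list(ivs))
            v1_genes.append(GeneModel(id1, bpa.seq_id, bpa.strand, [t]))
            v2_genes.append(_gene_model(id2a, bpa))
            v2_genes.append(_gene_model(id2b, bpb))
            counts["split"] += 1
            label = label_names[
                int(rng.choice(len(label_names), p=label_probs))
            ]
            _plant_hits(label, id1, [id2a, id2b], next_acc, emit_hit)
            ref_proteins.append((f"grp.{id1}", bpa.protein))
            events.append(
                {"event_id": next_ev(), "kind": "split",
                 "v1_ids": [id1], "v2_ids": [id2a, id2b], "label": label}
            )

    # --- evidence tracks ----------------------------------------------------
    evidence: dict[str, dict] = {}
    class_probs = {
        "transcript": cfg.p_transcript,
        "protein": cfg.p_protein,
        "denovo": cfg.p_denovo,
    }
    track_chains: dict[str, list] = {
        "rnaseq": [], "est": [], "genewise": [], "snap": [],
    }
    class_of_track = {
        "rnaseq": "transcript", "est": "transcript",
        "genewise": "protein", "snap": "denovo",
    }
    chain_no = 0
    for g in sorted(v2_genes, key=lambda g: g.id):
        rep = g.representative_isoform()
        if len(rep.exons) < 2:
            continue
        k = len(rep.exons) - 1
        rec = {"n_introns": k}
        emitted_by_class: dict[str, list[int]] = {}
        for cls in ("transcript", "protein", "denovo"):
            p = class_probs[cls]
            emitted = [i for i in range(k) if rng.random() < p]
            rec[cls] = emitted
            emitted_by_class[cls] = emitted
        evidence[g.id] = rec

        def chains_for(indices: list[int]) -> list:
            nonlocal chain_no
            out = []
            for first, last in _runs(indices):
                chain_no += 1
                segs = [
                    (e.seq_id, e.start, e.end, e.strand)
                    for e in rep.exons[first : last + 2]
                ]
                out.append((f"chain{chain_no:06d}", segs))
            return out

        track_chains["rnaseq"].extend(chains_for(emitted_by_class["transcript"]))
        est_sub = [
            i for i in emitted_by_class["transcript"] if rng.random() < cfg.p_est
        ]
        track_chains["est"].extend(chains_for(est_sub))
        track_chains["genewise"].extend(chains_for(emitted_by_class["protein"]))
        track_chains["snap"].extend(chains_for(emitted_by_class["denovo"]))

    # --- write everything ---------------------------------------------------
    os.makedirs(outdir, exist_ok=True)
    tracks_dir = os.path.join(outdir, "tracks")
    os.makedirs(tracks_dir, exist_ok=True)

    genome_fa = os.path.join(outdir, "genome.fa")
    _write_fasta(genome_fa, [(n, genome[n]) for n in seq_names])

    v1_path = os.path.join(outdir, "v1.gff3")
    v2_path = os.path.join(outdir, "v2.gff3")
    write_gff3(AnnotationSet("annotVer 1.0", v1_genes), v1_path)
    write_gff3(AnnotationSet("annotVer 2.0", v2_genes), v2_path)

    track_files = {}
    for name, chains in track_chains.items():
        path = os.path.join(tracks_dir, f"{name}.gff3")
        _write_track(path, chains, source=name)
        track_files[name] = (path, class_of_track[name])

    hits_tsv = os.path.join(outdir, "hits.tsv")
    with open(hits_tsv, "w") as fh:
        for row in hit_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    domains_tsv = os.path.join(outdir, "domains.tsv")
    with open(domains_tsv, "w") as fh:
        for gid, dom in domain_rows:
            fh.write(f"{gid}\t{dom}\n")

    ref_fa = os.path.join(outdir, "ref_proteins.fa")
    _write_fasta(ref_fa, ref_proteins, width=60)

    truth = TruthLedger(
        config=asdict(cfg),
        counts=counts,
        events=events,
        evidence=evidence,
        pairs=pairs,
    )
    truth_json = os.path.join(outdir, "truth.json")
    truth.to_json(truth_json)

    return SimOutput(
        outdir, genome_fa, v1_path, v2_path, track_files,
        hits_tsv, domains_tsv, ref_fa, truth_json, truth,
    )


def _plant_hits(label: str, merged_id: str, split_ids: list[str],
                next_acc, emit_hit) -> None:
    """Emit homology rows that make the rule table produce ``label``."""
    if label == "false_positive":
        return
    if label == "optimal_merged":
        acc = next_acc()
        emit_hit(merged_id, acc)
        # a worse secondary hit and an over-cutoff row exercise ranking/filter
        emit_hit(merged_id, next_acc(), evalue=1e-8, bitscore=80.0)
        emit_hit(merged_id, next_acc(), evalue=1e-3, bitscore=30.0)
        for gid in split_ids:
            emit_hit(gid, acc)
    elif label == "optimal_split":
        accs = [next_acc() for _ in split_ids]
        for gid, acc in zip(split_ids, accs):
            emit_hit(gid, acc)
        emit_hit(merged_id, accs[0])
    elif label == "ambiguous":
        acc = next_acc()
        emit_hit(merged_id, acc)
        emit_hit(split_ids[0], acc)
    else:
        raise ValueError(f"unknown planted label {label!r}")


# ---------------------------------------------------------------------------
# ledger-derived expectations (closed-form oracles for the test suite)


def expected_outputs(truth: TruthLedger) -> dict:
    """Expected downstream results implied by a truth ledger.

    Returns expected structural-event counts, the expected adjudication
    verdict per merge/split event keyed by its sorted member-id tuples, and
    the expected per-class support profile per multi-exon gene.
    """
    verdict_map_merged = {
        "optimal_merged": "optimal_v2",
        "optimal_split": "optimal_v1",
        "false_positive": "false_positive",
        "ambiguous": "ambiguous",
    }
    verdict_map_split = {
        "optimal_merged": "optimal_v1",
        "optimal_split": "optimal_v2",
        "false_positive": "false_positive",
        "ambiguous": "ambiguous",
    }
    verdicts = {}
    for ev in truth.events:
        if ev["kind"] not in ("merged", "split"):
            continue
        key = (tuple(sorted(ev["v1_ids"])), tuple(sorted(ev["v2_ids"])))
        mapping = (
            verdict_map_merged if ev["kind"] == "merged" else verdict_map_split
        )
        verdicts[key] = mapping[ev["label"]]

    profiles = {}
    for gid, rec in truth.evidence.items():
        k = rec["n_introns"]
        profiles[gid] = {
            cls: {
                "n_supported": len(rec[cls]),
                "supported": len(rec[cls]) >= 1,
                "full_length": len(rec[cls]) == k,
            }
            for cls in ("transcript", "protein", "denovo")
        }
    return {
        "event_counts": dict(truth.counts),
        "verdicts": verdicts,
        "profiles": profiles,
    }
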