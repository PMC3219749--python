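# Methods

## Scope and model

`annodiff` treats an annotation version as a set of gene models — gene →
transcript isoform(s) → exons and CDS segments — on a shared assembly,
with all coordinates 1-based inclusive as in GFF3. Three analyses sit on
top of that model: locus-level structural comparison of two versions,
homology-based adjudication of the differences, and intron-level evidence
support. All three follow the same two commitments:

* **Coding coordinates decide structure.** Loci are defined by ≥ 1 bp
  overlap of the per-base union of CDS segments (UTRs change too easily
  between versions to be informative), and two genes have "the same
  structure" exactly when some isoform of one has the identical ordered
  CDS coordinate list as some isoform of the other. A pair differs only
  when *all* isoform combinations differ.
* **Intron identity is exact.** An intron is the tuple
  (seq_id, strand, first base, last base); evidence supports it only on
  exact coordinate equality of both splice boundaries. No slack window is
  applied — a "fully supported" intron chain means every boundary agrees
  to the base.

## Locus clustering and classification

Genes of both versions are nodes of an overlap graph (CDS unions sharing
≥ 1 bp, same sequence and — by default — same strand); loci are its
connected components, computed by a sorted interval sweep with union-find
(equivalent to, and tested against, brute-force graph components).
Cluster shape {m v1 genes, n v2 genes} determines the category:
{1,0}/{0,1} version-specific, {1,1} identical or modified, {m≥2,1}
merged, {1,n≥2} split. {m≥2,n≥2} clusters are reported as `complex` and
never forced into merged or split — they are rare, structurally distinct,
and collapsing them would bias both tallies. Strandedness is a flag:
merged/split events are meaningful only within a strand, so
opposite-strand overlaps form separate loci unless `--unstranded` is
given. Ordering is deterministic everywhere (sequence, start, then gene
id), so repeated runs produce identical outputs.

Loci touching a gene with ≥ 2 isoforms can be excluded before
adjudication (`exclude_multi_isoform`), since alternative splicing makes
"the better structure" ill-posed for these analyses.

## Adjudication

Merge/split loci group one *merged* gene with ≥ 2 *split* counterparts.
With a hit table (12-column BLAST-style TSV, E-value cutoff 1e-5, best
hit = lowest E-value then highest bitscore), the rules apply in order:

1. no hit anywhere in the group → `false_positive`;
2. ≥ `min_shared` split-side genes share the merged gene's best hit →
   the merged side is optimal;
3. split-side genes have ≥ 2 distinct best hits → the split side is
   optimal;
4. otherwise (including the lone split-side hit case) → `ambiguous`.

`min_shared` defaults to 2: a two-gene merge has exactly two
counterparts, so requiring strictly more than two would leave the common
case unadjudicable; the stricter reading remains available through the
parameter.

Modified 1-to-1 pairs are compared through their shared best hit: each
protein is aligned globally to the hit's sequence and the four metrics —
identity, similarity, score, gap count (fewer is better) — are reported
per metric rather than collapsed, because the per-metric tallies are the
informative output; a composite winner (score, then identity, similarity,
fewer gaps) is available separately. Pairs without a shared best hit, or
whose hit sequence is absent from the reference FASTA, are flagged "not
comparable" rather than failing the run.

## Global aligner

A three-state Gotoh dynamic program under
`score = Σ matrix(a,b) − Σ_gaps (gap_open + (len−1)·gap_extend)`,
defaults BLOSUM62 / 12 / 2 — the conventional parameters of EMBOSS-style
global protein aligners. Identity and similarity use the full alignment
length as denominator (gap columns count toward length, never toward the
numerators), and similarity counts columns with a positive substitution
score. Traceback tie-breaking is fixed — diagonal, then vertical, then
horizontal — so alignments are reproducible. The implementation is
validated two ways: exhaustive enumeration of all alignment paths for
short peptides, and score agreement with Biopython's `PairwiseAligner`
on random proteins. All default scores are integers, so the float
comparisons in the traceback are exact.

## Summary statistics, ORFs and filters

The report panel counts genes/transcripts/exons/introns, their mean
lengths and GC, UTR statistics, gene density (kb/gene) and percent
coding. Percent coding uses the per-base union of CDS over the genome,
so overlapping isoforms are never double-counted and the value cannot
exceed 100 %. Transcript length is the genomic span (exons + introns);
the identity `n_introns = n_exons − n_transcripts` holds on every input
and is asserted in tests. UTRs absent from the input are derived as
exon-minus-CDS, split 5′/3′ by strand.

Report rounding is configurable (`half-up`, the default, or `truncate`)
because published annotation tables are not consistent: recomputing one
well-known table's percentage statistics from their printed count pairs
reproduces every value under half-up except a single statistic
(16,270/18,580 = 87.57 %, printed as 87.5), which only truncation
explains. The acceptance script reports that one statistic truncated and
everything else half-up.

The ORF scanner checks all six frames; an ORF runs from an ATG to the
first in-frame stop (stop included in the length) and only start+stop
ORFs count as complete. Per transcript it reports the longest complete
ORF — the convention when a published method does not say how multiple
ORFs were resolved — and a flag for any complete ORF ≥ `min_nt`
(default 30, the *getorf* default). The gene-model filter removes a gene
only when **every** isoform fails (protein < 50 aa, or missing
start/stop); the transcript filter keeps sequences ≥ 150 bp. Both
thresholds are inclusive on the keep side (50 aa kept, 150 bp kept).

## Evidence support

Evidence arrives as multi-segment chains (GFF3 `match`/`match_part` or
exon/Parent groupings, or BED12 blocks); each chain contributes the
intron keys between consecutive segments, de-duplicated per track.
Tracks carry a class label (transcript / protein / de novo); class
support is the union of that class's tracks. Which tracks belong to
which class — and which predictors to exclude because they were trained
on evidence — is configuration, not hard-coded names. Profiles are
computed per gene on the representative isoform (longest CDS, ties by
id), using the exon chain so UTR introns count; single-exon genes are
excluded from the analysis (they have no introns to support) and
reported as skipped. Venn regions are disjoint by construction and the
unsupported bucket is reported alongside, so regions + `none` always sum
to the number of genes profiled.

## Synthetic data generator

The generator stands in for the assemblies and evidence of a real
re-annotation study. Defaults, chosen once as a compact-plant-genome
caricature: GC 0.32; 1–8 exons per gene (uniform); proteins 60–200 aa;
introns 60–400 bp; intergenic gaps 200–800 bp; per-intron support
probabilities 0.9 (transcript), 0.6 (protein), 0.75 (de novo), echoing
the usual ordering in which transcript evidence supports the most
full-length genes and protein evidence the fewest; 5 % of unperturbed
genes get a second (exon-skipping) isoform; planted merge/split loci
draw their adjudication label from a 0.5/0.3/0.1/0.1 mix of
optimal-merged / optimal-split / false-positive / ambiguous.

Construction guarantees, which the tests rely on:

* Planted events occupy disjoint gene sets, so expected category counts
  are exact, not approximate.
* Every v2 gene carries a complete ATG…stop CDS with no internal stops;
  coding codons are sampled from the genome base composition (stop
  codons excluded), so genome GC stays close to the configured target.
  The exclusion of stops biases coding GC up very slightly; the GC test
  therefore allows max(3 σ, 0.01) absolute deviation.
* Boundary shifts move one internal CDS boundary by a multiple of 3 into
  the adjacent intron, preserving frame and both terminal codons, so
  shifted genes still pass the ≥ 50 aa / start+stop filter and differ
  from their partners purely structurally.
* Merged-event v1 genes are cut from the v2 gene's CDS chain, and
  split-event v1 genes fuse two adjacent same-strand v2 genes; these
  fragments re-use v2 coordinates and (like real fragmented predictions)
  need not be complete ORFs — structural comparison never translates.
* Evidence introns are emitted per gene, per class, per intron as
  independent Bernoulli draws; emitted runs of consecutive introns
  become multi-segment chains whose segments are the gene's own exons,
  so recovered intron keys match the ledger exactly. The EST track is a
  random subset of the RNA-Seq emissions (most EST support is covered by
  RNA-Seq).
* Hit tables are built so the rule table recovers each planted label,
  including decoy secondary hits and an over-cutoff row to exercise
  ranking and E-value filtering. For modified pairs, the reference
  protein is the v2 translation, so the v2 member of each pair aligns at
  least as well as the shifted v1 member.
* All randomness flows from one seeded generator; a config reproduces
  its output byte-for-byte.

What the generator does **not** emulate: read-level noise, alignment
error, repeat-driven mis-assembly, overlapping genes, trans-splicing,
non-canonical splice sites, UTR annotation (generated genes are fully
coding), or realistic E-value distributions. Passing the recovery tests
therefore shows the analyses are correct on well-formed input, not that
they are robust to noisy alignments or broken assemblies.

## Problem sizes and numerical choices

The full-scale simulation used by the tests and the acceptance script is
2,000 genes on 8 × 600 kb sequences with 30 merges, 30 splits, 100
boundary shifts and 50 + 50 version-specific genes — large enough that
every intron count 1–6 has ≥ 100 genes for the binomial
full-length-support check (observed fraction within 3 σ of p^k), while
the whole pipeline runs in seconds. Oracle-equivalence tests use 100
random 200-gene sets against brute-force graph components, and exhaustive
alignment-path enumeration on sampled peptide pairs (lengths 1–6 over a
four-letter alphabet; enumerating *all* such pairs would be ~30 M
alignments for no additional coverage). Degenerate inputs are defined
rather than accidental: empty annotation → zero counts with missing
means; empty or all-N sequence → GC undefined (reported missing); zero
denominators → missing ratios; genes without CDS form singleton loci;
abutting exons (no intron between) are rejected as invalid gene models.

## Known limitations

Clustering assumes both versions are on identical assembly coordinates —
mapping an annotation across assemblies (e.g. with spaln) must happen
upstream. The aligner is quadratic pure Python: fine for proteins of a
few hundred residues, not for genome-scale alignment. Redundant genes
mapping to one locus (a real phenomenon when an assembly collapses
repeats) appear as merged or complex clusters; the package reports them
but cannot tell redundancy from true merger without the homology step.
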