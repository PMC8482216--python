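# Methods

## Scope and data model

`snoscout` starts from alignments: read trimming and mapping are outside
its scope, and it consumes either SAM text or a simplified 7-column
alignment TSV (read id, sample, contig, strand, comma-separated block
starts/ends, MAPQ). All internal coordinates are 0-based half-open on a
(contig, strand) pair; conversion to/from GFF3's 1-based closed convention
happens only at the I/O boundary. Spliced alignments become multi-block
reads; in CIGAR terms, M/=/X and D consume reference within a block, N
splits blocks (a junction), S/I/H/P consume none. Strand `.` is treated as
matching both strands in overlap tests, because strandedness of a
size-selected library is a property of the protocol, not of the method;
stranded mode is a config flag.

## Feature assignment

Each read collects the set of feature classes overlapped (≥1 bp of any
aligned block, no minimum-overlap fraction) by querying per-contig interval
trees. Zero classes → IR (intergenic); one class → that class; two or more →
MF, removed from novelty calling. Overlap with an already-annotated sncRNA
or a repeat dominates everything else: those reads are excluded regardless
of other overlaps. Two records of the *same* class (e.g. introns of two
genes) count as unambiguous by default (`same_class_is_unique`), since
same-type ambiguity is resolved later by host assignment. Promoters default
to the 1 kb window upstream of each transcript start (strand-aware,
configurable); introns are derived as gaps between consecutive exons when
the annotation does not carry them explicitly.

## Cluster calling

Only iR/IR reads participate. Clusters are maximal runs of per-base depth
≥ 1 (runs separated by ≤ `merge_gap` uncovered bases merge; default 0); a
cluster's support is the number of **distinct reads** overlapping the run,
and candidates require ≥ `min_reads` (default 20) of them — the rule counts
reads, not per-base depth, though a `min_depth` mode implements the
alternative reading. Candidate strand is the majority strand of member
reads (ties → `.`); candidates shorter than `min_length` (default 50 nt,
the library's lower size bound) are dropped.

Boundaries: the raw envelope (min start / max end of member blocks) is
inflated by whatever end-raggedness the reads carry. Because the mature
termini of a processed RNA dominate its pileup, the default boundaries are
the **modal** member-read start and end (ties resolved outward); the
envelope is available via `refine_ends=False`. This matters downstream: the
H/ACA 3′ rule ("ACA exactly 3 nt from the end") carries most of that
class's specificity and only works on accurately called termini.

## Class prediction

The classifier is a deliberately transparent rule cascade — no trained
model, no scores that cannot be traced to a motif hit or a pair count. The
machine-learning predictors often used for this task are replaced, not
re-implemented: their training data and weights are not reproducible from
literature, whereas the class definitions are.

* **C/D**: C box `RUGAUGA` (≤1 mismatch) starting within the first
  `c_window` = 12 nt, D box `CUGA` (exact) within the last `d_window` = 12
  nt, and a terminal stem: Nussinov maximum pairing over the concatenated
  5′ and 3′ 15-mers, normalized by 7 (the maximum pairs that window can
  form given the loop minimum), must reach `min_stem_score` = 0.5.
* **H/ACA**: `ACA` ending exactly `aca_offset` = 3 nt from the 3′ end
  (exact), an H box `ANANNA` (≤1 mismatch) in the hinge window
  (0.30–0.80 of length), and both flanking segments folding to
  ≥ `min_hairpin_pairs` = 5 nested pairs.
* **scaRNA**: class requirements met *plus* a CAB box (default consensus
  `UGAG`, config-overridable — the canonical literature names the box but
  its consensus varies) in a hairpin apical loop. The loop test is direct
  stem complementarity: an antiparallel run of ≥ `cab_min_stem` = 6
  complementary pairs must close a small loop (≤ 3 spare bases per side)
  containing the hit. An earlier design inspected the dot-bracket of a
  locally folded window instead; that is fragile because maximum-pairing
  structures are massively degenerate under GU wobble, and whether the
  reported optimum leaves the loop unpaired is an arbitrary tie-break.
  Candidates meeting both the C/D and H/ACA cascades with a CAB box are
  tandem scaRNAs; without a CAB box the higher-confidence single class is
  reported and the conflict logged.

Confidence is `0.5·box_quality + 0.5·structure_score`, with box quality =
mean (1 − mismatches/length) over the required boxes. Degenerate inputs
(outside 50–400 nt, non-ACGU characters) return `unknown` rather than
raising.

Folding is Nussinov maximum nested base pairing (AU/GC/GU, loop minimum 3,
O(n³) dynamic programming with traceback). It is applied only to bounded
windows (30-nt terminal stems, hairpin domains, CAB neighborhoods), never
to whole candidates, so the cubic cost is irrelevant in practice. Maximum
pairing is a coarse stand-in for thermodynamic folding; it is used here as
*evidence of pairing capacity*, with the discriminative weight carried by
the boxes. On 1,000 uniform-random 140-mers the cascade labels ≥ 95%
`unknown` (measured in the test suite).

## Homology

BLAST is replaced by an in-repo seeded aligner: every k-mer (k = 11, both
strands) of the reference set is indexed; query k-mer hits rank subjects;
the top 10 are aligned with affine-gap Smith–Waterman (match +2, mismatch
−3; a gap of length L costs −5 − 2L, i.e. open charged once plus extend per
column — the parameters mirror common nucleotide-search defaults and the
convention is fixed by the tests against an independent aligner). Hits need
identity ≥ 0.8 over the aligned span and query coverage ≥ 0.5; ties break
by (score, identity, subject id). Reference families are read from
`family=<tag>` tokens on FASTA description lines. No E-value statistics:
at desk-scale reference sets, score/identity/coverage thresholds are
sufficient and deterministic.

## Host linkage and correlation

An intronic candidate links to the gene whose intron fully contains it;
when introns of several genes contain it the smallest boundary slack wins
(deterministic, logged). Counts are log(x+1)-transformed before Pearson
correlation (raw mode available); vectors with zero variance yield an
undefined r, flagged and excluded from the summary mean. Candidate count
rows carry locus coordinates so pipeline candidates are matched to
quantification rows by interval overlap rather than by id.

## Transcriptional-unit assembly

Junctions are aggregated inter-block gaps of spliced reads, keyed by
(contig, donor, acceptor, strand), and require ≥ 2 supporting reads
(filtering alignment noise). For an intergenic candidate, junctions within
±10 kb are considered; among those whose intron strictly contains the
candidate, the best-supported (then smallest) one hosts it. Exons grow
from the splice sites through non-zero total-RNA coverage, hopping across
further compatible junctions (chain capped at 10 exons per side); inner
exon edges are junction-defined and exact, outer edges are
coverage-defined and therefore soft (flagged `soft_edge` in the output
GFF3). A full flow-decomposition transcript assembler is intentionally out
of scope: the question is whether a containing intron is evidenced at all,
and a single best chain answers it.

## Synthetic data generator

The generator emulates the structure of a size-selected (50–200 nt insert)
experiment over one ~200 kb contig: 8 four-exon genes (exons 250–350 nt,
introns 1.2–2 kb, random strand); 30 planted snoRNAs (10 C/D, 10 H/ACA,
10 scaRNA — half of the scaRNAs C/D-flavoured, half H/ACA-flavoured), 24
intronic (≥30 nt from intron boundaries) and 6 intergenic (≥1 kb from any
gene), 4 of the intergenic inside unannotated two-exon transcripts; 10
decoy loci; 2 annotated "known" sncRNAs and 2 repeat regions to exercise
the exclusion rules. Planted sequences are built to satisfy the class
definitions (boxes placed per canonical architecture: C box at position 5,
D box in the last 10 nt, complementary 5-nt terminal stems; hairpin–H
box–hairpin–ACA–3 nt tail; CAB box in an engineered apical loop) and are
rejection-sampled so no sequence accidentally satisfies the *other*
class's signature — the truth table must be recoverable by independent
motif oracles at 100%.

Depths are negative binomial (mean 60, dispersion 8; variance
μ + μ²/disp), redrawn above 20 reads for real loci and capped at ≤ 19 for
decoys — the generator enforces the threshold semantics the caller is
tested against. Read ends jitter within ±5 nt of the locus boundaries with
a peaked distribution (60% of reads capture the exact terminus,
`end_precision`), reflecting how mature ends of processed RNAs dominate
real pileups; lengths clip to the insert range. Background reads scatter
over gene exons. Total-RNA evidence for each planted TU comprises reads
tiling both exons (inner ends flush with the splice sites, outer ends
jittered) plus 6 spliced junction reads.

Expression matrices: one latent standard-normal vector per host gene;
each paired candidate is drawn conditionally (z_c = r·z_h + √(1−r²)·ε) so
every pair carries its target correlation even when several snoRNAs share
one host; log-abundances (mean 5, sd 1, natural log scale) are
exponentiated and rounded to counts. The default target r = 0.31 for all
pairs; the per-pair list is configurable. With 12 samples the sample r is
noisy (sd ≈ 0.27 at r ≈ 0.3), so recovery is asserted on means over many
replicates, not single draws.

What the generator does **not** model — and hence what passing tests do
not show about real data: sequencing errors and quality values, PCR
duplicates, multi-mapping reads, expression-level variation between loci
beyond the NB depth model, overlapping genes, alternative splicing of
host transcripts, and any biological difference between samples
(proliferation vs differentiation contrasts are out of scope throughout).

## Numerical and design choices

* Determinism everywhere: one seed drives generation; the pipeline itself
  is deterministic (tie-breaks specified: modal ends resolve outward,
  junction choice by support then coordinate, homology by score/identity/
  subject id, candidate ids by coordinate order). Identical config + seed
  ⇒ byte-identical outputs, asserted in the tests.
* Problem sizes in the test and acceptance runs (30 planted loci, ~2,000
  reads medium + ~1,000 total-RNA, 2,000 Monte-Carlo replicates for
  correlation recovery, oracle suites of 50–5,000 instances) were chosen
  so the whole suite completes in well under a minute each while keeping
  Monte-Carlo standard errors comfortably inside the asserted bands.
* The pooled-samples interpretation of the 20-read rule is the default
  (per-sample mode available); the rule's boundary (19 → nothing, 20 →
  candidate) is asserted explicitly.
* `run_all` refuses to overwrite an existing result directory without
  `force`, and leaves a `FAILED` marker naming the stage on error.

## Known limitations

* Maximum base pairing over-predicts structure on random sequence; the
  cascade's specificity rests on the boxes, so motif-free snoRNA-like
  structures are invisible to it.
* Terminal refinement assumes a dominant mature end; loci with
  heterogeneous 5′/3′ processing would keep envelope boundaries and may
  fail the exact-offset ACA rule.
* The seeded homology search can miss a diverged homolog with no exact
  11-mer in common (as any seeded search can); lowering k trades speed for
  sensitivity.
* TU outer exon boundaries are only as good as total-RNA coverage; weakly
  expressed host transcripts yield truncated outer exons (soft edges).
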