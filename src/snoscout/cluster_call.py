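"""Candidate calling: read clusters of at least ``min_reads`` distinct reads
in intronic or intergenic space.

A cluster is a maximal run of non-zero pileup depth (runs separated by at
most ``merge_gap`` uncovered positions are merged); its read count is the
number of distinct reads overlapping the run.  The 20-read default follows
the discovery rule of the underlying protocol; it counts reads, not per-base
depth (a per-base mode is available via ``min_depth``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import AlignedRead, FeatureRecord, GenomicInterval


@dataclass
class Candidate:
    candidate_id: str
    interval: GenomicInterval
    read_count: int
    max_depth: int
    context: str                     # intronic | intergenic
    sequence: str | None = None
    sno_class: object | None = None  # SnoClassCall
    homology: object | None = None   # HomologyHit
    host_gene_id: str | None = None


def pileup(reads: Sequence[AlignedRead], region: GenomicInterval) -> np.ndarray:
    """Per-base depth over ``region``: depth[i] = number of reads with an
    aligned block covering region.start + i.  Difference-array accumulation,
    O(reads + region length)."""
    n = len(region)
    diff = np.zeros(n + 1, dtype=np.int64)
    for read in reads:
        if read.contig != region.contig:
            continue
        for b in read.blocks:
            s = max(b.start, region.start) - region.start
            e = min(b.end, region.end) - region.start
            if e > s:
                diff[s] += 1
                diff[e] -= 1
    return np.cumsum(diff[:-1])


def call_clusters(
    reads: Sequence[AlignedRead],
    assignments: Mapping[str, str],
    introns: Sequence[FeatureRecord] = (),
    min_reads: int = 20,
    merge_gap: int = 0,
    min_length: int = 50,
    min_depth: int | None = None,
    refine_ends: bool = True,
) -> list[Candidate]:
    """Call candidates from reads pre-filtered to intronic (iR) or intergenic
    (IR) labels.

    ``assignments`` maps read_id -> label and must contain every read; any
    label other than iR/IR raises (the caller performs the feature filter).
    ``min_depth`` switches to the per-base-depth interpretation of the
    cluster rule instead of the distinct-read count.  ``refine_ends`` trims
    each cluster to the modal member-read termini (read-end consensus, the
    usual way mature ends of processed RNAs are called from a pileup);
    disable it to keep the raw min-start/max-end envelope.
    """
    for read in reads:
        label = assignments.get(read.read_id)
        if label not in ("iR", "IR"):
            raise ValueError(
                f"read {read.read_id} labeled {label!r}; call_clusters accepts "
                "only iR/IR reads — pre-filter the input"
            )
    intron_ivs = [f.interval for f in introns if f.feature_class == "iR"]

    by_contig: dict[str, list[AlignedRead]] = {}
    for read in reads:
        by_contig.setdefault(read.contig, []).append(read)

    candidates: list[Candidate] = []
    for contig in sorted(by_contig):
        creads = by_contig[contig]
        lo = min(r.start for r in creads)
        hi = max(r.end for r in creads)
        region = GenomicInterval(contig, lo, hi)
        depth = pileup(creads, region)
        runs = _covered_runs(depth, merge_gap)
        for run_s, run_e in runs:
            s, e = run_s + lo, run_e + lo
            # membership and boundaries are block-level: a spliced read joins a
            # cluster only through blocks that actually cover it
            members = []
            blocks = []
            for r in creads:
                over = [b for b in r.blocks if b.start < e and b.end > s]
                if over:
                    members.append(r)
                    blocks.extend(over)
            if min_depth is not None:
                support = int(depth[run_s:run_e].max(initial=0))
                if support < min_depth:
                    continue
            elif len(members) < min_reads:
                continue
            cs = min(b.start for b in blocks)
            ce = max(b.end for b in blocks)
            if refine_ends:
                # processed-RNA termini: most reads of a mature locus share its
                # exact 5'/3' ends, so the modal block ends define the
                # candidate more faithfully than the ragged min/max envelope
                cs2 = _modal(Counter(b.start for b in blocks), prefer=min)
                ce2 = _modal(Counter(b.end for b in blocks), prefer=max)
                if ce2 - cs2 >= min_length:
                    cs, ce = cs2, ce2
            if ce - cs < min_length:
                continue
            iv = GenomicInterval(contig, cs, ce, _majority_strand(members))
            context = "intronic" if any(i.contains(iv) for i in intron_ivs) else "intergenic"
            candidates.append(
                Candidate(
                    candidate_id="",  # numbered below, in coordinate order
                    interval=iv,
                    read_count=len(members),
                    max_depth=int(depth[run_s:run_e].max(initial=0)),
                    context=context,
                )
            )
    candidates.sort(key=lambda c: (c.interval.contig, c.interval.start, c.interval.end))
    for i, c in enumerate(candidates, start=1):
        c.candidate_id = f"cand_{i}"
    return candidates


def _modal(counts: Counter, prefer) -> int:
    """Most frequent value; ties resolved outward (min for starts, max for
    ends) so refinement never invents an interior boundary."""
    top = max(counts.values())
    return prefer(v for v, n in counts.items() if n == top)


def _covered_runs(depth: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    covered = depth > 0
    if not covered.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], covered, [False])).astype(np.int8)))
    runs = list(zip(edges[::2], edges[1::2]))
    if merge_gap <= 0:
        return [(int(s), int(e)) for s, e in runs]
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(int(s), int(e)) for s, e in merged]


def _majority_strand(reads: Sequence[AlignedRead]) -> str:
    counts = Counter(r.strand for r in reads if r.strand in "+-")
    if not counts:
        return "."
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return "."
    return top[0][0]


def extract_sequences(candidates: Sequence[Candidate], genome: Mapping[str, str]) -> list[Candidate]:
    """Fill candidate sequences from the genome: substring of the interval,
    reverse-complemented on the minus strand, T->U normalized."""
    from .io import reverse_complement

    for c in candidates:
        iv = c.interval
        contig_seq = genome.get(iv.contig)
        if contig_seq is None or iv.end > len(contig_seq):
            raise ValueError(f"candidate {c.candidate_id}: interval outside genome bounds")
        seq = contig_seq[iv.start:iv.end].upper()
        if iv.strand == "-":
            seq = reverse_complement(seq)
        c.sequence = seq.replace("T", "U")
    return list(candidates)


def size_statistics(candidates: Sequence[Candidate]) -> dict[str, float]:
    """Mean/median/min/max of candidate lengths (median of an even count is
    the mean of the central pair)."""
    if not candidates:
        raise ValueError("size_statistics requires at least one candidate")
    lengths = np.array([len(c.interval) for c in candidates], dtype=float)
    return {
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "min": float(lengths.min()),
        "max": float(lengths.max()),
    }
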