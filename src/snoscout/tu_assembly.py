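"""Transcriptional-unit reconstruction around intergenic candidates.

Intergenic snoRNAs are frequently the only visible part of a weakly
expressed, unannotated host transcript.  From spliced total-RNA alignments
this module aggregates splice junctions, and for each intergenic candidate
looks for a junction whose intron strictly contains it; exons are then grown
from coverage abutting the splice sites and extended through compatible
junctions.  A candidate with a reconstructed unit is reclassified as hosted
by a novel transcript; the rest stay "autonomous or unknown".

This is deliberately a single-best-chain assembler, not a full transcript
assembler: the question it answers is whether a containing intron is
evidenced at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster_call import Candidate, pileup
from .io import AlignedRead, GenomicInterval

HOSTED = "intron_hosted_novel_TU"
AUTONOMOUS = "autonomous_or_unknown"


@dataclass(frozen=True)
class Junction:
    contig: str
    donor: int      # first intronic base (0-based)
    acceptor: int   # exclusive end of the intron
    strand: str
    support: int

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError("junction donor must precede acceptor")


@dataclass
class TranscriptionalUnit:
    tu_id: str
    exons: list[GenomicInterval]
    hosted_candidate_id: str
    hosting_intron_index: int
    min_junction_support: int
    soft_edges: tuple[bool, bool] = (True, True)  # outer ends are coverage-defined

    def __post_init__(self) -> None:
        if len(self.exons) < 2:
            raise ValueError("a transcriptional unit needs at least 2 exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError("exons overlap or are unsorted")


def extract_junctions(reads: Sequence[AlignedRead], min_support: int = 2) -> list[Junction]:
    """Aggregate the inter-block gaps of spliced reads into junctions;
    observations below ``min_support`` are dropped."""
    counts: dict[tuple[str, int, int, str], int] = {}
    for read in reads:
        for a, b in zip(read.blocks, read.blocks[1:]):
            key = (read.contig, a.end, b.start, read.strand)
            counts[key] = counts.get(key, 0) + 1
    juncs = [
        Junction(contig, donor, acceptor, strand, n)
        for (contig, donor, acceptor, strand), n in counts.items()
        if n >= min_support
    ]
    juncs.sort(key=lambda j: (j.contig, j.donor, j.acceptor, j.strand))
    return juncs


class CoverageTrack:
    """Lazy per-contig total-RNA coverage, queried by position."""

    def __init__(self, reads: Sequence[AlignedRead]):
        self._by_contig: dict[str, list[AlignedRead]] = {}
        for r in reads:
            self._by_contig.setdefault(r.contig, []).append(r)
        self._cache: dict[str, tuple[int, np.ndarray]] = {}

    def _track(self, contig: str) -> tuple[int, np.ndarray]:
        if contig not in self._cache:
            reads = self._by_contig.get(contig, [])
            if not reads:
                self._cache[contig] = (0, np.zeros(0, dtype=np.int64))
            else:
                lo = min(r.start for r in reads)
                hi = max(r.end for r in reads)
                self._cache[contig] = (lo, pileup(reads, GenomicInterval(contig, lo, hi)))
        return self._cache[contig]

    def depth(self, contig: str, pos: int) -> int:
        lo, track = self._track(contig)
        i = pos - lo
        if i < 0 or i >= len(track):
            return 0
        return int(track[i])


def _grow_left(cov: CoverageTrack, contig: str, end: int,
               donors: Mapping[int, Junction]) -> tuple[int, Junction | None]:
    """Walk left from ``end`` while covered; stop at a coverage gap or when an
    upstream junction's acceptor abuts the walk (returning that junction)."""
    pos = end
    while pos > 0 and cov.depth(contig, pos - 1) > 0:
        pos -= 1
        if pos in donors:
            return pos, donors[pos]
    return pos, None


def _grow_right(cov: CoverageTrack, contig: str, start: int,
                acceptors: Mapping[int, Junction]) -> tuple[int, Junction | None]:
    pos = start
    while cov.depth(contig, pos) > 0:
        pos += 1
        if pos in acceptors:
            return pos, acceptors[pos]
    return pos, None


def assemble_tu(
    candidate: Candidate,
    junctions: Sequence[Junction],
    coverage: CoverageTrack,
    window: int = 10_000,
    max_chain: int = 10,
) -> TranscriptionalUnit | None:
    """Best exon chain around one intergenic candidate, or None.

    Hosting junctions (intron strictly containing the candidate) are ranked
    by (support, smallest intron); exons grow outward from its splice sites
    through coverage, hopping across further compatible junctions.  Fully
    deterministic: every tie-break is by support, then coordinate.
    """
    if candidate.context != "intergenic":
        raise ValueError(f"candidate {candidate.candidate_id} is not intergenic")
    iv = candidate.interval
    near = [
        j for j in junctions
        if j.contig == iv.contig
        and iv.start - window <= j.donor and j.acceptor <= iv.end + window
    ]
    hosting = sorted(
        (j for j in near if j.donor < iv.start and iv.end < j.acceptor),
        key=lambda j: (-j.support, j.acceptor - j.donor, j.donor),
    )
    if not hosting:
        return None
    host = hosting[0]
    # junction lookup tables for chain extension (best support per site)
    by_acceptor: dict[int, Junction] = {}
    by_donor: dict[int, Junction] = {}
    for j in near:
        if j.acceptor not in by_acceptor or j.support > by_acceptor[j.acceptor].support:
            by_acceptor[j.acceptor] = j
        if j.donor not in by_donor or j.support > by_donor[j.donor].support:
            by_donor[j.donor] = j

    exons_left: list[GenomicInterval] = []
    supports = [host.support]
    # leftward: exon ends at the hosting donor
    end = host.donor
    for _ in range(max_chain):
        start, hop = _grow_left(coverage, iv.contig, end, {j.acceptor: j for j in near if j.acceptor < end})
        if start >= end:
            break
        exons_left.append(GenomicInterval(iv.contig, start, end, iv.strand))
        if hop is None:
            break
        supports.append(hop.support)
        end = hop.donor
    exons_right: list[GenomicInterval] = []
    start = host.acceptor
    for _ in range(max_chain):
        end, hop = _grow_right(coverage, iv.contig, start, {j.donor: j for j in near if j.donor > start})
        if end <= start:
            break
        exons_right.append(GenomicInterval(iv.contig, start, end, iv.strand))
        if hop is None:
            break
        supports.append(hop.support)
        start = hop.acceptor
    if not exons_left or not exons_right:
        return None
    exons = list(reversed(exons_left)) + exons_right
    return TranscriptionalUnit(
        tu_id=f"TU_{candidate.candidate_id}",
        exons=exons,
        hosted_candidate_id=candidate.candidate_id,
        hosting_intron_index=len(exons_left) - 1,
        min_junction_support=min(supports),
    )


def classify_intergenic(
    candidates: Sequence[Candidate],
    tus: Mapping[str, TranscriptionalUnit | None],
) -> pd.DataFrame:
    """Partition intergenic candidates by whether a hosting TU was assembled;
    the two groups always sum to the input count."""
    rows = []
    for c in candidates:
        tu = tus.get(c.candidate_id)
        rows.append({
            "candidate_id": c.candidate_id,
            "classification": HOSTED if tu is not None else AUTONOMOUS,
            "tu_id": tu.tu_id if tu is not None else "",
        })
    return pd.DataFrame(rows, columns=["candidate_id", "classification", "tu_id"])


def write_tu_gff3(tus: Sequence[TranscriptionalUnit], path) -> None:
    lines = ["##gff-version 3"]
    for tu in tus:
        c = tu.exons[0].contig
        strand = tu.exons[0].strand if tu.exons[0].strand != "." else "+"
        lines.append(
            f"{c}\t snoscout\tgene\t{tu.exons[0].start + 1}\t{tu.exons[-1].end}\t.\t"
            f"{strand}\t.\tID={tu.tu_id};hosted_candidate={tu.hosted_candidate_id};"
            f"min_junction_support={tu.min_junction_support}".replace("\t ", "\t")
        )
        for i, ex in enumerate(tu.exons):
            soft = (i == 0 and tu.soft_edges[0]) or (i == len(tu.exons) - 1 and tu.soft_edges[1])
            lines.append(
                f"{c}\tsnoscout\texon\t{ex.start + 1}\t{ex.end}\t.\t{strand}\t.\t"
                f"ID={tu.tu_id}.e{i + 1};Parent={tu.tu_id};soft_edge={'true' if soft else 'false'}"
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
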