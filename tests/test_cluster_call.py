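"""Cluster calling against brute-force pileup/clustering oracles, and the
at-least-20-reads boundary semantics."""

from __future__ import annotations

import numpy as np
import pytest

from snoscout.cluster_call import (
    call_clusters,
    extract_sequences,
    pileup,
    size_statistics,
)
from snoscout.cluster_call import Candidate
from snoscout.io import AlignedRead, FeatureRecord, GenomicInterval


def _read(i, s, e, contig="c1", strand="+", sample="S"):
    return AlignedRead(f"r{i}", sample, [GenomicInterval(contig, s, e, strand)])


def _stack(n, s, e, start_id=0):
    return [_read(start_id + i, s, e) for i in range(n)]


def brute_force_pileup(reads, region):
    depth = np.zeros(len(region), dtype=int)
    for i, pos in enumerate(range(region.start, region.end)):
        for r in reads:
            if r.contig == region.contig and any(b.start <= pos < b.end for b in r.blocks):
                depth[i] += 1
    return depth


def brute_force_clusters(reads, min_reads):
    """O(n^2) connected components under covered-run connectivity: blocks
    that overlap or abut (no uncovered base between them) join a component,
    matching the maximal-runs-of-depth>=1 cluster definition; components
    with >= min_reads survive."""
    by_contig = {}
    for r in reads:
        by_contig.setdefault(r.contig, []).append(r)
    out = []
    for contig, rs in by_contig.items():
        parent = list(range(len(rs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(rs)):
            for j in range(i + 1, len(rs)):
                for bi in rs[i].blocks:
                    for bj in rs[j].blocks:
                        if bi.start <= bj.end and bj.start <= bi.end:
                            parent[find(i)] = find(j)
        comps = {}
        for i in range(len(rs)):
            comps.setdefault(find(i), []).append(rs[i])
        for members in comps.values():
            if len(members) >= min_reads:
                s = min(b.start for r in members for b in r.blocks)
                e = max(b.end for r in members for b in r.blocks)
                out.append((contig, s, e, len(members)))
    return sorted(out)


class TestPileup:
    def test_no_reads_all_zero(self):
        region = GenomicInterval("c1", 0, 100)
        assert pileup([], region).sum() == 0

    def test_stacked_reads(self):
        region = GenomicInterval("c1", 50, 200)
        depth = pileup(_stack(20, 100, 160), region)
        assert (depth[50:110] == 20).all()
        assert depth[:50].sum() == 0 and depth[110:].sum() == 0

    def test_matches_positional_counting_oracle(self):
        rng = np.random.default_rng(9)
        reads = []
        for i in range(500):
            s = int(rng.integers(0, 900))
            blocks = [GenomicInterval("c1", s, s + int(rng.integers(10, 80)))]
            if rng.random() < 0.3:
                g = blocks[0].end + int(rng.integers(5, 50))
                blocks.append(GenomicInterval("c1", g, g + 30))
            reads.append(AlignedRead(f"r{i}", "S", blocks))
        region = GenomicInterval("c1", 0, 1100)
        assert (pileup(reads, region) == brute_force_pileup(reads, region)).all()


class TestCallClusters:
    def _labels(self, reads, label="IR"):
        return {r.read_id: label for r in reads}

    def test_nineteen_reads_is_no_candidate(self):
        reads = _stack(19, 100, 160)
        assert call_clusters(reads, self._labels(reads)) == []

    def test_twenty_reads_is_one_candidate(self):
        reads = _stack(20, 100, 160)
        (cand,) = call_clusters(reads, self._labels(reads))
        assert cand.read_count == 20
        assert (cand.interval.start, cand.interval.end) == (100, 160)

    def test_rejects_unfiltered_labels(self):
        reads = _stack(20, 100, 160)
        labels = self._labels(reads)
        labels["r0"] = "ER"
        with pytest.raises(ValueError, match="pre-filter"):
            call_clusters(reads, labels)

    def test_intronic_context_from_intron_record(self):
        reads = _stack(25, 100, 170)
        intron = FeatureRecord(GenomicInterval("c1", 0, 1000), "iR", gene_id="g")
        (cand,) = call_clusters(reads, self._labels(reads, "iR"), introns=[intron])
        assert cand.context == "intronic"
        (cand2,) = call_clusters(reads, self._labels(reads))
        assert cand2.context == "intergenic"

    def test_merge_gap_bridges_uncovered_run(self):
        reads = _stack(15, 100, 160) + _stack(15, 170, 230, start_id=100)
        labels = self._labels(reads)
        assert call_clusters(reads, labels, min_reads=20) == []
        (cand,) = call_clusters(reads, labels, min_reads=20, merge_gap=10)
        assert cand.read_count == 30
        assert (cand.interval.start, cand.interval.end) == (100, 230)

    def test_matches_brute_force_components(self):
        """Candidate set equals an O(n^2) connected-components oracle over
        100 random read sets (merge_gap=0, envelope boundaries)."""
        rng = np.random.default_rng(31)
        for trial in range(100):
            reads = []
            for i in range(int(rng.integers(10, 80))):
                s = int(rng.integers(0, 2000))
                reads.append(_read(i, s, s + int(rng.integers(50, 120))))
            min_reads = int(rng.integers(2, 8))
            got = call_clusters(
                reads, self._labels(reads), min_reads=min_reads,
                min_length=1, refine_ends=False,
            )
            got_tuples = sorted(
                (c.interval.contig, c.interval.start, c.interval.end, c.read_count)
                for c in got
            )
            assert got_tuples == brute_force_clusters(reads, min_reads), f"trial {trial}"

    def test_candidates_never_overlap(self):
        rng = np.random.default_rng(12)
        starts = rng.integers(0, 3000, size=400)
        reads = [_read(i, int(s), int(s) + int(rng.integers(20, 120))) for i, s in enumerate(starts)]
        cands = call_clusters(reads, self._labels(reads), min_reads=5, min_length=1)
        for a, b in zip(cands, cands[1:]):
            assert a.interval.end <= b.interval.start

    def test_end_refinement_recovers_modal_termini(self):
        # 12 reads at the exact locus, 4 ragged ones: the modal ends win
        reads = _stack(12, 100, 180)
        reads += [_read(100 + i, 100 - i - 1, 180 + i + 1) for i in range(4)]
        (cand,) = call_clusters(reads, self._labels(reads), min_reads=10)
        assert (cand.interval.start, cand.interval.end) == (100, 180)
        (env,) = call_clusters(reads, self._labels(reads), min_reads=10, refine_ends=False)
        assert (env.interval.start, env.interval.end) == (96, 184)


class TestExtractSequences:
    def test_plus_strand_t_to_u(self):
        c = Candidate("cand_1", GenomicInterval("g", 0, 4, "+"), 20, 20, "intergenic")
        extract_sequences([c], {"g": "ACGTAAAA"})
        assert c.sequence == "ACGU"

    def test_minus_strand_reverse_complement(self):
        # revcomp("ACGT") = "ACGT" -> "ACGU" after T->U
        c = Candidate("cand_1", GenomicInterval("g", 0, 4, "-"), 20, 20, "intergenic")
        extract_sequences([c], {"g": "ACGTAAAA"})
        assert c.sequence == "ACGU"
        c2 = Candidate("cand_2", GenomicInterval("g", 0, 5, "-"), 20, 20, "intergenic")
        extract_sequences([c2], {"g": "AACGTTTT"})
        assert c2.sequence == "ACGUU"

    def test_out_of_bounds_names_candidate(self):
        c = Candidate("cand_9", GenomicInterval("g", 0, 50, "+"), 20, 20, "intergenic")
        with pytest.raises(ValueError, match="cand_9"):
            extract_sequences([c], {"g": "ACGT"})

    def test_interval_flush_with_contig_end(self):
        c = Candidate("cand_1", GenomicInterval("g", 4, 8, "+"), 20, 20, "intergenic")
        extract_sequences([c], {"g": "AAAACGTA"})
        assert c.sequence == "CGUA"


class TestSizeStatistics:
    def _cands(self, lengths):
        return [
            Candidate(f"c{i}", GenomicInterval("g", 0, n), 20, 20, "intergenic")
            for i, n in enumerate(lengths)
        ]

    def test_single_length(self):
        stats = size_statistics(self._cands([100]))
        assert stats == {"mean": 100, "median": 100, "min": 100, "max": 100}

    def test_reported_extremes_and_median(self):
        stats = size_statistics(self._cands([52, 126, 772]))
        assert (stats["min"], stats["median"], stats["max"]) == (52, 126, 772)

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(8)
        lengths = rng.integers(50, 800, size=1001)
        stats = size_statistics(self._cands(lengths))
        srt = sorted(lengths)
        assert stats["median"] == srt[500]
        assert stats["mean"] == pytest.approx(sum(lengths) / 1001)
        assert (stats["min"], stats["max"]) == (srt[0], srt[-1])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            size_statistics([])
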