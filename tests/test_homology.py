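"""Seeded local alignment against Biopython's PairwiseAligner as the
independent scoring oracle."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align

from snoscout.homology import assign_family, build_kmer_index, local_align
from snoscout.io import reverse_complement


def oracle_score(a, b):
    """Independent affine-gap local alignment score (gap of length L costs
    -5 - 2L, matching the package's convention)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    try:
        return int(aligner.score(a, b))
    except ValueError:
        return 0


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng, seq, rate):
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([c for c in "ACGT" if c != ch]))
        else:
            out.append(ch)
    return "".join(out)


def substitute_one(rng, seq):
    i = int(rng.integers(len(seq)))
    return seq[:i] + rng.choice([c for c in "ACGT" if c != seq[i]]) + seq[i + 1:]


class TestLocalAlign:
    def test_identical_sequences(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 50)
        score, span, identity = local_align(seq, seq)
        assert score == 100 and identity == 1.0
        assert span == (0, 50, 0, 50)

    def test_unrelated_polyA(self):
        score, _, _ = local_align("GCGCGCGCGC", "A" * 30)
        assert score == 0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            a, b = random_dna(rng, 40), random_dna(rng, 40)
            assert local_align(a, b)[0] == local_align(b, a)[0]

    def test_matches_independent_dp_oracle(self):
        """200 random pairs up to 30 nt: optimal scores equal Biopython's
        affine-gap local aligner."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = random_dna(rng, int(rng.integers(5, 31)))
            b = random_dna(rng, int(rng.integers(5, 31)))
            if rng.random() < 0.5:  # include related pairs, not only noise
                b = mutate(rng, a, 0.2)
            assert local_align(a, b)[0] == oracle_score(a, b), (a, b)

    def test_gap_cost_convention(self):
        # 18 matches around one 2-nt deletion: 36 + open(-5) + 2*extend(-4)
        a = "ACGGTTCAAGCTTACGGATC"
        b = a[:10] + a[12:]
        score, _, _ = local_align(a, b)
        assert score == 36 - 5 - 4


class TestKmerIndex:
    def test_single_kmer_reference(self):
        idx = build_kmer_index({"s1": ("ACGTACGTACG", "s1 family=snoRNA")}, k=11)
        fwd = [p for ps in idx.postings.values() for p in ps if p[2] == "+"]
        assert len(fwd) == 1

    def test_posting_count_is_length_minus_k_plus_one(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 73)
        idx = build_kmer_index({"s1": (seq, "")}, k=11)
        fwd = [p for ps in idx.postings.values() for p in ps if p[2] == "+"]
        assert len(fwd) == 73 - 11 + 1

    def test_postings_match_naive_enumeration(self):
        rng = np.random.default_rng(5)
        refs = {f"s{i}": (random_dna(rng, int(rng.integers(20, 60))), "")
                for i in range(10)}
        k = 8
        idx = build_kmer_index(refs, k=k)
        naive = {}
        for sid, (seq, _) in refs.items():
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                for i in range(len(s) - k + 1):
                    naive.setdefault(s[i : i + k], []).append((sid, i, strand))
        assert {k_: sorted(v) for k_, v in idx.postings.items()} == {
            k_: sorted(v) for k_, v in naive.items()
        }

    def test_duplicate_reference_ids_rejected(self, tmp_path):
        from snoscout.io import read_fasta_with_descriptions

        fa = tmp_path / "dup.fa"
        fa.write_text(">s1 family=snoRNA\nACGTACGTACGT\n>s1 family=tRNA\nTTTTACGTACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            build_kmer_index(read_fasta_with_descriptions(fa))


class TestAssignFamily:
    def _refs(self, rng, n=6):
        fams = ("miRNA", "snRNA", "snoRNA", "tRNA")
        return {
            f"ref{i}": (random_dna(rng, int(rng.integers(70, 120))),
                        f"ref{i} family={fams[i % 4]}")
            for i in range(n)
        }

    def test_exact_copy_recovers_subject(self):
        rng = np.random.default_rng(6)
        refs = self._refs(rng)
        idx = build_kmer_index(refs)
        hit = assign_family("q", refs["ref2"][0], idx)
        assert hit is not None
        assert hit.subject_id == "ref2" and hit.identity == 1.0
        assert hit.subject_family == "snoRNA"

    def test_shuffled_query_has_no_hit(self):
        rng = np.random.default_rng(7)
        refs = self._refs(rng)
        idx = build_kmer_index(refs)
        q = list(refs["ref0"][0])
        rng.shuffle(q)
        assert assign_family("q", "".join(q), idx) is None

    def test_reverse_complement_query_found_on_minus(self):
        rng = np.random.default_rng(8)
        refs = self._refs(rng)
        idx = build_kmer_index(refs)
        hit = assign_family("q", reverse_complement(refs["ref1"][0]), idx)
        assert hit is not None and hit.subject_id == "ref1" and hit.strand == "-"

    def test_mutated_copies_recovered(self):
        """Queries with 10% substitutions recover the right subject in
        >= 95% of 200 seeded replicates."""
        rng = np.random.default_rng(9)
        refs = self._refs(rng, n=8)
        idx = build_kmer_index(refs)
        ok = 0
        for rep in range(200):
            sid = f"ref{rep % 8}"
            q = mutate(rng, refs[sid][0], 0.10)
            hit = assign_family(f"q{rep}", q, idx, min_identity=0.8)
            ok += hit is not None and hit.subject_id == sid
        assert ok >= 190

    def test_seeded_search_equals_all_pairs_sw(self):
        """On short references (<= 30 nt) the seeded result agrees with an
        exhaustive all-pairs Smith-Waterman whenever a seed must exist
        (one substitution in >= 15 nt guarantees an exact 7-mer)."""
        rng = np.random.default_rng(10)
        for trial in range(30):
            refs = {
                f"r{i}": (random_dna(rng, int(rng.integers(15, 31))), f"r{i} family=other")
                for i in range(6)
            }
            idx = build_kmer_index(refs, k=7)
            base = refs[f"r{trial % 6}"][0]
            query = substitute_one(rng, base)
            got = assign_family("q", query, idx, min_identity=0.8, min_coverage=0.5)
            # oracle: align against every subject on both strands
            best = None
            for sid, (sseq, _) in sorted(refs.items()):
                for strand, s in (("+", sseq), ("-", reverse_complement(sseq))):
                    score, (qs, qe, _, _), ident = local_align(query, s)
                    cov = (qe - qs) / len(query)
                    if ident >= 0.8 and cov >= 0.5:
                        key = (score, ident, sid)
                        if best is None or key > best[0]:
                            best = (key, sid)
            if best is None:
                assert got is None
            else:
                assert got is not None and got.subject_id == best[1]
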