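"""Homology assignment against a known-sncRNA reference set.

A self-contained k-mer-seeded Smith–Waterman search stands in for BLAST:
candidate k-mers are looked up in a two-strand seed index, the most
seed-rich subjects are aligned with affine-gap local alignment, and the best
hit passing identity/coverage thresholds is reported.  Reference FASTA
description lines carry the family as ``family=<tag>``.

Scoring defaults (+2/−3, gap open −5, extend −2) mirror common nucleotide
search parameters; a gap of length L costs gap_open + L·gap_extend.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import reverse_complement

FAMILIES = ("miRNA", "snRNA", "snoRNA", "tRNA", "other")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    subject_family: str
    identity: float
    query_coverage: float
    alignment_score: int
    strand: str


@dataclass
class KmerIndex:
    k: int
    subjects: dict[str, tuple[str, str]]      # id -> (sequence DNA-normalized, family)
    postings: dict[str, list[tuple[str, int, str]]]  # kmer -> [(subject, offset, strand)]


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def build_kmer_index(references: dict[str, tuple[str, str]], k: int = 11) -> KmerIndex:
    """Index reference sequences by k-mer on both strands.

    ``references`` maps subject id -> (sequence, description); the family tag
    is parsed from the description (``family=<tag>``, default "other").
    """
    subjects: dict[str, tuple[str, str]] = {}
    postings: dict[str, list[tuple[str, int, str]]] = {}
    for sid, (seq, desc) in references.items():
        if sid in subjects:
            raise ValueError(f"duplicate subject id {sid!r}")
        family = "other"
        for token in desc.split():
            if token.startswith("family="):
                family = token.split("=", 1)[1]
        seq = _norm(seq)
        subjects[sid] = (seq, family)
        rc = reverse_complement(seq)
        for strand, s in (("+", seq), ("-", rc)):
            for i in range(len(s) - k + 1):
                postings.setdefault(s[i : i + k], []).append((sid, i, strand))
    return KmerIndex(k=k, subjects=subjects, postings=postings)


def local_align(
    query: str,
    subject: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> tuple[int, tuple[int, int, int, int], float]:
    """Affine-gap Smith–Waterman.

    Returns (score, (q_start, q_end, s_start, s_end), identity) for one
    optimal local alignment; identity = matches / alignment columns.
    Gotoh three-matrix recursion, O(|query|·|subject|).
    """
    q = _norm(query)
    s = _norm(subject)
    n, m = len(q), len(s)
    if n == 0 or m == 0:
        raise ValueError("local_align requires non-empty sequences")
    NEG = float("-inf")
    H = [[0] * (m + 1) for _ in range(n + 1)]   # best ending at (i, j)
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (subject consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject
    ptr: dict[tuple[int, int, str], tuple[int, int, str]] = {}
    best, best_pos = 0, (0, 0)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i][j - 1] + gap_open + gap_extend
            e_ext = E[i][j - 1] + gap_extend
            E[i][j] = max(e_open, e_ext)
            ptr[(i, j, "E")] = (i, j - 1, "H" if e_open >= e_ext else "E")
            f_open = H[i - 1][j] + gap_open + gap_extend
            f_ext = F[i - 1][j] + gap_extend
            F[i][j] = max(f_open, f_ext)
            ptr[(i, j, "F")] = (i - 1, j, "H" if f_open >= f_ext else "F")
            diag = H[i - 1][j - 1] + (match if qi == s[j - 1] else mismatch)
            h = max(0, diag, E[i][j], F[i][j])
            H[i][j] = h
            if h > 0:
                if h == diag:
                    ptr[(i, j, "H")] = (i - 1, j - 1, "H")
                elif h == E[i][j]:
                    ptr[(i, j, "H")] = (i, j, "E")
                else:
                    ptr[(i, j, "H")] = (i, j, "F")
            if h > best:
                best, best_pos = h, (i, j)
    if best == 0:
        return 0, (0, 0, 0, 0), 0.0
    # traceback for span and identity
    i, j = best_pos
    state = "H"
    q_end, s_end = i, j
    matches = columns = 0
    while H[i][j] > 0 or state != "H":
        pi, pj, pstate = ptr[(i, j, state)]
        if state == "H" and pstate == "H" and (pi, pj) == (i - 1, j - 1):
            columns += 1
            if q[i - 1] == s[j - 1]:
                matches += 1
        elif state in ("E", "F") and (pi != i or pj != j):
            columns += 1
        i, j, state = pi, pj, pstate
        if state == "H" and H[i][j] == 0:
            break
    q_start, s_start = i, j
    identity = matches / columns if columns else 0.0
    return best, (q_start, q_end, s_start, s_end), identity


def assign_family(
    query_id: str,
    query_seq: str,
    index: KmerIndex,
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
    top_n: int = 10,
    **align_params,
) -> HomologyHit | None:
    """Best reference hit for one candidate, or None.

    Subjects are ranked by shared seed count per strand; the ``top_n`` are
    aligned in full.  Ties break by (score, identity, subject id)."""
    q = _norm(query_seq)
    k = index.k
    seed_counts: dict[tuple[str, str], int] = {}
    for i in range(len(q) - k + 1):
        for sid, _off, strand in index.postings.get(q[i : i + k], ()):
            seed_counts[(sid, strand)] = seed_counts.get((sid, strand), 0) + 1
    ranked = sorted(seed_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    best: HomologyHit | None = None
    for (sid, strand), _count in ranked:
        subject, family = index.subjects[sid]
        if strand == "-":
            subject = reverse_complement(subject)
        score, (qs, qe, _ss, _se), identity = local_align(q, subject, **align_params)
        coverage = (qe - qs) / len(q)
        if identity < min_identity or coverage < min_coverage:
            continue
        hit = HomologyHit(query_id, sid, family, identity, coverage, score, strand)
        if best is None or (hit.alignment_score, hit.identity, hit.subject_id) > (
            best.alignment_score, best.identity, best.subject_id
        ):
            best = hit
    return best
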