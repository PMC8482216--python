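"""Rule-based snoRNA classification from box motifs and secondary structure.

Candidates are labelled as C/D box snoRNAs, H/ACA box snoRNAs, scaRNAs
(including the tandem H/ACA–C/D architecture) or ``unknown`` using a
transparent cascade over the canonical box consensi:

* C box ``RUGAUGA`` near the 5' end and D box ``CUGA`` near the 3' end,
  supported by a terminal stem bringing the two termini together;
* H box ``ANANNA`` in the single-stranded hinge between two hairpins and an
  ``ACA`` triplet a fixed offset from the 3' end;
* scaRNAs additionally carry a CAB box in a hairpin apical loop.

Structure evidence is maximum nested base pairing (Nussinov dynamic
programming) over bounded windows; no thermodynamic model is used.  All
thresholds live in :class:`ClassifierParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

C_BOX = "RUGAUGA"
D_BOX = "CUGA"
H_BOX = "ANANNA"
ACA_BOX = "ACA"
DEFAULT_CAB_BOX = "UGAG"

_CAN_PAIR = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})
MIN_LOOP = 3  # unpaired bases required inside a hairpin loop


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CAN_PAIR


@dataclass(frozen=True)
class BoxHit:
    box: str                # C, D, Cprime, Dprime, H, ACA, CAB
    position: int           # 0-based offset of the match in the candidate
    matched: str
    mismatches: int


@dataclass
class SnoClassCall:
    label: str = "unknown"  # CD, HACA, SCA_HACA, SCA_CD, SCA_TANDEM, unknown
    box_hits: list[BoxHit] = field(default_factory=list)
    structure_score: float = 0.0
    confidence: float = 0.0


@dataclass
class ClassifierParams:
    """Thresholds of the classification cascade.

    Window sizes are in nt from the relevant terminus; mismatch budgets
    follow the convention that the degenerate C and H boxes tolerate one
    mismatch while the short D/ACA/CAB boxes must be exact.
    """

    c_window: int = 12
    d_window: int = 12
    max_mm_c: int = 1
    max_mm_d: int = 0
    max_mm_h: int = 1
    max_mm_aca: int = 0
    max_mm_cab: int = 0
    aca_offset: int = 3           # nt between the ACA box end and the 3' end
    hinge_lo: float = 0.30        # H-box search window, fractions of length
    hinge_hi: float = 0.80
    terminal_arm: int = 15        # nt from each terminus folded for the stem
    stem_norm: int = 7            # max pairs achievable in the stem window
    min_stem_score: float = 0.5
    min_hairpin_pairs: int = 5    # per H/ACA hairpin domain
    min_hairpin_len: int = 12
    cab_motif: str = DEFAULT_CAB_BOX
    cab_min_stem: int = 6         # complementary pairs closing the CAB loop
    cab_loop_margin: int = 3      # loop bases allowed on each side of the box
    max_len: int = 400
    min_len: int = 50
    w_box: float = 0.5
    w_struct: float = 0.5


# ---------------------------------------------------------------------------
# motif scanning


def _check_motif(seq: str, pos: int, motif: str) -> int:
    mm = 0
    for k, code in enumerate(motif):
        if seq[pos + k] not in IUPAC[code]:
            mm += 1
    return mm


def scan_motif(
    seq: str,
    motif: str,
    window: tuple[int, int] | None = None,
    max_mismatch: int = 0,
    box: str = "",
) -> list[BoxHit]:
    """All matches of an IUPAC motif within ``window`` (0-based half-open,
    bounding the whole match), sorted by (mismatches, position)."""
    for code in motif:
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} in motif {motif!r}")
    seq = seq.upper().replace("T", "U")
    lo, hi = window if window is not None else (0, len(seq))
    lo = max(lo, 0)
    hi = min(hi, len(seq))
    hits = []
    for pos in range(lo, hi - len(motif) + 1):
        mm = _check_motif(seq, pos, motif)
        if mm <= max_mismatch:
            hits.append(BoxHit(box or motif, pos, seq[pos : pos + len(motif)], mm))
    hits.sort(key=lambda h: (h.mismatches, h.position))
    return hits


# ---------------------------------------------------------------------------
# maximum base pairing (Nussinov)


def fold_maxpairs(seq: str) -> tuple[int, str]:
    """Maximum number of nested AU/GC/GU pairs with loop size >= 3, plus one
    optimal structure in dot-bracket notation.

    O(n^3) dynamic programming; intended for bounded windows (terminal stems,
    hairpin domains), not whole transcripts.
    """
    s = seq.upper().replace("T", "U")
    n = len(s)
    if n < 4:
        raise ValueError("sequence shorter than 4 nt cannot fold")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    M = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i][j - 1]  # j unpaired
            for k in range(i, j - MIN_LOOP):
                if can_pair(s[k], s[j]):
                    left = M[i][k - 1] if k > i else 0
                    inner = M[k + 1][j - 1]
                    cand = left + inner + 1
                    if cand > best:
                        best = cand
            M[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or M[i][j] == 0:
            continue
        if M[i][j] == M[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - MIN_LOOP):
            if can_pair(s[k], s[j]):
                left = M[i][k - 1] if k > i else 0
                if left + M[k + 1][j - 1] + 1 == M[i][j]:
                    structure[k] = "("
                    structure[j] = ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return M[0][n - 1], "".join(structure)


def max_possible_pairs(n: int) -> int:
    """Upper bound on nested pairs for an n-nt window given the loop minimum."""
    return max(0, (n - MIN_LOOP) // 2)


# ---------------------------------------------------------------------------
# classification cascade


def _terminal_stem_score(seq: str, p: ClassifierParams) -> float:
    arm = p.terminal_arm
    if len(seq) < 2 * arm:
        arm = len(seq) // 2
    window = seq[:arm] + seq[-arm:]
    if len(window) < 4:
        return 0.0
    pairs, _ = fold_maxpairs(window)
    return min(pairs / p.stem_norm, 1.0)


def _check_cd(seq: str, p: ClassifierParams) -> tuple[bool, list[BoxHit], float]:
    c_hits = scan_motif(seq, C_BOX, (0, p.c_window), p.max_mm_c, box="C")
    if not c_hits:
        return False, [], 0.0
    d_hits = scan_motif(seq, D_BOX, (len(seq) - p.d_window, len(seq)), p.max_mm_d, box="D")
    if not d_hits:
        return False, [], 0.0
    stem = _terminal_stem_score(seq, p)
    if stem < p.min_stem_score:
        return False, [], stem
    return True, [c_hits[0], d_hits[-1]], stem


def _check_haca(seq: str, p: ClassifierParams) -> tuple[bool, list[BoxHit], float]:
    n = len(seq)
    tail = n - p.aca_offset
    if tail - 3 < 0 or seq[tail - 3 : tail].replace("T", "U") != ACA_BOX:
        if p.max_mm_aca == 0:
            return False, [], 0.0
    aca_hit = BoxHit("ACA", tail - 3, seq[tail - 3 : tail], 0)
    lo, hi = int(p.hinge_lo * n), int(p.hinge_hi * n)
    h_hits = scan_motif(seq, H_BOX, (lo, hi), p.max_mm_h, box="H")
    for h in h_hits:
        left = seq[: h.position]
        right = seq[h.position + len(H_BOX) : tail - 3]
        if len(left) < p.min_hairpin_len or len(right) < p.min_hairpin_len:
            continue
        lp, _ = fold_maxpairs(left)
        if lp < p.min_hairpin_pairs:
            continue
        rp, _ = fold_maxpairs(right)
        if rp < p.min_hairpin_pairs:
            continue
        frac = (
            min(lp / max_possible_pairs(len(left)), 1.0)
            + min(rp / max_possible_pairs(len(right)), 1.0)
        ) / 2
        return True, [h, aca_hit], frac
    return False, [], 0.0


def _find_cab(seq: str, p: ClassifierParams) -> BoxHit | None:
    """A CAB box counts only when it sits in a hairpin apical loop: an
    antiparallel run of >= ``cab_min_stem`` complementary pairs must close a
    small loop containing the hit.

    The stem is checked by direct complementarity rather than by inspecting
    one optimal fold: maximum-pairing structures are highly degenerate (GU
    wobble), so whether the reported optimum leaves the loop unpaired is an
    arbitrary tie-break, while the existence of a closing stem is not.
    """
    m = len(p.cab_motif)
    for hit in scan_motif(seq, p.cab_motif, None, p.max_mm_cab, box="CAB"):
        pos = hit.position
        for a in range(0, p.cab_loop_margin + 1):      # loop bases left of the box
            for b in range(0, p.cab_loop_margin + 1):  # and right of it
                run = 0
                while True:
                    i = pos - 1 - a - run
                    j = pos + m + b + run
                    if i < 0 or j >= len(seq) or not can_pair(seq[i], seq[j]):
                        break
                    run += 1
                if run >= p.cab_min_stem:
                    return hit
    return None


def classify_candidate(seq: str, params: ClassifierParams | None = None) -> SnoClassCall:
    """Classify one candidate sequence.

    Degenerate inputs (too short/long, non-ACGU characters) yield ``unknown``
    rather than raising: upstream cluster calling does not guarantee clean
    sequence content.
    """
    p = params or ClassifierParams()
    seq = (seq or "").upper().replace("T", "U")
    if not (p.min_len <= len(seq) <= p.max_len) or set(seq) - set("ACGU"):
        return SnoClassCall()

    cd_ok, cd_hits, cd_struct = _check_cd(seq, p)
    haca_ok, haca_hits, haca_struct = _check_haca(seq, p)
    if not cd_ok and not haca_ok:
        return SnoClassCall()

    def _conf(hits: list[BoxHit], struct: float) -> float:
        quality = sum(1 - h.mismatches / len(h.matched) for h in hits) / len(hits)
        return p.w_box * quality + p.w_struct * struct

    cab = _find_cab(seq, p) if (cd_ok or haca_ok) else None

    if cd_ok and haca_ok:
        if cab is not None:
            hits = cd_hits + haca_hits + [cab]
            struct = (cd_struct + haca_struct) / 2
            return SnoClassCall("SCA_TANDEM", hits, struct, _conf(hits, struct))
        cd_conf = _conf(cd_hits, cd_struct)
        haca_conf = _conf(haca_hits, haca_struct)
        log.info("candidate passes both C/D and H/ACA cascades without a CAB box; "
                 "reporting the higher-confidence class")
        if cd_conf >= haca_conf:
            return SnoClassCall("CD", cd_hits, cd_struct, cd_conf)
        return SnoClassCall("HACA", haca_hits, haca_struct, haca_conf)
    if cd_ok:
        hits = cd_hits + ([cab] if cab else [])
        label = "SCA_CD" if cab else "CD"
        return SnoClassCall(label, hits, cd_struct, _conf(hits, cd_struct))
    hits = haca_hits + ([cab] if cab else [])
    label = "SCA_HACA" if cab else "HACA"
    return SnoClassCall(label, hits, haca_struct, _conf(hits, haca_struct))
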