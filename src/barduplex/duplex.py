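"""Duplex assembly: matching opposite-strand SSCS and building duplex consensus.

Two single-strand consensus sequences are traced back to one parental
double-stranded molecule when they share fragment coordinates, carry
opposite strand tags, and their barcodes agree at the positions adjacent
to the ligation sites.  Annealing artifacts concentrate in the *outer*
barcode positions, so only the terminal six nucleotides of each barcode
(6 + 6 = 12 for the 12-nt design) form the duplex key; up to two key
mismatches are tolerated.  Random coordinate collisions are flagged as
spurious via the full combined-UID distance, which for unrelated
molecules sits near half the UID length.

Because the two strands of a molecule present the barcode halves in
swapped order, the minus-strand key and UID are half-swapped before
comparison so true partners line up position by position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .adapter import hamming
from .consensus import SSCSRecord


def swapped_uid(sscs: SSCSRecord) -> str:
    """Combined UID with halves in plus-strand order."""
    if sscs.orientation == "minus":
        return sscs.uid.barcode_3p + sscs.uid.barcode_5p
    return sscs.uid.combined


def duplex_key(sscs: SSCSRecord, key_len: int = 6) -> str:
    """Ligation-adjacent barcode positions (last *key_len* of each half),
    in plus-strand half order."""
    if sscs.orientation == "minus":
        h1, h2 = sscs.uid.barcode_3p, sscs.uid.barcode_5p
    else:
        h1, h2 = sscs.uid.barcode_5p, sscs.uid.barcode_3p
    return h1[-key_len:] + h2[-key_len:]


def _key_distance(key_a: str, key_b: str, key_len: int, per_block: bool) -> int:
    if per_block:
        return max(hamming(key_a[:key_len], key_b[:key_len]),
                   hamming(key_a[key_len:], key_b[key_len:]))
    return hamming(key_a, key_b)


@dataclass
class DuplexRecord:
    sscs_plus: SSCSRecord
    sscs_minus: SSCSRecord
    key_mismatches: int
    full_uid_mismatches: int
    sequence: str  # duplex consensus; 'N' where the strands disagree
    ambiguous: frozenset[int]
    mispairing_positions: tuple[int, ...]  # 0-based over the combined UID

    @property
    def locus(self) -> str:
        return self.sscs_plus.locus

    @property
    def start(self) -> int:
        return self.sscs_plus.start

    @property
    def end(self) -> int:
        return self.sscs_plus.end

    @property
    def trim_n(self) -> int:
        return max(self.sscs_plus.trim_n, self.sscs_minus.trim_n)


def build_duplex_consensus(plus: SSCSRecord, minus: SSCSRecord,
                           key_len: int = 6) -> DuplexRecord:
    """Combine two strand consensuses: agreement keeps the base, any
    disagreement (including a one-strand ambiguity) becomes 'N'.

    Ambiguous positions carry no variant support and are excluded from
    error counts, which is what cancels strand-specific damage.
    """
    if (plus.locus, plus.start, plus.end) != (minus.locus, minus.start, minus.end):
        raise ValueError("duplex partners must share fragment coordinates")
    seq = []
    ambiguous = set()
    for i, (a, b) in enumerate(zip(plus.sequence, minus.sequence)):
        if a == b and a not in "N-":
            seq.append(a)
        else:
            seq.append("N")
            ambiguous.add(i)
    uid_p, uid_m = plus.uid.combined, swapped_uid(minus)
    mispairs = tuple(i for i, (a, b) in enumerate(zip(uid_p, uid_m)) if a != b)
    return DuplexRecord(
        sscs_plus=plus,
        sscs_minus=minus,
        key_mismatches=hamming(duplex_key(plus, key_len), duplex_key(minus, key_len)),
        full_uid_mismatches=len(mispairs),
        sequence="".join(seq),
        ambiguous=frozenset(ambiguous),
        mispairing_positions=mispairs,
    )


def resolve_key_clash(
    candidates: Sequence[tuple[SSCSRecord, int, int]],
) -> SSCSRecord | None:
    """Pick one partner among (sscs, key_distance, full_uid_distance) triples.

    Ties on key distance fall back to the minimal full-UID distance; an
    exact tie on both is left unresolved (``None``) — conservatively, no
    pairing beats a guessed one.
    """
    if not candidates:
        return None
    ranked = sorted(candidates, key=lambda c: (c[1], c[2], c[0].uid.combined))
    if len(ranked) > 1 and ranked[0][1:3] == ranked[1][1:3]:
        return None
    return ranked[0][0]


@dataclass
class MatchResult:
    duplexes: list[DuplexRecord]
    unpaired_plus: list[SSCSRecord]
    unpaired_minus: list[SSCSRecord]
    spurious: list[tuple[SSCSRecord, SSCSRecord, int]]  # (plus, minus, full_uid_dist)


def match_duplexes(
    sscs_records: Sequence[SSCSRecord],
    max_key_mismatches: int = 2,
    spurious_threshold: int = 5,
    key_len: int = 6,
    per_block: bool = False,
) -> MatchResult:
    """Greedy minimum-distance duplex matching within coordinate buckets.

    Candidate plus/minus pairs within a (locus, start, end) bucket are
    ranked by duplex-key Hamming distance, then full-UID distance; pairs
    above *max_key_mismatches* are never considered, pairs whose full-UID
    distance exceeds *spurious_threshold* are flagged as spurious
    coordinate collisions, and exact ties are left unpaired.  Each SSCS
    joins at most one duplex; results are independent of input order.
    SSCS with unknown orientation are never matched.
    """
    buckets: dict[tuple, dict[str, list[SSCSRecord]]] = {}
    unpaired_unknown: list[SSCSRecord] = []
    for rec in sscs_records:
        if rec.orientation not in ("plus", "minus"):
            unpaired_unknown.append(rec)
            continue
        b = buckets.setdefault((rec.locus, rec.start, rec.end),
                               {"plus": [], "minus": []})
        b[rec.orientation].append(rec)
    duplexes: list[DuplexRecord] = []
    unpaired_plus: list[SSCSRecord] = []
    unpaired_minus: list[SSCSRecord] = []
    spurious: list[tuple[SSCSRecord, SSCSRecord, int]] = []
    for key in sorted(buckets):
        plus = sorted(buckets[key]["plus"], key=lambda r: r.uid.combined)
        minus = sorted(buckets[key]["minus"], key=lambda r: r.uid.combined)
        candidates = []  # (key_dist, full_dist, i, j)
        for i, p in enumerate(plus):
            kp, up = duplex_key(p, key_len), swapped_uid(p)
            for j, m in enumerate(minus):
                kd = _key_distance(kp, duplex_key(m, key_len), key_len, per_block)
                if kd <= max_key_mismatches:
                    candidates.append((kd, hamming(up, swapped_uid(m)), i, j))
        real, seen_spurious = [], []
        for kd, fd, i, j in candidates:
            (seen_spurious if fd > spurious_threshold else real).append((kd, fd, i, j))
        used_p: set[int] = set()
        used_m: set[int] = set()
        blocked_p: set[int] = set()
        blocked_m: set[int] = set()
        # process candidates in ascending (key, full) groups; exact ties
        # contested by one SSCS block it (conservative: no match on a clash)
        groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for kd, fd, i, j in real:
            groups.setdefault((kd, fd), []).append((i, j))
        for dist in sorted(groups):
            live = [(i, j) for i, j in groups[dist]
                    if i not in used_p | blocked_p and j not in used_m | blocked_m]
            count_i: dict[int, int] = {}
            count_j: dict[int, int] = {}
            for i, j in live:
                count_i[i] = count_i.get(i, 0) + 1
                count_j[j] = count_j.get(j, 0) + 1
            for i, j in live:
                if count_i[i] > 1:
                    blocked_p.add(i)
                if count_j[j] > 1:
                    blocked_m.add(j)
            for i, j in live:
                if (i in used_p | blocked_p) or (j in used_m | blocked_m):
                    continue
                duplexes.append(build_duplex_consensus(plus[i], minus[j], key_len))
                used_p.add(i)
                used_m.add(j)
        for kd, fd, i, j in seen_spurious:
            if i not in used_p and j not in used_m:
                spurious.append((plus[i], minus[j], fd))
        unpaired_plus.extend(p for i, p in enumerate(plus) if i not in used_p)
        unpaired_minus.extend(m for j, m in enumerate(minus) if j not in used_m)
    # unknown-orientation SSCS are excluded from duplexing altogether
    return MatchResult(duplexes, unpaired_plus, unpaired_minus, spurious)


@dataclass(frozen=True)
class DuplexRecoveryStats:
    n_fwd: int
    n_rev: int
    n_duplexes: int
    unique_molecules: int
    recovery_rate: float


def duplex_recovery(n_fwd: int, n_rev: int, d: int) -> DuplexRecoveryStats:
    """Duplex recovery accounting.

    With *n_fwd* forward-strand and *n_rev* reverse-strand consensus
    sequences of which *d* pairs assemble into duplexes, the unique
    molecule count is (n_fwd - d) + (n_rev - d) + d and the recovery rate
    is d over that total (e.g. 1,000 + 1,000 with 600 duplexes -> 1,400
    unique molecules, rate 0.4286).
    """
    if min(n_fwd, n_rev, d) < 0:
        raise ValueError("counts must be non-negative")
    if d > min(n_fwd, n_rev):
        raise ValueError(f"d={d} exceeds min(n_fwd, n_rev)={min(n_fwd, n_rev)}")
    unique = (n_fwd - d) + (n_rev - d) + d
    rate = d / unique if unique else 0.0
    return DuplexRecoveryStats(n_fwd, n_rev, d, unique, rate)


@dataclass
class MispairingProfile:
    per_position_frequency: list[float]  # over the combined UID positions
    histogram_full: dict[int, int]  # mispairs per duplex, all positions
    histogram_terminal: dict[int, int]  # mispairs within the duplex key
    n_duplexes: int


def mispairing_profile(duplexes: Sequence[DuplexRecord],
                       key_len: int = 6) -> MispairingProfile:
    """Annealing-mispair landscape over accepted duplexes.

    A mispairing is any position where the canonicalised plus and minus
    barcodes of a duplex disagree; counts are reported per position over
    the combined UID and as per-duplex histograms over all positions and
    over the terminal (ligation-adjacent) key positions.
    """
    if not duplexes:
        return MispairingProfile([], {}, {}, 0)
    uid_len = len(duplexes[0].sscs_plus.uid)
    half = uid_len // 2
    terminal = set(range(half - key_len, half)) | set(range(uid_len - key_len, uid_len))
    counts = np.zeros(uid_len, dtype=float)
    hist_full: dict[int, int] = {}
    hist_term: dict[int, int] = {}
    for dup in duplexes:
        positions = dup.mispairing_positions
        for p in positions:
            counts[p] += 1
        n_term = sum(1 for p in positions if p in terminal)
        hist_full[len(positions)] = hist_full.get(len(positions), 0) + 1
        hist_term[n_term] = hist_term.get(n_term, 0) + 1
    return MispairingProfile(
        per_position_frequency=list(counts / len(duplexes)),
        histogram_full=hist_full,
        histogram_terminal=hist_term,
        n_duplexes=len(duplexes),
    )
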