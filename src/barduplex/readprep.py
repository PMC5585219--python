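"""Read-pair merging, tag/barcode extraction and ligation-site soft-trim.

Reads from a barcoded library carry, at each end in sequencing
orientation, a tri-nucleotide strand tag, a semi-degenerate barcode and a
T overhang before the insert begins (the 3' end presents the mirror image
and is parsed after reverse complementation).  Merging the overlapping
mates reconstructs the full tagged fragment, after which both barcodes
are canonicalised to the plus-oligo pattern orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .adapter import AdapterSpec, UID, revcomp


@dataclass
class MergedRead:
    name: str
    sequence: str
    qualities: str  # phred33
    uid: UID | None = None
    tag_pair: tuple[str, str] | None = None
    orientation: str = "unknown"  # plus | minus | unknown
    insert: str | None = None
    insert_start_offset: int = 0
    trim_n: int = 0  # ligation-adjacent insert bases masked at each end


def merge_pair(
    r1: tuple[str, str],
    r2: tuple[str, str],
    min_overlap: int = 30,
    max_mismatch_frac: float = 0.1,
    name: str = "",
) -> MergedRead | None:
    """Merge two mates via their best ungapped 3' overlap.

    Scans every suffix(R1)/prefix(revcomp(R2)) overlap of length >=
    *min_overlap*; the overlap with the lowest mismatch fraction wins
    (ties go to the longest).  Disagreeing columns take the higher-quality
    base, with R1 winning quality ties.  Returns ``None`` when no overlap
    satisfies *max_mismatch_frac*.
    """
    seq1, qual1 = r1
    seq2, qual2 = r2
    if not seq1 or not seq2:
        return None
    rc2 = revcomp(seq2)
    q2r = qual2[::-1]
    a1 = np.frombuffer(seq1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(rc2.encode(), dtype=np.uint8)
    best: tuple[float, int] | None = None  # (mismatch_frac, overlap)
    for o in range(min(len(seq1), len(rc2)), min_overlap - 1, -1):
        mm = int((a1[len(seq1) - o:] != a2[:o]).sum())
        if mm <= max_mismatch_frac * o:
            frac = mm / o
            if best is None or frac < best[0]:
                best = (frac, o)
                if mm == 0:  # cannot be beaten; longest zero-mismatch overlap
                    break
    if best is None:
        return None
    o = best[1]
    head_len = len(seq1) - o
    seq = list(seq1[:head_len])
    qual = list(qual1[:head_len])
    for k in range(o):
        b1, b2 = seq1[head_len + k], rc2[k]
        c1, c2 = qual1[head_len + k], q2r[k]
        if b1 == b2:
            seq.append(b1)
            qual.append(max(c1, c2))
        elif c2 > c1:
            seq.append(b2)
            qual.append(c2)
        else:
            seq.append(b1)  # R1 wins ties
            qual.append(c1)
    seq.extend(rc2[o:])
    qual.extend(q2r[o:])
    return MergedRead(name=name, sequence="".join(seq), qualities="".join(qual))


def _parse_end_block(block: str, adapter: AdapterSpec) -> tuple[str, str]:
    """(tag, barcode) from one canonical end block (overhang base ignored)."""
    t, b = adapter.tag_length, adapter.barcode_length
    if adapter.tag_position == "before_barcode":
        return block[:t], block[t:t + b]
    return block[b:b + t], block[:b]


def extract_tags(merged: MergedRead, adapter: AdapterSpec) -> tuple[MergedRead | None, str | None]:
    """Slice and validate both end blocks; returns (read, None) or (None, reason).

    The 5' block is read directly; the 3' block is parsed after reverse
    complementation, so both stored barcodes are canonical (plus-pattern
    orientation).  Reads whose barcodes violate the pattern are rejected
    with reason ``"barcode_pattern"``; too-short reads with ``"short"``.
    """
    block = adapter.end_block_length
    if len(merged.sequence) < 2 * block + 1:
        return None, "short"
    end5 = merged.sequence[:block]
    end3 = revcomp(merged.sequence[-block:])
    tag5, bc5 = _parse_end_block(end5, adapter)
    tag3, bc3 = _parse_end_block(end3, adapter)
    if not (adapter.plus_pattern.matches(bc5) and adapter.plus_pattern.matches(bc3)):
        return None, "barcode_pattern"
    out = replace(
        merged,
        uid=UID(bc5, bc3),
        tag_pair=(tag5, tag3),
        insert=merged.sequence[block:len(merged.sequence) - block],
        insert_start_offset=block,
    )
    return out, None


def assign_orientation(tag_pair: tuple[str, str],
                       tag_table: Sequence[tuple[str, str]]) -> str:
    """Strand of origin from the observed (5', 3') tag pair.

    A pair matching a permitted (plus_tag, minus_tag) combination reads as
    the plus strand; the swapped reading as the minus strand; anything
    else is unknown (excluded from duplexing, optionally kept for ssDNA
    analyses).
    """
    table = set(map(tuple, tag_table))
    if tuple(tag_pair) in table:
        return "plus"
    if (tag_pair[1], tag_pair[0]) in table:
        return "minus"
    return "unknown"


def soft_trim_ligation(merged: MergedRead, n: int = 2) -> MergedRead:
    """Mask the first and last *n* insert bases for error accounting.

    End-repair artifacts concentrate in the ligation-adjacent bases, so
    those positions are excluded from error-rate denominators and variant
    calls without being removed from the alignment.
    """
    if n < 0:
        raise ValueError("trim length must be >= 0")
    return replace(merged, trim_n=n)


def prepare_pairs(
    pairs: Iterable[tuple[str, str, str, str, str, str]],
    adapter: AdapterSpec,
    min_overlap: int = 30,
    max_mismatch_frac: float = 0.1,
    trim_n: int = 2,
) -> tuple[list[MergedRead], list[tuple[str, str]]]:
    """Merge, extract, orient and soft-trim a stream of read pairs.

    *pairs* yields (name, comment, r1_seq, r1_qual, r2_seq, r2_qual).
    Every input pair ends in exactly one of: the merged output list or the
    reject list with a reason (``unmerged``, ``short``,
    ``barcode_pattern``).
    """
    merged_out: list[MergedRead] = []
    rejects: list[tuple[str, str]] = []
    for name, _comment, s1, q1, s2, q2 in pairs:
        m = merge_pair((s1, q1), (s2, q2), min_overlap, max_mismatch_frac, name=name)
        if m is None:
            rejects.append((name, "unmerged"))
            continue
        m, reason = extract_tags(m, adapter)
        if m is None:
            rejects.append((name, reason))
            continue
        m.orientation = assign_orientation(m.tag_pair, adapter.tag_table)
        merged_out.append(soft_trim_ligation(m, trim_n))
    return merged_out, rejects
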