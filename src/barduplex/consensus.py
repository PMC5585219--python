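"""Alignment to the target reference, PCR-family grouping and SSCS calling.

A PCR family is the set of reads descending from one parental strand of
one original molecule: same locus, strand orientation and fragment
coordinates, and UIDs within a small mismatch tolerance of each other
(PCR and sequencing errors occasionally hit the barcode itself).  The
single-strand consensus sequence (SSCS) of a family with at least three
reads keeps the plurality base per column; exact ties become 'N' and are
excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .adapter import UID, hamming, revcomp
from .readprep import MergedRead


@dataclass
class AlignedRead:
    name: str
    locus: str
    start: int  # 0-based half-open fragment coordinates on the locus
    end: int
    sequence: str  # insert in reference orientation ('-' marks no coverage)
    orientation: str  # parental strand from the tags: plus | minus | unknown
    uid: UID
    tag_pair: tuple[str, str]
    nm: int  # alignment edit distance
    merged_length: int  # tagged read length (insert + both end blocks)
    trim_n: int = 0


def align_to_reference(
    merged_reads: Sequence[MergedRead],
    reference: dict[str, str],
    max_edit_frac: float = 0.05,
) -> tuple[list[AlignedRead], list[tuple[str, str]]]:
    """Glocal (infix) alignment of each insert against every locus and strand.

    The best-scoring placement wins (deterministic tie-break by locus name,
    forward strand first); inserts whose edit distance exceeds
    *max_edit_frac* of their length are rejected as off-target.  Sequences
    are stored in reference orientation.
    """
    if not reference:
        raise ValueError("empty reference")
    loci = sorted(reference.items())
    aligned: list[AlignedRead] = []
    rejects: list[tuple[str, str]] = []
    for m in merged_reads:
        if m.insert is None or m.uid is None:
            raise ValueError(f"read {m.name!r} has no extracted insert/UID")
        best = None  # (nm, locus_idx, strand_idx, start, end)
        for li, (locus, seq) in enumerate(loci):
            for si, query in enumerate((m.insert, revcomp(m.insert))):
                res = edlib.align(query, seq, mode="HW", task="locations")
                nm = res["editDistance"]
                if nm >= 0 and (best is None or nm < best[0]):
                    s, e = res["locations"][0]
                    best = (nm, li, si, s, e + 1)
        if best is None or best[0] > max_edit_frac * len(m.insert):
            rejects.append((m.name, "off_target"))
            continue
        nm, li, si, start, end = best
        seq = m.insert if si == 0 else revcomp(m.insert)
        aligned.append(AlignedRead(
            name=m.name,
            locus=loci[li][0],
            start=start,
            end=end,
            sequence=seq,
            orientation=m.orientation,
            uid=m.uid,
            tag_pair=m.tag_pair,
            nm=nm,
            merged_length=len(m.sequence),
            trim_n=m.trim_n,
        ))
    return aligned, rejects


@dataclass
class PCRFamily:
    family_id: int
    locus: str
    orientation: str
    start: int
    end: int
    members: list[AlignedRead]
    uid: UID  # per-column plurality over member UIDs

    @property
    def size(self) -> int:
        return len(self.members)


def _consensus_string(strings: Sequence[str], skip: str = "-") -> tuple[str, set[int]]:
    """Column-wise plurality; exact ties -> 'N'; *skip* characters excluded.

    Returns the consensus and the set of ambiguous ('N') columns.  Columns
    where no string has coverage come out as '-'.
    """
    length = len(strings[0])
    out = []
    ambiguous: set[int] = set()
    for col in range(length):
        counts: dict[str, int] = {}
        for s in strings:
            c = s[col]
            if c in skip:
                continue
            counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("-")
            continue
        top = max(counts.values())
        winners = sorted(c for c, n in counts.items() if n == top)
        if len(winners) > 1 or winners[0] == "N":
            out.append("N")
            ambiguous.add(col)
        else:
            out.append(winners[0])
    return "".join(out), ambiguous


def _plurality_uid(uids: Sequence[UID]) -> UID:
    # UIDs never carry ambiguity codes; plurality ties break alphabetically.
    def col_consensus(strings):
        out = []
        for col in range(len(strings[0])):
            counts: dict[str, int] = {}
            for s in strings:
                counts[s[col]] = counts.get(s[col], 0) + 1
            top = max(counts.values())
            out.append(min(c for c, n in counts.items() if n == top))
        return "".join(out)

    return UID(col_consensus([u.barcode_5p for u in uids]),
               col_consensus([u.barcode_3p for u in uids]))


def brute_force_single_linkage(uids: Sequence[str], threshold: int) -> list[int]:
    """Reference clustering: full pairwise matrix + transitive closure.

    Returns a cluster label per input, labelled by first occurrence.  Used
    as the oracle that the production grouping must agree with.
    """
    n = len(uids)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if hamming(uids[i], uids[j]) <= threshold:
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    labels = []
    for i in range(n):
        r = find(i)
        labels.append(roots.setdefault(r, len(roots)))
    return labels


def _incremental_single_linkage(uids: Sequence[str], threshold: int) -> list[int]:
    """Single-linkage by incremental insertion with cluster merging.

    Each sequence joins every existing cluster holding a member within
    *threshold* mismatches; multiple hits merge those clusters.  Yields the
    same partition as the full-pairwise-matrix closure.
    """
    clusters: list[list[int]] = []  # member indices
    for i, u in enumerate(uids):
        hits = [ci for ci, cluster in enumerate(clusters)
                if any(hamming(u, uids[j]) <= threshold for j in cluster)]
        if not hits:
            clusters.append([i])
        else:
            keep = clusters[hits[0]]
            keep.append(i)
            for ci in reversed(hits[1:]):
                keep.extend(clusters.pop(ci))
    labels = [0] * len(uids)
    order = sorted(range(len(clusters)), key=lambda ci: min(clusters[ci]))
    for lab, ci in enumerate(order):
        for j in clusters[ci]:
            labels[j] = lab
    return labels


def group_families(
    aligned: Sequence[AlignedRead],
    mismatch_frac: float = 0.01,
) -> list[PCRFamily]:
    """Partition aligned reads into PCR families.

    Reads are bucketed by (locus, orientation, fragment start, fragment
    end); within a bucket, single-linkage clustering on the combined UID
    with threshold ``max(1, floor(mismatch_frac * tagged read length))``
    mismatches — the 1%-of-read-length rule applied to barcode plus
    insert.  Deterministic: buckets and members ordered by coordinates
    then UID.
    """
    buckets: dict[tuple, list[AlignedRead]] = {}
    for read in aligned:
        buckets.setdefault((read.locus, read.orientation, read.start, read.end),
                           []).append(read)
    families: list[PCRFamily] = []
    fid = 0
    for key in sorted(buckets):
        locus, orientation, start, end = key
        members = sorted(buckets[key], key=lambda r: (r.uid.combined, r.name))
        threshold = max(1, int(mismatch_frac * members[0].merged_length))
        labels = _incremental_single_linkage([r.uid.combined for r in members], threshold)
        clusters: dict[int, list[AlignedRead]] = {}
        for read, lab in zip(members, labels):
            clusters.setdefault(lab, []).append(read)
        for lab in sorted(clusters):
            reads = clusters[lab]
            families.append(PCRFamily(
                family_id=fid,
                locus=locus,
                orientation=orientation,
                start=start,
                end=end,
                members=reads,
                uid=_plurality_uid([r.uid for r in reads]),
            ))
            fid += 1
    return families


@dataclass
class SSCSRecord:
    family_id: int
    locus: str
    orientation: str
    start: int
    end: int
    uid: UID
    sequence: str  # reference-oriented insert consensus; 'N' at ties
    n_reads: int
    ambiguous: frozenset[int] = frozenset()
    trim_n: int = 0


def build_sscs(family: PCRFamily, min_reads: int = 3) -> SSCSRecord | None:
    """Plurality consensus of one family; ``None`` below *min_reads*.

    Exact per-column ties (two variants at equal proportions) become 'N'
    and are excluded from error counts and variant support downstream; gap
    columns from reads with coverage holes are skipped per column.
    """
    if not family.members:
        raise ValueError("empty family")
    if family.size < min_reads:
        return None
    seq, ambiguous = _consensus_string([r.sequence for r in family.members])
    return SSCSRecord(
        family_id=family.family_id,
        locus=family.locus,
        orientation=family.orientation,
        start=family.start,
        end=family.end,
        uid=family.uid,
        sequence=seq,
        n_reads=family.size,
        ambiguous=frozenset(ambiguous),
        trim_n=max(r.trim_n for r in family.members),
    )


@dataclass
class FamilySizeDistribution:
    histogram: dict[int, int]  # family size -> number of families
    peak_family_size: int | None  # size >1 whose families hold the most reads
    frac_unique_coordinates: dict[str, float]  # per orientation

    @property
    def total_reads(self) -> int:
        return sum(size * count for size, count in self.histogram.items())


def family_size_stats(families: Sequence[PCRFamily]) -> FamilySizeDistribution:
    """Histogram, peak family size and coordinate-collision fraction.

    The peak is the family size >1 whose families together contain the
    highest total read count (ties go to the smaller size); the
    unique-coordinate fraction is computed per strand orientation.
    """
    histogram: dict[int, int] = {}
    for fam in families:
        histogram[fam.size] = histogram.get(fam.size, 0) + 1
    peak = None
    best_reads = -1
    for size in sorted(histogram):
        if size <= 1:
            continue
        reads = size * histogram[size]
        if reads > best_reads:
            best_reads = reads
            peak = size
    frac_unique: dict[str, float] = {}
    by_orient: dict[str, list[tuple]] = {}
    for fam in families:
        by_orient.setdefault(fam.orientation, []).append((fam.locus, fam.start, fam.end))
    for orientation, coords in by_orient.items():
        counts: dict[tuple, int] = {}
        for c in coords:
            counts[c] = counts.get(c, 0) + 1
        frac_unique[orientation] = sum(1 for c in coords if counts[c] == 1) / len(coords)
    return FamilySizeDistribution(histogram, peak, frac_unique)
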