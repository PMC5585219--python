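"""Semi-degenerate barcoded adapter models and barcode/UID statistics.

A semi-degenerate barcode restricts every position to a two-letter IUPAC
set (W, S, M, R, Y, K), so an *L*-position barcode spans exactly ``2**L``
sequences.  The shipped v2 design uses the 12-nt pattern ``WSMRWSYWKMWW``
on the plus oligo (``WWKMWRSWYKSW`` on the minus oligo, its reverse
complement) giving 4,096 barcodes per adapter and 2**24 combined unique
molecular identifiers (UIDs) per double-tagged fragment.  The legacy v1
design uses the 5-nt pattern ``WSWSW``.

Each adapter also carries a fixed tri-nucleotide strand tag; the plus and
minus oligos of one adapter carry non-complementary tags, which is what
lets downstream code tell the two parental strands of a molecule apart.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: IUPAC code -> allowed concrete bases (sorted tuples for determinism).
IUPAC_SETS: dict[str, tuple[str, ...]] = {
    "A": ("A",),
    "C": ("C",),
    "G": ("G",),
    "T": ("T",),
    "W": ("A", "T"),
    "S": ("C", "G"),
    "M": ("A", "C"),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "K": ("G", "T"),
    "N": ("A", "C", "G", "T"),
}

#: IUPAC complement table (W and S are self-complementary; M<->K, R<->Y).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "W": "W", "S": "S", "M": "K", "K": "M", "R": "Y", "Y": "R", "N": "N",
}

_DNA_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def revcomp(seq: str) -> str:
    """Reverse complement of a concrete nucleotide string (N and '-' pass through)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


class IUPACPattern:
    """An ordered list of IUPAC codes defining a barcode sequence space."""

    __slots__ = ("symbols",)

    def __init__(self, pattern: str | Sequence[str]):
        symbols = tuple(str(s).upper() for s in pattern)
        if not symbols:
            raise ValueError("empty pattern")
        for i, s in enumerate(symbols):
            if s not in IUPAC_SETS:
                raise ValueError(f"invalid IUPAC symbol {s!r} at position {i}")
        self.symbols = symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return "".join(self.symbols)

    def __repr__(self) -> str:
        return f"IUPACPattern({str(self)!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, IUPACPattern):
            return self.symbols == other.symbols
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.symbols)

    def space_size(self) -> int:
        """Cardinality of the sequence space (product of per-symbol set sizes)."""
        n = 1
        for s in self.symbols:
            n *= len(IUPAC_SETS[s])
        return n

    def enumerate(self) -> set[str]:
        """Every concrete sequence consistent with the pattern, each once."""
        return {
            "".join(bases)
            for bases in itertools.product(*(IUPAC_SETS[s] for s in self.symbols))
        }

    def matches(self, seq: str) -> bool:
        """True iff every base of *seq* lies in its position's allowed set.

        Raises ``ValueError`` on length mismatch (distinct from a False
        result) and treats ambiguity codes in *seq* as non-matching: a
        barcode read must be a concrete base at every position.
        """
        if len(seq) != len(self.symbols):
            raise ValueError(
                f"sequence length {len(seq)} != pattern length {len(self.symbols)}"
            )
        return all(base in IUPAC_SETS[sym] for base, sym in zip(seq.upper(), self.symbols))

    def revcomp(self) -> "IUPACPattern":
        """Symbol-wise IUPAC complement, order reversed (an involution)."""
        return IUPACPattern([IUPAC_COMPLEMENT[s] for s in reversed(self.symbols)])

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        weights: Sequence[Sequence[float]] | None = None,
    ) -> list[str]:
        """Draw *n* pattern-conforming barcodes.

        Degenerate positions default to uniform base usage; *weights* may
        supply one probability vector per position (same order as the
        position's allowed set) to emulate skewed machine-mixing ratios.
        """
        cols = []
        for i, sym in enumerate(self.symbols):
            bases = np.array(IUPAC_SETS[sym])
            p = None
            if weights is not None and weights[i] is not None:
                p = np.asarray(weights[i], dtype=float)
                p = p / p.sum()
            cols.append(rng.choice(bases, size=n, p=p))
        return ["".join(row) for row in zip(*cols)]


# Published designs ---------------------------------------------------------

PLUS_PATTERN_V2 = "WSMRWSYWKMWW"
MINUS_PATTERN_V2 = "WWKMWRSWYKSW"
PLUS_PATTERN_V1 = "WSWSW"

#: Default strand-tag pool: 6 plus x 4 minus tri-nucleotides chosen so that
#: exactly 19 non-complementary (plus, minus) combinations remain after
#: excluding reverse-complement and position-wise-complement pairs.
DEFAULT_PLUS_TAGS = ("CTA", "CTG", "GAT", "GTC", "TAC", "TTA")
DEFAULT_MINUS_TAGS = ("CAG", "GAA", "GAC", "TAA")


def _complementary_tags(p: str, m: str) -> bool:
    comp = "".join(IUPAC_COMPLEMENT[c] for c in p)
    return m == comp[::-1] or m == comp


def default_tag_table() -> tuple[tuple[str, str], ...]:
    """The 19 permitted (plus_tag, minus_tag) combinations of the default pool."""
    return tuple(
        (p, m)
        for p in DEFAULT_PLUS_TAGS
        for m in DEFAULT_MINUS_TAGS
        if not _complementary_tags(p, m)
    )


@dataclass(frozen=True)
class AdapterSpec:
    """Barcode patterns, strand-tag table and read layout of one adapter design.

    ``tag_position`` is ``"before_barcode"`` for the 12-nt v2 design (read
    layout per end: tag, barcode, T overhang, insert) and
    ``"after_barcode"`` for the legacy 5-nt v1 design (barcode, tag, T,
    insert).
    """

    design_version: str  # "v1_5nt" | "v2_12nt"
    plus_pattern: IUPACPattern
    minus_pattern: IUPACPattern
    tag_table: tuple[tuple[str, str], ...]
    tag_position: str  # "before_barcode" | "after_barcode"
    tag_length: int = 3
    overhang_base: str = "T"

    def __post_init__(self):
        if self.minus_pattern.revcomp() != self.plus_pattern:
            raise ValueError("minus pattern is not the reverse complement of plus pattern")
        if self.tag_position not in ("before_barcode", "after_barcode"):
            raise ValueError(f"bad tag_position {self.tag_position!r}")
        for p, m in self.tag_table:
            if len(p) != self.tag_length or len(m) != self.tag_length:
                raise ValueError(f"tag pair ({p},{m}) does not match tag_length")

    @property
    def barcode_length(self) -> int:
        return len(self.plus_pattern)

    @property
    def end_block_length(self) -> int:
        """Non-insert bases contributed per fragment end (tag + barcode + overhang)."""
        return self.tag_length + self.barcode_length + len(self.overhang_base)

    @property
    def duplex_key_length(self) -> int:
        """Barcode positions per end used for duplex matching.

        v2 uses the terminal six positions adjacent to each ligation site
        (6 + 6 = 12); v1 uses the full 5-nt barcodes (5 + 5 = 10).
        """
        return 6 if self.design_version == "v2_12nt" else self.barcode_length

    @classmethod
    def v2_default(cls, tag_table: Iterable[tuple[str, str]] | None = None) -> "AdapterSpec":
        return cls(
            design_version="v2_12nt",
            plus_pattern=IUPACPattern(PLUS_PATTERN_V2),
            minus_pattern=IUPACPattern(MINUS_PATTERN_V2),
            tag_table=tuple(tag_table) if tag_table is not None else default_tag_table(),
            tag_position="before_barcode",
        )

    @classmethod
    def v1_default(cls) -> "AdapterSpec":
        # v1 tags are the fixed complementary GAC/GTC pair; both strands of a
        # molecule present the same canonical tag pair, so v1 reads cannot be
        # strand-oriented from tags alone.
        return cls(
            design_version="v1_5nt",
            plus_pattern=IUPACPattern(PLUS_PATTERN_V1),
            minus_pattern=IUPACPattern(PLUS_PATTERN_V1).revcomp(),
            tag_table=(("GAC", "GAC"),),
            tag_position="after_barcode",
        )

    def to_dict(self) -> dict:
        return {
            "design_version": self.design_version,
            "plus_pattern": str(self.plus_pattern),
            "minus_pattern": str(self.minus_pattern),
            "tag_table": [list(t) for t in self.tag_table],
            "tag_position": self.tag_position,
            "tag_length": self.tag_length,
            "overhang_base": self.overhang_base,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdapterSpec":
        return cls(
            design_version=d["design_version"],
            plus_pattern=IUPACPattern(d["plus_pattern"]),
            minus_pattern=IUPACPattern(d["minus_pattern"]),
            tag_table=tuple(tuple(t) for t in d["tag_table"]),
            tag_position=d["tag_position"],
            tag_length=int(d.get("tag_length", 3)),
            overhang_base=d.get("overhang_base", "T"),
        )


# Convenience wrappers matching the operation-level vocabulary ---------------

def enumerate_pattern(pattern: IUPACPattern | str) -> set[str]:
    if not isinstance(pattern, IUPACPattern):
        pattern = IUPACPattern(pattern)
    return pattern.enumerate()


def matches_pattern(seq: str, pattern: IUPACPattern | str) -> bool:
    if not isinstance(pattern, IUPACPattern):
        pattern = IUPACPattern(pattern)
    return pattern.matches(seq)


def revcomp_pattern(pattern: IUPACPattern | str) -> IUPACPattern:
    if not isinstance(pattern, IUPACPattern):
        pattern = IUPACPattern(pattern)
    return pattern.revcomp()


# UID diversity --------------------------------------------------------------

@dataclass(frozen=True)
class UID:
    """A molecule's combined unique identifier: the two canonicalised barcodes."""

    barcode_5p: str
    barcode_3p: str

    @property
    def combined(self) -> str:
        return self.barcode_5p + self.barcode_3p

    def __len__(self) -> int:
        return len(self.combined)


@dataclass(frozen=True)
class UIDDiversityStats:
    n_uids: int
    n_unique: int
    frac_unique: float
    max_multiplicity: int
    mean_pairwise_distance: float
    sd_pairwise_distance: float


_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(uids: Sequence[str]) -> np.ndarray:
    arr = np.empty((len(uids), len(uids[0])), dtype=np.uint8)
    for i, u in enumerate(uids):
        try:
            arr[i] = [_BASE_CODES[c] for c in u]
        except KeyError as exc:
            raise ValueError(f"UID {u!r} contains non-ACGT symbol") from exc
    return arr


def mean_pairwise_distance(uids: Sequence[str]) -> float:
    """Exact mean Hamming distance over all unordered UID pairs.

    Uses the per-column base-count identity (pair mismatches at one column
    = (N^2 - sum n_b^2)/2), so it scales to tens of thousands of UIDs.
    """
    if len(uids) < 2:
        raise ValueError("need at least two UIDs")
    arr = _encode(uids)
    n = arr.shape[0]
    total = 0.0
    for col in range(arr.shape[1]):
        counts = np.bincount(arr[:, col], minlength=4)
        total += (n * n - np.sum(counts.astype(np.int64) ** 2)) / 2.0
    return total / (n * (n - 1) / 2.0)


def _pairwise_distances(arr: np.ndarray, max_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Hamming distances over all pairs, or a random pair subsample if too many."""
    n = arr.shape[0]
    n_pairs = n * (n - 1) // 2
    if n_pairs <= max_pairs:
        ii, jj = np.triu_indices(n, k=1)
    else:
        ii = rng.integers(0, n, size=max_pairs)
        jj = rng.integers(0, n - 1, size=max_pairs)
        jj = np.where(jj >= ii, jj + 1, jj)
    out = np.zeros(len(ii), dtype=np.int64)
    chunk = 1_000_000
    for s in range(0, len(ii), chunk):
        out[s:s + chunk] = (arr[ii[s:s + chunk]] != arr[jj[s:s + chunk]]).sum(axis=1)
    return out


def uid_diversity_stats(
    uids: Sequence[str],
    max_pairs: int = 8_000_000,
    seed: int = 0,
) -> UIDDiversityStats:
    """Multiplicity and pairwise-distance statistics over a list of UID strings.

    Multiplicities are counted before deduplication.  The mean distance is
    exact; the SD falls back to a seeded random pair subsample when the
    number of unordered pairs exceeds *max_pairs*.
    """
    if len(uids) < 2:
        raise ValueError("need at least two UIDs")
    lengths = {len(u) for u in uids}
    if len(lengths) != 1:
        raise ValueError("UIDs must share one length")
    counts: dict[str, int] = {}
    for u in uids:
        counts[u] = counts.get(u, 0) + 1
    arr = _encode(list(uids))
    dists = _pairwise_distances(arr, max_pairs, np.random.default_rng(seed))
    return UIDDiversityStats(
        n_uids=len(uids),
        n_unique=len(counts),
        frac_unique=sum(1 for c in counts.values() if c == 1) / len(uids),
        max_multiplicity=max(counts.values()),
        mean_pairwise_distance=mean_pairwise_distance(uids),
        sd_pairwise_distance=float(np.std(dists, ddof=1)) if len(dists) > 1 else 0.0,
    )
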