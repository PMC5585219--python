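"""Synthetic barcoded paired-end read generator with full ground truth.

The generator emulates the statistical structure of a targeted,
capture-enriched cfDNA library built with semi-degenerate barcoded
adapters:

* duplex cfDNA fragments (~170 bp) spanning targeted sites, a fraction of
  which carry a spiked-in variant allele at a configured VAF;
* one barcoded adapter per fragment end, whose minus oligo is the reverse
  complement of its plus oligo except at annealing-mispaired positions
  drawn from a per-position profile that decreases toward the ligation
  site;
* independent PCR families per parental strand, with sizes drawn from a
  zero-inflated negative binomial by default (size 0 models strand
  dropout, which is why duplex recovery sits below 100%);
* strand-asymmetric oxidative damage (C>A on the minus strand, applied
  once per molecule before amplification), per-copy polymerase
  substitution errors, and per-read sequencing errors;
* paired 150-bp reads laid out as tag + barcode + T overhang + insert,
  phred33, constant Q30.

Every emitted read traces back to exactly one :class:`TruthRecord`.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .adapter import AdapterSpec, IUPAC_SETS, revcomp

DEFAULT_REFERENCE_SEED = 20170905  # fixed: the shipped reference is part of the study conditions
_BASES = np.array(list("ACGT"))


def make_reference(n_loci: int = 5, locus_length: int = 1000,
                   seed: int = DEFAULT_REFERENCE_SEED) -> dict[str, str]:
    """Deterministic pseudo-random reference: *n_loci* concatenated target loci."""
    rng = np.random.default_rng(seed)
    return {
        f"locus{i + 1}": "".join(rng.choice(_BASES, size=locus_length))
        for i in range(n_loci)
    }


@dataclass(frozen=True)
class SimTarget:
    """One targeted site with its spiked-in variant."""

    locus: str
    position: int  # 0-based on the locus
    ref: str
    alt: str
    vaf: float

    def __post_init__(self):
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")


def default_targets(reference: dict[str, str], vaf: float = 0.1) -> list[SimTarget]:
    """One site per locus, at the locus midpoint, alt = transversion of ref."""
    transversion = {"A": "T", "T": "A", "C": "G", "G": "C"}
    targets = []
    for locus, seq in sorted(reference.items()):
        pos = len(seq) // 2
        ref = seq[pos]
        targets.append(SimTarget(locus, pos, ref, transversion[ref], vaf))
    return targets


def default_mispair_profile(length: int = 12) -> list[float]:
    """Per-position annealing-mispair probabilities, decreasing toward the
    ligation site (position 0 is farthest from it).

    Calibrated so that ~80% of duplexes show zero artifacts over the
    terminal 6+6 positions and most show <=3 over all 24.
    """
    high = [0.28, 0.24, 0.20, 0.16, 0.12, 0.09]
    low = [0.035, 0.025, 0.018, 0.012, 0.008, 0.005]
    profile = (high + low)[:length]
    if len(profile) < length:
        profile += [0.005] * (length - len(profile))
    return profile


@dataclass
class SimulationConfig:
    reference: dict[str, str] = field(default_factory=make_reference)
    target_sites: list[SimTarget] = None
    n_molecules: int = 500
    fragment_length_mean: float = 170.0
    fragment_length_sd: float = 10.0
    adapter: AdapterSpec = field(default_factory=AdapterSpec.v2_default)
    mispair_profile: list[float] = None
    family_size_model: str = "zinb"
    family_size_params: dict = field(
        default_factory=lambda: {"p_zero": 0.25, "mean": 8.0, "r": 4.0}
    )
    polymerase_error_rate: float = 1e-4
    damage_rate_c_to_a: float = 3e-4
    seq_error_rate: float = 1e-3
    read_length: int = 150
    quality: int = 30
    seed: int = 1

    def __post_init__(self):
        if self.target_sites is None:
            self.target_sites = default_targets(self.reference)
        if self.mispair_profile is None:
            self.mispair_profile = default_mispair_profile(self.adapter.barcode_length)
        if len(self.mispair_profile) != self.adapter.barcode_length:
            raise ValueError("mispair_profile length must equal barcode length")
        for rate in (self.polymerase_error_rate, self.damage_rate_c_to_a,
                     self.seq_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.fragment_length_mean <= 2 * self.adapter.end_block_length:
            raise ValueError("fragment mean must exceed twice the adapter end block")
        if self.read_length < self.adapter.end_block_length + 1:
            raise ValueError("read_length shorter than tag+barcode+overhang+1")
        for t in self.target_sites:
            if t.locus not in self.reference:
                raise ValueError(f"target locus {t.locus!r} not in reference")
            if not 0 <= t.position < len(self.reference[t.locus]):
                raise ValueError(f"target position {t.position} outside {t.locus}")
            if self.reference[t.locus][t.position] != t.ref:
                raise ValueError(f"ref allele mismatch at {t.locus}:{t.position}")


@dataclass
class Molecule:
    molecule_id: int
    locus: str
    start: int  # 0-based half-open on the locus
    end: int
    site: SimTarget
    carries_alt: bool


@dataclass
class TaggedDuplex:
    """A duplex molecule with adapters attached to both ends.

    ``bc5``/``bc3`` are the plus-oligo barcodes as synthesized;
    ``mispairs5``/``mispairs3`` list barcode positions (0-based, plus-pattern
    orientation) where the minus oligo carries a non-complementary base.
    """

    molecule: Molecule
    tag_pair: tuple[str, str]
    bc5: str
    bc3: str
    mispairs5: tuple[int, ...]
    mispairs3: tuple[int, ...]


@dataclass
class TruthRecord:
    molecule_id: int
    locus: str
    fragment_start: int
    fragment_end: int
    carries_alt: bool
    tag_plus: str
    tag_minus: str
    uid_5p: str  # plus-oligo barcode at the left ligation site
    uid_3p: str  # plus-oligo barcode at the right ligation site
    mispairs_5p: tuple[int, ...]
    mispairs_3p: tuple[int, ...]
    family_size_plus: int
    family_size_minus: int
    errors: list = field(default_factory=list)  # (read, position, frm, to, mechanism)


@dataclass
class Read:
    name: str
    comment: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str


@dataclass
class SimulationResult:
    config: SimulationConfig
    reads: list[Read]
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row = asdict(t)
            row["mispairs_5p"] = ",".join(map(str, t.mispairs_5p))
            row["mispairs_3p"] = ",".join(map(str, t.mispairs_3p))
            row["errors"] = ";".join(
                f"{r}:{p}:{f}>{o}:{m}" for r, p, f, o, m in t.errors
            )
            rows.append(row)
        return pd.DataFrame(rows)


# Stage 1: molecules ---------------------------------------------------------

def simulate_molecules(config: SimulationConfig, rng: np.random.Generator) -> list[Molecule]:
    """Draw duplex cfDNA fragments spanning the targeted sites.

    Each molecule is assigned a target site uniformly; its fragment length
    is normal (mean ~170 bp) and placed so the site falls inside the
    fragment, emulating hybridization capture around the bait. The alt
    allele is carried with probability equal to the site's VAF.
    """
    sites = config.target_sites
    mols: list[Molecule] = []
    site_idx = rng.integers(0, len(sites), size=config.n_molecules)
    lengths = np.maximum(
        np.rint(rng.normal(config.fragment_length_mean, config.fragment_length_sd,
                           size=config.n_molecules)).astype(int),
        2 * config.adapter.end_block_length + 20,
    )
    for i in range(config.n_molecules):
        site = sites[int(site_idx[i])]
        locus_len = len(config.reference[site.locus])
        length = min(int(lengths[i]), locus_len)
        margin = min(10, length // 4)  # keep the site away from soft-trimmed ends
        offset = int(rng.integers(margin, length - margin))
        start = site.position - offset
        start = max(0, min(start, locus_len - length))
        carries_alt = bool(rng.random() < site.vaf)
        mols.append(Molecule(i, site.locus, start, start + length, site, carries_alt))
    return mols


# Stage 2: adapters ----------------------------------------------------------

def attach_adapters(
    molecules: Sequence[Molecule],
    adapter: AdapterSpec,
    mispair_profile: Sequence[float],
    rng: np.random.Generator,
    barcode_weights=None,
) -> list[TaggedDuplex]:
    """Ligate a barcoded adapter to each fragment end.

    Each end draws a plus-oligo barcode from the pattern; the annealed
    minus oligo is its reverse complement except at positions flagged as
    mispaired, where it carries the complement of the *other* base allowed
    at that position (so the canonicalised barcode still conforms to the
    pattern, as observed for real annealing artifacts). One strand-tag
    combination is drawn per molecule from the permitted table.
    """
    if len(mispair_profile) != adapter.barcode_length:
        raise ValueError("mispair_profile length != barcode length")
    if not adapter.tag_table:
        raise ValueError("empty tag table")
    profile = np.asarray(mispair_profile, dtype=float)
    tagged = []
    for mol in molecules:
        tag_pair = adapter.tag_table[int(rng.integers(0, len(adapter.tag_table)))]
        bc5 = adapter.plus_pattern.sample(1, rng, weights=barcode_weights)[0]
        bc3 = adapter.plus_pattern.sample(1, rng, weights=barcode_weights)[0]
        mis5 = tuple(int(j) for j in np.nonzero(rng.random(len(profile)) < profile)[0])
        mis3 = tuple(int(j) for j in np.nonzero(rng.random(len(profile)) < profile)[0])
        tagged.append(TaggedDuplex(mol, tag_pair, bc5, bc3, mis5, mis3))
    return tagged


def _flip_mispairs(barcode: str, positions: Sequence[int], adapter: AdapterSpec) -> str:
    """Barcode as seen *through the minus oligo* (canonicalised): mispaired
    positions carry the other base the pattern allows there."""
    out = list(barcode)
    for j in positions:
        allowed = IUPAC_SETS[adapter.plus_pattern.symbols[j]]
        others = [b for b in allowed if b != barcode[j]]
        out[j] = others[0] if others else barcode[j]
    return "".join(out)


# Stage 3: amplification and sequencing --------------------------------------

def _draw_family_size(config: SimulationConfig, rng: np.random.Generator) -> int:
    model, params = config.family_size_model, config.family_size_params
    if model == "fixed":
        return int(params["size"])
    if model == "poisson":
        return int(rng.poisson(params["mean"]))
    if model == "zinb":
        if rng.random() < params["p_zero"]:
            return 0
        r, mean = float(params["r"]), float(params["mean"])
        return int(rng.negative_binomial(r, r / (r + mean)))
    raise ValueError(f"unknown family size model {model!r}")


def _mutate(seq: list[str], rate: float, rng: np.random.Generator,
            mechanism: str, read_id: str, errors: list) -> None:
    """In-place uniform substitution errors at per-base *rate*."""
    if rate <= 0.0:
        return
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return
    for pos in rng.choice(len(seq), size=n, replace=False):
        frm = seq[pos]
        choices = [b for b in "ACGT" if b != frm]
        to = choices[int(rng.integers(0, 3))]
        seq[int(pos)] = to
        errors.append((read_id, int(pos), frm, to, mechanism))


def _end_block(tag: str, barcode: str, adapter: AdapterSpec) -> str:
    if adapter.tag_position == "before_barcode":
        return tag + barcode + adapter.overhang_base
    return barcode + tag + adapter.overhang_base


def amplify_and_sequence(
    tagged: Sequence[TaggedDuplex],
    config: SimulationConfig,
) -> tuple[list[Read], list[TruthRecord]]:
    """PCR-amplify each parental strand independently and emit paired reads.

    The plus-strand read presents (in sequencing orientation) the plus tag,
    the left barcode, the T overhang, the insert, and then the reverse
    complement of the right end block; the minus strand is the mirror
    image. Oxidative damage (C>A) hits the minus strand's insert once per
    molecule before amplification; polymerase errors are drawn per copy and
    sequencing errors per read.
    """
    rng = np.random.default_rng(config.seed + 1)
    adapter = config.adapter
    qual = chr(33 + config.quality)
    reads: list[Read] = []
    truth: list[TruthRecord] = []
    for dup in tagged:
        mol = dup.molecule
        insert_plus = list(config.reference[mol.locus][mol.start:mol.end])
        if mol.carries_alt:
            insert_plus[mol.site.position - mol.start] = mol.site.alt
        insert_plus = "".join(insert_plus)
        errors: list = []

        # minus strand template, damaged once pre-PCR
        insert_minus = list(revcomp(insert_plus))
        if config.damage_rate_c_to_a > 0:
            c_positions = [i for i, b in enumerate(insert_minus) if b == "C"]
            for i in c_positions:
                if rng.random() < config.damage_rate_c_to_a:
                    insert_minus[i] = "A"
                    errors.append((f"M{mol.molecule_id}.minus", i, "C", "A", "damage"))
        insert_minus = "".join(insert_minus)

        p_tag, m_tag = dup.tag_pair
        bc5_via_minus = _flip_mispairs(dup.bc5, dup.mispairs5, adapter)
        bc3_via_minus = _flip_mispairs(dup.bc3, dup.mispairs3, adapter)
        plus_template = (
            _end_block(p_tag, dup.bc5, adapter)
            + insert_plus
            + revcomp(_end_block(m_tag, bc3_via_minus, adapter))
        )
        minus_template = (
            _end_block(m_tag, dup.bc3, adapter)
            + insert_minus
            + revcomp(_end_block(p_tag, bc5_via_minus, adapter))
        )

        sizes = {}
        for strand, template in (("plus", plus_template), ("minus", minus_template)):
            size = _draw_family_size(config, rng)
            sizes[strand] = size
            for copy in range(size):
                read_id = f"M{mol.molecule_id}.{strand}.{copy}"
                copy_seq = list(template)
                _mutate(copy_seq, config.polymerase_error_rate, rng,
                        "polymerase", read_id, errors)
                r1 = copy_seq[: config.read_length]
                r2 = list(revcomp("".join(copy_seq)))[: config.read_length]
                _mutate(r1, config.seq_error_rate, rng, "sequencing", read_id + "/1", errors)
                _mutate(r2, config.seq_error_rate, rng, "sequencing", read_id + "/2", errors)
                reads.append(Read(
                    name=read_id,
                    comment=f"mol={mol.molecule_id} strand={strand}",
                    r1_seq="".join(r1), r1_qual=qual * len(r1),
                    r2_seq="".join(r2), r2_qual=qual * len(r2),
                ))
        truth.append(TruthRecord(
            molecule_id=mol.molecule_id,
            locus=mol.locus,
            fragment_start=mol.start,
            fragment_end=mol.end,
            carries_alt=mol.carries_alt,
            tag_plus=p_tag,
            tag_minus=m_tag,
            uid_5p=dup.bc5,
            uid_3p=dup.bc3,
            mispairs_5p=dup.mispairs5,
            mispairs_3p=dup.mispairs3,
            family_size_plus=sizes["plus"],
            family_size_minus=sizes["minus"],
            errors=errors,
        ))
    return reads, truth


def simulate_run(config: SimulationConfig) -> SimulationResult:
    """Run all three stages under the config's seed (fully deterministic)."""
    rng = np.random.default_rng(config.seed)
    molecules = simulate_molecules(config, rng)
    tagged = attach_adapters(molecules, config.adapter, config.mispair_profile, rng)
    reads, truth = amplify_and_sequence(tagged, config)
    return SimulationResult(config, reads, truth)


# I/O ------------------------------------------------------------------------

def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, mode + "b"))
    return open(path, mode)


def write_fastq(result: SimulationResult, out_dir: str | Path, gz: bool = True) -> dict:
    """Write paired FASTQ (Illumina 1.8+ headers, molecule id in the comment),
    the truth table, the reference FASTA and a config echo; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gz else ".fastq"
    paths = {
        "r1": out / f"reads_R1{suffix}",
        "r2": out / f"reads_R2{suffix}",
        "truth": out / "truth.tsv",
        "reference": out / "reference.fasta",
        "config": out / "config.yaml",
    }
    with _open_text(paths["r1"], "w") as f1, _open_text(paths["r2"], "w") as f2:
        for read in result.reads:
            f1.write(f"@{read.name} {read.comment}\n{read.r1_seq}\n+\n{read.r1_qual}\n")
            f2.write(f"@{read.name} {read.comment}\n{read.r2_seq}\n+\n{read.r2_qual}\n")
    result.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["reference"], "w") as fh:
        for name, seq in sorted(result.config.reference.items()):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    from .config import dump_sim_config
    dump_sim_config(result.config, paths["config"])
    return paths


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path):
    """Yield (name, comment, r1_seq, r1_qual, r2_seq, r2_qual) tuples."""
    from Bio import SeqIO

    def records(path):
        handle = _open_text(Path(path), "r")
        return SeqIO.parse(handle, "fastq")

    for idx, (rec1, rec2) in enumerate(zip(records(r1_path), records(r2_path))):
        if rec1.id != rec2.id:
            raise ValueError(f"FASTQ pair mismatch at record {idx}: {rec1.id} vs {rec2.id}")
        q1 = "".join(chr(33 + q) for q in rec1.letter_annotations["phred_quality"])
        q2 = "".join(chr(33 + q) for q in rec2.letter_annotations["phred_quality"])
        comment = rec1.description[len(rec1.id):].strip()
        yield rec1.id, comment, str(rec1.seq), q1, str(rec2.seq), q2
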