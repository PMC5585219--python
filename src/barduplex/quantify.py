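"""Targeted-site pileup, VAF calling and background error profiling.

Variant allele fractions are computed as mutant molecules over all
molecules with a concrete base call at the site (reference + alternate +
third alleles; ambiguities excluded).  A call is high-confidence only
when independently supported by the consensus sequences of both parental
strands, i.e. by at least one duplex.  Background error rates are the
fraction of non-reference calls over all evaluated consensus bases,
excluding a-priori known SNP/somatic sites, soft-trimmed ligation bases
and ambiguous positions, tracked per substitution class in reference
orientation so that the C>A / G>T damage asymmetry stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)
ERROR_CLASSES = SUBSTITUTION_CLASSES + ("ins", "del")


@dataclass(frozen=True)
class TargetSite:
    locus: str
    position: int  # 0-based on the locus
    ref: str
    alt: str
    annotation: str = "somatic"  # somatic | known_SNP

    def validate(self, reference: Mapping[str, str]) -> None:
        if self.locus not in reference:
            raise ValueError(f"site locus {self.locus!r} not in reference")
        if not 0 <= self.position < len(reference[self.locus]):
            raise ValueError(f"site position {self.position} outside {self.locus}")
        if reference[self.locus][self.position] != self.ref:
            raise ValueError(
                f"ref allele {self.ref} does not match reference at "
                f"{self.locus}:{self.position}"
            )


def read_bed(path: str | Path) -> list[TargetSite]:
    """Targets from BED (0-based half-open): chrom, start, end, name, ref, alt[, annotation]."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            sites.append(TargetSite(
                locus=fields[0],
                position=int(fields[1]),
                ref=fields[4],
                alt=fields[5],
                annotation=fields[6] if len(fields) > 6 else "somatic",
            ))
    return sites


def write_bed(sites: Sequence[TargetSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.locus}\t{s.position}\t{s.position + 1}\t"
                     f"{s.locus}_{s.position}\t{s.ref}\t{s.alt}\t{s.annotation}\n")


@dataclass
class PileupCounts:
    site: TargetSite
    n_ref: int = 0
    n_alt: int = 0
    n_other: int = 0
    n_ambiguous: int = 0

    @property
    def n_called(self) -> int:
        return self.n_ref + self.n_alt + self.n_other

    @property
    def total(self) -> int:
        return self.n_called + self.n_ambiguous

    @property
    def vaf(self) -> float | None:
        return self.n_alt / self.n_called if self.n_called else None


def pileup(records: Sequence, sites: Sequence[TargetSite],
           reference: Mapping[str, str]) -> dict[TargetSite, PileupCounts]:
    """Molecule counts per targeted site from consensus records.

    Each record spanning a site contributes exactly one count:
    reference/alternate/other by its base, or ambiguous when the base is
    'N', a coverage gap, or inside the soft-trim mask.  Records need
    ``locus``/``start``/``end``/``sequence``/``trim_n``.
    """
    for site in sites:
        site.validate(reference)
    out = {site: PileupCounts(site) for site in sites}
    for rec in records:
        for site in sites:
            if rec.locus != site.locus or not rec.start <= site.position < rec.end:
                continue
            counts = out[site]
            offset = site.position - rec.start
            length = rec.end - rec.start
            base = rec.sequence[offset]
            if offset < rec.trim_n or offset >= length - rec.trim_n or base in "N-":
                counts.n_ambiguous += 1
            elif base == site.ref:
                counts.n_ref += 1
            elif base == site.alt:
                counts.n_alt += 1
            else:
                counts.n_other += 1
    return out


@dataclass
class VariantCall:
    site: TargetSite
    level: str  # sscs | duplex
    n_ref: int
    n_alt: int
    n_other: int
    n_ambiguous: int
    vaf: float | None
    duplex_support: bool
    high_confidence: bool


def call_variants(
    sscs_pileup: Mapping[TargetSite, PileupCounts],
    duplex_pileup: Mapping[TargetSite, PileupCounts],
    min_duplex_molecules: int = 1,
) -> list[VariantCall]:
    """Per-site calls at both consensus levels.

    ``duplex_support`` requires at least one alt-bearing duplex;
    ``high_confidence`` additionally requires *min_duplex_molecules* alt
    duplexes (both strands of those molecules independently support the
    variant).
    """
    calls = []
    for site in sscs_pileup:
        dup = duplex_pileup.get(site)
        support = bool(dup and dup.n_alt >= 1)
        high = bool(dup and support and dup.n_alt >= min_duplex_molecules)
        for level, counts in (("sscs", sscs_pileup[site]), ("duplex", dup)):
            if counts is None:
                continue
            calls.append(VariantCall(
                site=site,
                level=level,
                n_ref=counts.n_ref,
                n_alt=counts.n_alt,
                n_other=counts.n_other,
                n_ambiguous=counts.n_ambiguous,
                vaf=counts.vaf,
                duplex_support=support,
                high_confidence=high,
            ))
    return calls


@dataclass
class ErrorProfile:
    level: str  # raw | sscs | duplex
    total_bases: int
    counts: dict[str, int]  # per error class

    @property
    def overall_rate(self) -> float:
        return sum(self.counts.values()) / self.total_bases if self.total_bases else 0.0

    def rate(self, error_class: str) -> float:
        return self.counts.get(error_class, 0) / self.total_bases if self.total_bases else 0.0


def background_error_profile(
    records: Sequence,
    reference: Mapping[str, str],
    exclude_sites: Iterable[TargetSite] = (),
    level: str = "sscs",
) -> ErrorProfile:
    """Non-reference call rates by substitution class, reference-oriented.

    Known SNP/somatic sites, soft-trim-masked bases, coverage gaps and
    ambiguous ('N') positions are excluded from both numerator and
    denominator.  C>A and its reciprocal G>T are tracked separately so
    strand-asymmetric oxidative damage shows up as an imbalance.
    """
    excluded: dict[str, set[int]] = {}
    for site in exclude_sites:
        excluded.setdefault(site.locus, set()).add(site.position)
    counts = {c: 0 for c in ERROR_CLASSES}
    total = 0
    for rec in records:
        ref_seq = reference[rec.locus]
        skip = excluded.get(rec.locus, ())
        length = rec.end - rec.start
        for offset in range(rec.trim_n, length - rec.trim_n):
            base = rec.sequence[offset]
            if base in "N-" or (rec.start + offset) in skip:
                continue
            total += 1
            ref_base = ref_seq[rec.start + offset]
            if base != ref_base:
                counts[f"{ref_base}>{base}"] += 1
    return ErrorProfile(level=level, total_bases=total, counts=counts)


# Unique-molecule accounting -------------------------------------------------

def copies_from_mass(input_mass_ng: float, pg_per_haploid: float = 3.3) -> int:
    """Expected haploid genome copies per locus from DNA input mass
    (2.3 ng at 3.3 pg per haploid genome -> 697 copies)."""
    if input_mass_ng < 0 or pg_per_haploid <= 0:
        raise ValueError("mass must be >= 0 and pg per haploid > 0")
    return round(input_mass_ng * 1000.0 / pg_per_haploid)


def replicate_stats(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of replicate counts."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    return float(arr.mean()), float(arr.std(ddof=1))


def unique_molecule_table(
    molecule_counts: Mapping[str, int],
    input_mass_ng: float,
    pg_per_haploid: float = 3.3,
) -> pd.DataFrame:
    """Per-site unique-molecule counts and recovery efficiency versus the
    copy number expected from the DNA input mass."""
    expected = copies_from_mass(input_mass_ng, pg_per_haploid)
    rows = [
        {
            "site": name,
            "unique_molecules": int(count),
            "expected_copies": expected,
            "efficiency": count / expected if expected else 0.0,
        }
        for name, count in sorted(molecule_counts.items())
    ]
    return pd.DataFrame(rows)


# Report emission ------------------------------------------------------------

def calls_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "locus": c.site.locus,
            "position_1based": c.site.position + 1,
            "ref": c.site.ref,
            "alt": c.site.alt,
            "level": c.level,
            "n_ref": c.n_ref,
            "n_alt": c.n_alt,
            "n_other": c.n_other,
            "n_ambiguous": c.n_ambiguous,
            "vaf": c.vaf if c.vaf is not None else float("nan"),
            "duplex_support": c.duplex_support,
            "high_confidence": c.high_confidence,
        }
        for c in calls
    ])


def write_vcf(calls: Sequence[VariantCall], path: str | Path,
              reference: Mapping[str, str]) -> None:
    """Minimal VCF 4.2 with molecule counts and duplex support in INFO."""
    by_site: dict[TargetSite, dict[str, VariantCall]] = {}
    for c in calls:
        by_site.setdefault(c.site, {})[c.level] = c
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SSCS_ALT,Number=1,Type=Integer,Description="Alt SSCS molecules">\n')
        fh.write('##INFO=<ID=SSCS_DP,Number=1,Type=Integer,Description="Called SSCS molecules">\n')
        fh.write('##INFO=<ID=DUP_ALT,Number=1,Type=Integer,Description="Alt duplex molecules">\n')
        fh.write('##INFO=<ID=DUP_DP,Number=1,Type=Integer,Description="Called duplex molecules">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="SSCS variant allele fraction">\n')
        fh.write('##INFO=<ID=DS,Number=0,Type=Flag,Description="Duplex support">\n')
        for name, seq in sorted(reference.items()):
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for site in sorted(by_site, key=lambda s: (s.locus, s.position)):
            levels = by_site[site]
            sscs = levels.get("sscs")
            dup = levels.get("duplex")
            info = []
            if sscs:
                info += [f"SSCS_ALT={sscs.n_alt}",
                         f"SSCS_DP={sscs.n_ref + sscs.n_alt + sscs.n_other}"]
                if sscs.vaf is not None:
                    info.append(f"VAF={sscs.vaf:.6g}")
            if dup:
                info += [f"DUP_ALT={dup.n_alt}",
                         f"DUP_DP={dup.n_ref + dup.n_alt + dup.n_other}"]
                if dup.duplex_support:
                    info.append("DS")
            fh.write(f"{site.locus}\t{site.position + 1}\t.\t{site.ref}\t{site.alt}"
                     f"\t.\tPASS\t{';'.join(info) or '.'}\n")
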