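"""End-to-end orchestration: simulate, call and summarise.

The calling pipeline mirrors the three-stage analysis the assay needs:
read preparation (merge, tag extraction, orientation, soft-trim), then
per-strand consensus (alignment, family grouping, SSCS), then duplex
assembly and targeted quantification.  Every stage's counts land in a
machine-readable summary whose totals are mutually consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import consensus, duplex, quantify, readprep
from .config import RunConfig
from .quantify import TargetSite

logger = logging.getLogger("barduplex")


@dataclass
class CallResult:
    summary: dict
    merged: list
    rejects: list
    aligned: list
    families: list
    sscs: list
    match: duplex.MatchResult
    recovery: duplex.DuplexRecoveryStats
    sscs_pileup: dict
    duplex_pileup: dict
    calls: list
    error_profiles: dict = field(default_factory=dict)


def run_call(
    pairs: Iterable[tuple[str, str, str, str, str, str]],
    reference: dict[str, str],
    sites: Sequence[TargetSite],
    config: RunConfig | None = None,
) -> CallResult:
    """Execute readprep -> consensus -> duplex -> quantify on a pair stream."""
    config = config or RunConfig()
    pairs = list(pairs)
    merged, rejects = readprep.prepare_pairs(
        pairs, config.adapter,
        min_overlap=config.min_overlap,
        max_mismatch_frac=config.max_mismatch_frac,
        trim_n=config.trim_n,
    )
    logger.info("readprep: %d pairs in, %d merged, %d rejected",
                len(pairs), len(merged), len(rejects))
    aligned, off_target = consensus.align_to_reference(
        merged, reference, max_edit_frac=config.max_edit_frac)
    rejects = rejects + off_target
    families = consensus.group_families(aligned, config.family_mismatch_frac)
    sscs = [s for fam in families
            if (s := consensus.build_sscs(fam, config.min_reads)) is not None]
    if not config.keep_unknown_orientation:
        sscs = [s for s in sscs if s.orientation in ("plus", "minus")]
    logger.info("consensus: %d aligned, %d families, %d SSCS",
                len(aligned), len(families), len(sscs))
    match = duplex.match_duplexes(
        sscs,
        max_key_mismatches=config.max_key_mismatches,
        spurious_threshold=config.spurious_threshold,
        key_len=config.adapter.duplex_key_length,
        per_block=config.per_block_key,
    )
    n_fwd = sum(1 for s in sscs if s.orientation == "plus")
    n_rev = sum(1 for s in sscs if s.orientation == "minus")
    recovery = duplex.duplex_recovery(n_fwd, n_rev, len(match.duplexes))
    logger.info("duplex: %d duplexes from %d fwd + %d rev SSCS (recovery %.3f)",
                len(match.duplexes), n_fwd, n_rev, recovery.recovery_rate)

    sscs_pileup = quantify.pileup(sscs, sites, reference)
    duplex_pileup = quantify.pileup(match.duplexes, sites, reference)
    calls = quantify.call_variants(sscs_pileup, duplex_pileup,
                                   config.min_duplex_molecules)
    profiles = {
        "raw": quantify.background_error_profile(aligned, reference, sites, "raw"),
        "sscs": quantify.background_error_profile(sscs, reference, sites, "sscs"),
        "duplex": quantify.background_error_profile(
            match.duplexes, reference, sites, "duplex"),
    }
    reject_reasons: dict[str, int] = {}
    for _name, reason in rejects:
        reject_reasons[reason] = reject_reasons.get(reason, 0) + 1
    summary = {
        "reads_in": len(pairs),
        "merged": len(merged),
        "rejected": reject_reasons,
        "rejected_total": len(rejects),
        "aligned": len(aligned),
        "families": len(families),
        "sscs": len(sscs),
        "sscs_fwd": n_fwd,
        "sscs_rev": n_rev,
        "duplexes": len(match.duplexes),
        "spurious_pairs": len(match.spurious),
        "unique_molecules": recovery.unique_molecules,
        "duplex_recovery_rate": recovery.recovery_rate,
        "calls": len(calls),
    }
    return CallResult(summary, merged, rejects, aligned, families, sscs,
                      match, recovery, sscs_pileup, duplex_pileup, calls, profiles)


def run_stats(result: CallResult) -> dict:
    """Descriptive report: family sizes, UID diversity, recovery, mispairings."""
    from .adapter import uid_diversity_stats

    fam_stats = consensus.family_size_stats(result.families)
    report: dict = {
        "family_size_histogram": dict(sorted(fam_stats.histogram.items())),
        "peak_family_size": fam_stats.peak_family_size,
        "frac_unique_coordinates": fam_stats.frac_unique_coordinates,
        "duplex_recovery": {
            "n_fwd": result.recovery.n_fwd,
            "n_rev": result.recovery.n_rev,
            "n_duplexes": result.recovery.n_duplexes,
            "unique_molecules": result.recovery.unique_molecules,
            "recovery_rate": result.recovery.recovery_rate,
        },
    }
    plus_uids = [s.uid.combined for s in result.sscs if s.orientation == "plus"]
    if len(plus_uids) >= 2:
        stats = uid_diversity_stats(plus_uids)
        report["uid_diversity"] = {
            "n_uids": stats.n_uids,
            "n_unique": stats.n_unique,
            "frac_unique": stats.frac_unique,
            "max_multiplicity": stats.max_multiplicity,
            "mean_pairwise_distance": stats.mean_pairwise_distance,
            "sd_pairwise_distance": stats.sd_pairwise_distance,
        }
    prof = duplex.mispairing_profile(
        result.match.duplexes)
    if prof.n_duplexes:
        report["mispairing"] = {
            "per_position_frequency": prof.per_position_frequency,
            "histogram_full": dict(sorted(prof.histogram_full.items())),
            "histogram_terminal": dict(sorted(prof.histogram_terminal.items())),
        }
    return report
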