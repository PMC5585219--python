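"""Alignment, PCR-family grouping, SSCS construction and family statistics."""

import numpy as np
import pytest

from barduplex.adapter import UID, revcomp
from barduplex.consensus import (AlignedRead, PCRFamily, align_to_reference,
                                 brute_force_single_linkage, build_sscs,
                                 _incremental_single_linkage,
                                 family_size_stats, group_families)
from barduplex.readprep import prepare_pairs
from barduplex.simulate import simulate_run
from conftest import as_pairs, clean_config


def _aligned(uid5, uid3, start=0, end=4, seq="ACGT", orientation="plus",
             name="r", locus="locus1", merged_length=200, trim_n=0):
    return AlignedRead(name=name, locus=locus, start=start, end=end,
                       sequence=seq, orientation=orientation,
                       uid=UID(uid5, uid3), tag_pair=("CTA", "GAA"),
                       nm=0, merged_length=merged_length, trim_n=trim_n)


# Alignment ------------------------------------------------------------------

def test_alignment_recovers_truth_coordinates(reference, adapter_v2):
    cfg = clean_config(reference, n_molecules=30)
    res = simulate_run(cfg)
    truth = {t.molecule_id: t for t in res.truth}
    merged, _ = prepare_pairs(as_pairs(res), adapter_v2)
    aligned, rejects = align_to_reference(merged, reference)
    assert not rejects
    for read in aligned:
        t = truth[int(read.name.split(".")[0][1:])]
        assert (read.locus, read.start, read.end) == \
            (t.locus, t.fragment_start, t.fragment_end)
        # sequences stored in reference orientation regardless of strand
        expected = list(reference[t.locus][t.fragment_start:t.fragment_end])
        if t.carries_alt:
            site = next(s for s in cfg.target_sites if s.locus == t.locus)
            expected[site.position - t.fragment_start] = site.alt
        assert read.sequence == "".join(expected)


def test_minus_strand_reads_share_plus_coordinates(clean_run):
    _cfg, res, call = clean_run
    by_mol = {}
    for read in call.aligned:
        mol = int(read.name.split(".")[0][1:])
        by_mol.setdefault(mol, set()).add((read.locus, read.start, read.end))
    for coords in by_mol.values():
        assert len(coords) == 1


def test_random_sequence_is_off_target(reference):
    rng = np.random.default_rng(0)
    from barduplex.readprep import MergedRead
    junk = "".join(rng.choice(list("ACGT"), size=150))
    m = MergedRead("junk", junk, "?" * 150, uid=UID("A" * 12, "A" * 12),
                   insert=junk, orientation="plus")
    m.tag_pair = ("CTA", "GAA")
    aligned, rejects = align_to_reference([m], reference)
    assert aligned == [] and rejects == [("junk", "off_target")]


def test_empty_reference_is_an_error():
    with pytest.raises(ValueError):
        align_to_reference([], {})


# Family grouping ------------------------------------------------------------

def test_identical_uids_one_family():
    reads = [_aligned("A" * 12, "C" * 12, name=f"r{i}") for i in range(5)]
    fams = group_families(reads)
    assert len(fams) == 1 and fams[0].size == 5
    assert fams[0].uid.combined == "A" * 12 + "C" * 12


def test_distant_uids_split_coordinate_collisions():
    # two molecules sharing coordinates: UID distance 11 >> 1% threshold
    a = ["A" * 12, "C" * 12]
    b = ["T" * 11 + "A", "C" * 12]
    reads = [_aligned(*a, name="a1"), _aligned(*a, name="a2"),
             _aligned(*b, name="b1"), _aligned(*b, name="b2")]
    fams = group_families(reads)
    assert sorted(f.size for f in fams) == [2, 2]


def test_single_barcode_error_stays_in_family():
    reads = [_aligned("A" * 12, "C" * 12, name="r0"),
             _aligned("A" * 11 + "T", "C" * 12, name="r1"),
             _aligned("A" * 12, "C" * 12, name="r2")]
    fams = group_families(reads)
    assert len(fams) == 1 and fams[0].size == 3
    assert fams[0].uid.combined == "A" * 12 + "C" * 12  # plurality barcode


def test_orientation_and_coordinates_partition_buckets():
    reads = [_aligned("A" * 12, "C" * 12, name="p", orientation="plus"),
             _aligned("A" * 12, "C" * 12, name="m", orientation="minus"),
             _aligned("A" * 12, "C" * 12, name="s", start=1, end=5)]
    assert len(group_families(reads)) == 3


def test_grouping_is_idempotent_and_a_partition(clean_run):
    _cfg, _res, call = clean_run
    fams_again = group_families(call.aligned)
    key = lambda fams: [sorted(r.name for r in f.members) for f in fams]
    assert key(fams_again) == key(call.families)
    names = [r.name for f in call.families for r in f.members]
    assert sorted(names) == sorted(r.name for r in call.aligned)
    assert len(names) == len(set(names))


def test_incremental_linkage_agrees_with_brute_force():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        n = int(rng.integers(2, 51))
        # low-cardinality alphabet forces frequent borderline distances
        uids = ["".join(rng.choice(list("AT"), size=8)) for _ in range(n)]
        threshold = int(rng.integers(1, 4))
        fast = _incremental_single_linkage(uids, threshold)
        slow = brute_force_single_linkage(uids, threshold)
        as_partition = lambda labels: {
            frozenset(i for i, l in enumerate(labels) if l == lab)
            for lab in set(labels)}
        assert as_partition(fast) == as_partition(slow)


# SSCS -----------------------------------------------------------------------

def _family(seqs, **kw):
    reads = [_aligned("A" * 12, "C" * 12, seq=s, end=len(seqs[0]), name=f"r{i}")
             for i, s in enumerate(seqs)]
    fam = PCRFamily(0, "locus1", "plus", 0, len(seqs[0]), reads,
                    UID("A" * 12, "C" * 12))
    return fam


def test_sscs_of_identical_reads_is_the_read():
    sscs = build_sscs(_family(["ACGTACGT"] * 3))
    assert sscs.sequence == "ACGTACGT"
    assert sscs.n_reads == 3 and sscs.ambiguous == frozenset()


def test_sscs_plurality_beats_single_error():
    sscs = build_sscs(_family(["ACGTACGT", "ACGTACGT", "ACTTACGT"]))
    assert sscs.sequence == "ACGTACGT"


def test_sscs_even_split_becomes_ambiguity():
    sscs = build_sscs(_family(["ACGTACGT", "ACGTACGT", "ACTTACGT", "ACTTACGT"]))
    assert sscs.sequence == "AC" + "N" + "TACGT"
    assert sscs.ambiguous == frozenset({2})


def test_sscs_requires_three_reads():
    assert build_sscs(_family(["ACGT"] * 2)) is None
    assert build_sscs(_family(["ACGT"] * 3), min_reads=4) is None


def test_sscs_gap_columns_are_skipped():
    sscs = build_sscs(_family(["AC-T", "ACGT", "ACGT"]))
    assert sscs.sequence == "ACGT"


def test_zero_error_sscs_equal_true_fragments(clean_run):
    cfg, res, call = clean_run
    truth = {t.molecule_id: t for t in res.truth}
    # every simulated strand with >=3 reads yields exactly one SSCS
    assert len(call.sscs) == 2 * cfg.n_molecules
    for s in call.sscs:
        mol = int(call.families[s.family_id].members[0].name.split(".")[0][1:])
        t = truth[mol]
        expected = list(cfg.reference[t.locus][t.fragment_start:t.fragment_end])
        if t.carries_alt:
            site = next(ts for ts in cfg.target_sites if ts.locus == t.locus)
            expected[site.position - t.fragment_start] = site.alt
        assert s.sequence == "".join(expected)


# Family-size statistics -----------------------------------------------------

def test_family_size_stats_hand_worked():
    fams = []
    sizes = [1] * 10 + [3] * 5 + [6] * 4
    for i, size in enumerate(sizes):
        reads = [_aligned("A" * 12, "C" * 12, start=i, end=i + 4,
                          name=f"f{i}r{j}") for j in range(size)]
        fams.append(PCRFamily(i, "locus1", "plus", i, i + 4, reads,
                              UID("A" * 12, "C" * 12)))
    stats = family_size_stats(fams)
    assert stats.histogram == {1: 10, 3: 5, 6: 4}
    # reads per size: 10, 15, 24 -> the peak (size >1 by read mass) is 6
    assert stats.peak_family_size == 6
    assert stats.total_reads == 49
    assert stats.frac_unique_coordinates["plus"] == 1.0


def test_all_singletons_have_no_peak():
    fams = [PCRFamily(i, "locus1", "plus", i, i + 4,
                      [_aligned("A" * 12, "C" * 12, start=i, end=i + 4)],
                      UID("A" * 12, "C" * 12)) for i in range(5)]
    assert family_size_stats(fams).peak_family_size is None


def test_simulated_peak_family_size_in_published_range(reference):
    cfg = clean_config(reference, n_molecules=300, family_size=0,
                       family_size_model="zinb",
                       family_size_params={"p_zero": 0.25, "mean": 8.0, "r": 4.0},
                       seed=5)
    res = simulate_run(cfg)
    sizes = [t.family_size_plus for t in res.truth] + \
            [t.family_size_minus for t in res.truth]
    hist = {}
    for s in sizes:
        if s > 0:
            hist[s] = hist.get(s, 0) + 1
    peak = max((s for s in hist if s > 1), key=lambda s: s * hist[s])
    assert 6 <= peak <= 12
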