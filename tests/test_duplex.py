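"""Duplex matching, consensus, recovery accounting and mispairing profiles."""

import numpy as np
import pytest

from barduplex.adapter import IUPACPattern, UID, hamming
from barduplex.consensus import SSCSRecord
from barduplex.duplex import (DuplexRecoveryStats, build_duplex_consensus,
                              duplex_key, duplex_recovery, match_duplexes,
                              mispairing_profile, resolve_key_clash,
                              swapped_uid)

BC_A = "ACAAACCAGAAA"  # conforms to WSMRWSYWKMWW
BC_B = "TGCGTGTTGCTT"  # a second pattern-conforming barcode
PATTERN = IUPACPattern("WSMRWSYWKMWW")


def _sscs(uid5, uid3, orientation="plus", seq="ACGTACGT", start=0, end=8,
          locus="locus1", fid=0):
    return SSCSRecord(family_id=fid, locus=locus, orientation=orientation,
                      start=start, end=end, uid=UID(uid5, uid3),
                      sequence=seq, n_reads=3)


def _flip(barcode, positions):
    out = list(barcode)
    for j in positions:
        allowed = {"W": "AT", "S": "CG", "M": "AC", "R": "AG",
                   "Y": "CT", "K": "GT"}[PATTERN.symbols[j]]
        out[j] = [b for b in allowed if b != barcode[j]][0]
    return "".join(out)


def _true_pair(mispairs5=(), mispairs3=(), **kw):
    """Plus/minus SSCS pair as the two strands of one molecule present them."""
    plus = _sscs(BC_A, _flip(BC_B, mispairs3), "plus", **kw)
    minus = _sscs(BC_B, _flip(BC_A, mispairs5), "minus", **kw)
    return plus, minus


def test_duplex_key_aligns_true_partners():
    plus, minus = _true_pair()
    assert duplex_key(plus) == duplex_key(minus)
    assert swapped_uid(plus) == swapped_uid(minus)


def test_perfect_duplex_matches_with_zero_key_mismatches():
    plus, minus = _true_pair()
    result = match_duplexes([plus, minus])
    assert len(result.duplexes) == 1
    assert result.duplexes[0].key_mismatches == 0
    assert not result.unpaired_plus and not result.unpaired_minus


@pytest.mark.parametrize("n_terminal,expect_match", [(1, True), (2, True), (3, False)])
def test_terminal_key_mismatch_threshold(n_terminal, expect_match):
    # mispairings in the terminal six positions of the 5' barcode
    positions = tuple(range(11, 11 - n_terminal, -1))
    plus, minus = _true_pair(mispairs5=positions)
    result = match_duplexes([plus, minus])
    assert bool(result.duplexes) is expect_match
    if expect_match:
        assert result.duplexes[0].key_mismatches == n_terminal


def test_outer_barcode_mispairs_do_not_block_matching():
    # five artifacts, all outside the terminal six positions
    plus, minus = _true_pair(mispairs5=(0, 1, 2), mispairs3=(0, 3))
    result = match_duplexes([plus, minus])
    assert len(result.duplexes) == 1
    assert result.duplexes[0].key_mismatches == 0
    assert result.duplexes[0].full_uid_mismatches == 5


def test_random_uid_collision_rejected_as_spurious():
    rng = np.random.default_rng(7)
    hits = 0
    spurious_seen = 0
    trials = 200
    for _ in range(trials):
        a5, a3, b5, b3 = PATTERN.sample(4, rng)
        plus = _sscs(a5, a3, "plus")
        minus = _sscs(b5, b3, "minus")
        result = match_duplexes([plus, minus])
        hits += len(result.duplexes)
        spurious_seen += len(result.spurious)
        for _p, _m, fd in result.spurious:
            assert fd > 5
    # random 12-nt keys pass the <=2 rule with prob ~1.9%; the full-UID
    # distance (~12 of 24) then flags the pair instead of accepting it
    assert hits == 0
    assert spurious_seen <= 20


def test_spurious_pair_uid_distance_near_half():
    rng = np.random.default_rng(11)
    dists = []
    for _ in range(300):
        a5, a3, b5, b3 = PATTERN.sample(4, rng)
        dists.append(hamming(a5 + a3, b3 + b5))
    assert np.mean(dists) == pytest.approx(12.0, abs=0.5)


def test_resolve_key_clash_rules():
    near = _sscs(BC_A, BC_B, "minus")
    far = _sscs(_flip(BC_A, (0, 1, 2)), BC_B, "minus")
    # lower key distance wins
    assert resolve_key_clash([(near, 1, 3), (far, 2, 3)]) is near
    # key tie -> smaller full-UID distance wins
    assert resolve_key_clash([(near, 1, 3), (far, 1, 12)]) is near
    # exact tie on both -> unresolved
    assert resolve_key_clash([(near, 1, 3), (far, 1, 3)]) is None
    assert resolve_key_clash([]) is None


def test_exact_tie_leaves_all_unpaired():
    plus, minus = _true_pair()
    minus2 = _sscs(minus.uid.barcode_5p, minus.uid.barcode_3p, "minus", fid=1)
    result = match_duplexes([plus, minus, minus2])
    assert result.duplexes == []
    assert len(result.unpaired_minus) == 2


def test_matching_is_symmetric_and_exclusive():
    rng = np.random.default_rng(3)
    records = []
    for fid in range(6):
        b5, b3 = PATTERN.sample(2, rng)
        plus = _sscs(b5, b3, "plus", fid=2 * fid)
        minus = _sscs(b3, b5, "minus", fid=2 * fid + 1)
        records += [plus, minus]
    fwd = match_duplexes(records)
    rev = match_duplexes(records[::-1])
    key = lambda r: sorted((d.sscs_plus.family_id, d.sscs_minus.family_id)
                           for d in r.duplexes)
    assert key(fwd) == key(rev)
    assert len(fwd.duplexes) == 6
    used = [d.sscs_plus.family_id for d in fwd.duplexes] + \
           [d.sscs_minus.family_id for d in fwd.duplexes]
    assert len(used) == len(set(used))


def test_duplex_consensus_agreement_and_damage_cancellation():
    plus, minus = _true_pair()
    dup = build_duplex_consensus(plus, minus)
    assert dup.sequence == plus.sequence
    # one strand carries a damage-derived call: position becomes ambiguous
    damaged = _sscs(minus.uid.barcode_5p, minus.uid.barcode_3p, "minus",
                    seq="ACGTATGT")
    dup2 = build_duplex_consensus(plus, damaged)
    assert dup2.sequence == "ACGTANGT"
    assert dup2.ambiguous == frozenset({5})
    # both strands carrying the alt keep it
    alt_p = _sscs(BC_A, BC_B, "plus", seq="ACGTATGT")
    dup3 = build_duplex_consensus(alt_p, damaged)
    assert dup3.sequence == "ACGTATGT"


def test_duplex_consensus_requires_shared_coordinates():
    plus, _ = _true_pair()
    other = _sscs(BC_B, BC_A, "minus", start=2, end=10)
    with pytest.raises(ValueError):
        build_duplex_consensus(plus, other)


def test_recovery_worked_example():
    stats = duplex_recovery(1000, 1000, 600)
    assert stats.unique_molecules == 1400
    assert stats.recovery_rate == pytest.approx(600 / 1400)


@pytest.mark.parametrize("n_fwd,n_rev,d,unique,rate", [
    (5, 7, 0, 12, 0.0),
    (3, 3, 3, 3, 1.0),
])
def test_recovery_edge_cases(n_fwd, n_rev, d, unique, rate):
    stats = duplex_recovery(n_fwd, n_rev, d)
    assert (stats.unique_molecules, stats.recovery_rate) == (unique, rate)


def test_recovery_validates_inputs():
    with pytest.raises(ValueError):
        duplex_recovery(3, 5, 4)
    with pytest.raises(ValueError):
        duplex_recovery(-1, 5, 0)


def test_recovery_monotone_in_duplex_count():
    rates = [duplex_recovery(100, 100, d).recovery_rate for d in range(0, 101, 10)]
    assert rates == sorted(rates)


def test_mispairing_profile_counts_constructed_duplex():
    plus, minus = _true_pair(mispairs5=(1,), mispairs3=(7,))
    dup = build_duplex_consensus(plus, minus)
    assert dup.mispairing_positions == (1, 19)  # 5' pos 1, 3' pos 7 -> 12+7
    prof = mispairing_profile([dup])
    assert prof.histogram_full == {2: 1}
    assert prof.histogram_terminal == {1: 1}  # only position 19 is terminal
    assert prof.per_position_frequency[1] == 1.0
    assert prof.per_position_frequency[19] == 1.0


def test_mispairing_profile_zero_rates_all_zero():
    plus, minus = _true_pair()
    prof = mispairing_profile([build_duplex_consensus(plus, minus)])
    assert all(f == 0.0 for f in prof.per_position_frequency)
    assert prof.histogram_full == {0: 1}
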