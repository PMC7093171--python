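import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrmine.mining import (
    MiningThresholds,
    find_perfect_ssrs,
    loci_to_frame,
    read_loci_tsv,
    write_loci_tsv,
)
from ssrmine.motifs import revcomp

from _oracles import brute_force_ssrs

DEFAULT = MiningThresholds()


def test_mono_run_between_flanks():
    loci = find_perfect_ssrs("GGC" + "A" * 12 + "CGG")
    assert len(loci) == 1
    l = loci[0]
    assert (l.start, l.end, l.motif, l.canonical_motif, l.rcn) == (4, 15, "A", "A", 12)


def test_whole_sequence_dinucleotide():
    (l,) = find_perfect_ssrs("AC" * 7)
    assert (l.canonical_motif, l.rcn, l.length_bp) == ("AC", 7, 14)


def test_below_threshold_not_reported():
    assert find_perfect_ssrs("ATATATAT") == []


def test_trailing_partial_unit_truncated():
    (l,) = find_perfect_ssrs("G" + "AC" * 7 + "A" + "GGG")
    assert (l.start, l.end, l.rcn) == (2, 15, 7)  # trailing A excluded


def test_n_terminates_runs_and_case_ignored():
    seq = "a" * 6 + "N" + "a" * 12
    (l,) = find_perfect_ssrs(seq)
    assert (l.start, l.end, l.motif) == (8, 19, "A")


def test_invalid_character_names_position():
    with pytest.raises(ValueError, match="position 5"):
        find_perfect_ssrs("ACGTX" + "A" * 12)


def test_empty_sequence():
    assert find_perfect_ssrs("") == []


def test_smallest_primitive_unit_reported():
    # (AC)x8 is also (ACAC)x4 but must be reported with the 2 bp unit
    (l,) = find_perfect_ssrs("AC" * 8)
    assert l.unit_length == 2


def _random_seq(rng, n, gc=0.5, with_n=False):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=n, p=p))
    if with_n:
        i = int(rng.integers(0, n - 10))
        seq = seq[:i] + "N" * 5 + seq[i + 5 :]
    return seq


def test_oracle_equivalence_random_sequences(rng):
    """Mining equals the exhaustive scalar scan on random sequences with
    low-complexity patches (which guarantee some hits)."""
    thr = MiningThresholds({1: 6, 2: 4, 3: 3, 4: 3, 5: 2, 6: 2})
    for rep in range(30):
        seq = _random_seq(rng, 800, gc=float(rng.uniform(0.3, 0.7)), with_n=rep % 3 == 0)
        # splice in low-complexity material so candidates are plentiful
        i = int(rng.integers(0, 700))
        seq = seq[:i] + "TA" * 6 + seq[i:]
        got = [(l.start, l.end, l.motif) for l in find_perfect_ssrs(seq, thr)]
        assert got == brute_force_ssrs(seq, thr.min_rcn)


def test_revcomp_symmetry(rng):
    """Mining the reverse complement yields the same canonical-motif
    multiset with mirrored coordinates (up to the phase of a trailing
    partial unit, which trimming moves to the other end of the run)."""
    for _ in range(10):
        seq = _random_seq(rng, 500) + "GT" * 9 + _random_seq(rng, 100)
        fwd = find_perfect_ssrs(seq)
        rev = find_perfect_ssrs(revcomp(seq))
        assert sorted(l.canonical_motif for l in fwd) == sorted(
            l.canonical_motif for l in rev
        )
        n = len(seq)
        mirrored = sorted(
            (n - l.end + 1, n - l.start + 1, l.canonical_motif, l.unit_length)
            for l in fwd
        )
        observed = sorted((l.start, l.end, l.canonical_motif, l.unit_length) for l in rev)
        for (ms, me, mc, mk), (os_, oe, oc, ok) in zip(mirrored, observed):
            assert (mc, mk) == (oc, ok)
            assert me - ms == oe - os_  # identical span length
            assert abs(ms - os_) < mk  # shifted at most one partial unit


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=0, max_size=120), st.integers(0, 3))
def test_property_oracle_equivalence(seq, pad):
    """Hypothesis-generated sequences (with N) match the brute-force scan."""
    seq = seq + "A" * (12 + pad)
    thr = MiningThresholds({1: 5, 2: 3, 3: 2, 4: 2, 5: 2, 6: 2})
    got = [(l.start, l.end, l.motif) for l in find_perfect_ssrs(seq, thr)]
    assert got == brute_force_ssrs(seq, thr.min_rcn)


def test_loci_invariants(default_sim):
    import ssrmine

    for sid, seq in default_sim.sequences.items():
        loci = ssrmine.find_perfect_ssrs(seq, seq_id=sid)
        last_end = 0
        for l in loci:
            assert l.length_bp == l.unit_length * l.rcn
            assert l.start > last_end  # non-overlapping, sorted
            last_end = l.end
            assert seq[l.start - 1 : l.end] == l.motif * l.rcn


def test_threshold_parsing_and_validation():
    thr = MiningThresholds.from_string("12,7,5,4,4,4")
    assert thr.min_rcn[1] == 12 and thr.min_rcn[6] == 4
    with pytest.raises(ValueError):
        MiningThresholds.from_string("12,7")
    with pytest.raises(ValueError):
        MiningThresholds({1: 1, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4})


def test_tsv_round_trip(tmp_path):
    loci = find_perfect_ssrs("GGC" + "A" * 12 + "CGG" + "AC" * 9, seq_id="s1")
    path = tmp_path / "loci.tsv"
    write_loci_tsv(loci, path, header_lines=["test"])
    assert read_loci_tsv(path) == loci
    df = loci_to_frame(loci)
    assert list(df["length_bp"]) == [l.length_bp for l in loci]
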