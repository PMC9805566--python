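"""Seed-level detection: k-mer enumeration, window indexing, pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irscan import enumerate_kmers, hamming, kmer_space_size, pair_windows, scan_windows
from irscan.core import hamming1_neighbors

from conftest import naive_pairs


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("CCCCGTG", "CCCCGTG", 0),
        ("CCCCGTG", "CCCCGTA", 1),
        ("AAAAAAA", "AAGGAAA", 2),
    ],
)
def test_hamming_counts_substitutions(a, b, expected):
    assert hamming(a, b) == expected


def test_hamming_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        hamming("ACGT", "ACG")


def test_kmer_enumeration_is_complete_and_ordered():
    assert enumerate_kmers(1) == ["A", "C", "G", "T"]
    k2 = enumerate_kmers(2)
    assert len(k2) == 16 and k2[0] == "AA" and k2[-1] == "TT"
    k7 = enumerate_kmers(7)
    assert len(k7) == 16384 == len(set(k7)) == kmer_space_size(7)
    with pytest.raises(ValueError):
        enumerate_kmers(0)


def test_hamming1_neighborhood_size_and_distance():
    nbrs = list(hamming1_neighbors("ACGTACG"))
    assert len(nbrs) == 3 * 7
    assert len({n for n, _ in nbrs}) == 21
    assert all(hamming("ACGTACG", n) == 1 for n, _ in nbrs)


def test_scan_windows_slides_and_excludes_n():
    assert scan_windows("AAAA", 3) == {"AAA": [0, 1]}
    assert scan_windows("AANAA", 3) == {}


def test_scan_windows_counts_match_direct_recount():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGTN"), size=10_000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    k = 7
    index = scan_windows(seq, k)
    n_free = sum("N" not in seq[i : i + k] for i in range(len(seq) - k + 1))
    assert sum(len(v) for v in index.values()) == n_free
    for kmer, positions in index.items():
        assert positions == sorted(positions)
        assert all(seq[p : p + k] == kmer for p in positions)


def test_pair_windows_finds_planted_exact_pair():
    seq = "CCCCGTG" + "A" * 10 + "CCCCGTG"
    recs = pair_windows(scan_windows(seq, 7), 7, 1000, True)
    assert [(r.start1, r.start2, r.spacer, r.mismatches) for r in recs] == [(0, 17, 10, 0)]
    assert recs[0].seq1 == recs[0].seq2 == "CCCCGTG"


def test_pair_windows_mismatch_pairs_match_enumeration():
    # direct enumeration of this 17 bp string yields three 1-mismatch pairs,
    # among them the planted (0, 10) pair with its mismatch at offset 6
    seq = "AAAAAAA" + "CCC" + "AAAAAAT"
    recs = pair_windows(scan_windows(seq, 7), 7, 1000, True)
    got = {(r.start1, r.start2, r.mismatches, r.mismatch_offset) for r in recs}
    assert got == {(0, 9, 1, 0), (0, 10, 1, 6), (1, 10, 1, 6)}
    assert set(naive_pairs(seq, 7, 1000, True)) == {(0, 9, 1), (0, 10, 1), (1, 10, 1)}
    assert pair_windows(scan_windows(seq, 7), 7, 1000, False) == []


def test_pair_windows_spacer_boundary():
    for spacer, expect in [(1000, 1), (1001, 0)]:
        seq = "CCCCGTG" + "A" * spacer + "CCCCGTG"
        recs = pair_windows(scan_windows(seq, 7), 7, 1000, True)
        planted = [r for r in recs if (r.start1, r.start2) == (0, 7 + spacer)]
        assert len(planted) == expect


dna = st.text(alphabet="ACGTN", min_size=20, max_size=300)


@settings(max_examples=60, deadline=None)
@given(seq=dna, k=st.integers(7, 9), max_spacer=st.integers(0, 60),
       allow=st.booleans())
def test_pair_windows_equals_naive_enumeration(seq, k, max_spacer, allow):
    """The bucketed pairing is exactly the all-pairs predicate scan."""
    if len(seq) < k:
        return
    recs = pair_windows(scan_windows(seq, k), k, max_spacer, allow)
    got = [(r.start1, r.start2, r.mismatches) for r in recs]
    assert got == naive_pairs(seq, k, max_spacer, allow)


@settings(max_examples=40, deadline=None)
@given(seq=dna, k=st.integers(7, 8))
def test_exact_mode_is_the_mismatch_free_subset(seq, k):
    if len(seq) < k:
        return
    with_mm = pair_windows(scan_windows(seq, k), k, 50, True)
    without = pair_windows(scan_windows(seq, k), k, 50, False)
    assert without == [r for r in with_mm if r.mismatches == 0]


_RC = str.maketrans("ACGTN", "TGCAN")


@settings(max_examples=40, deadline=None)
@given(seq=dna, k=st.integers(7, 8))
def test_reverse_complement_symmetry(seq, k):
    """Scanning the reverse complement mirrors coordinates and swaps the copies."""
    if len(seq) < k:
        return
    n = len(seq)
    fwd = pair_windows(scan_windows(seq, k), k, 50, True)
    rc = seq.translate(_RC)[::-1]
    rev = pair_windows(scan_windows(rc, k), k, 50, True)
    mirrored = {(n - r.start2 - k, n - r.start1 - k, r.mismatches) for r in rev}
    assert {(r.start1, r.start2, r.mismatches) for r in fwd} == mirrored


@settings(max_examples=40, deadline=None)
@given(seq=dna, k=st.integers(7, 8))
def test_no_coordinate_pair_emitted_twice(seq, k):
    """A 1-mismatch pair is reachable from two k-mer buckets but appears once."""
    if len(seq) < k:
        return
    recs = pair_windows(scan_windows(seq, k), k, 60, True)
    coords = [(r.start1, r.start2) for r in recs]
    assert len(coords) == len(set(coords))
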