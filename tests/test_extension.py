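"""Inductive growth of the repeat length and whole-database construction."""

import pytest

from irscan import (
    GenomeSequence,
    IRSRecord,
    TranscriptModel,
    build_database,
    extend_once,
    pair_windows,
    scan_windows,
)
from irscan.errors import InputError
from irscan.exome import assign_genes
from irscan.extension import iter_levels
from irscan.oracle import brute_force_pairs


def _genome(seq, name="chrT"):
    return GenomeSequence(name=name, seq=seq)


def test_extend_grows_both_copies_rightward():
    seq = "CCCCGTGA" + "A" * 9 + "CCCCGTGA"
    g = _genome(seq)
    k7 = pair_windows(scan_windows(g, 7), 7, 1000, True, chrom="chrT")
    k8 = extend_once(k7, g, 1000)
    target = [r for r in k8 if (r.start1, r.start2) == (0, 17)]
    assert len(target) == 1
    r = target[0]
    assert r.k == 8 and r.seq1 == r.seq2 == "CCCCGTGA" and r.spacer == 9
    # independent direct scan at k=8 finds the same single record there
    direct = [
        (p.start1, p.start2, p.mismatches)
        for p in brute_force_pairs(seq, 8, 1000, True)
        if (p.start1, p.start2) == (0, 17)
    ]
    assert direct == [(0, 17, 0)]


def test_extension_stops_after_a_second_mismatch():
    # copies differ at offset 0 already; the next bases differ too
    seq = "TAAAAAA" + "CG" + "AAAAAAA" + "T"
    g = _genome(seq)
    rec = IRSRecord(
        chrom="chrT", k=7, start1=0, start2=9, seq1="TAAAAAA", seq2="AAAAAAA",
        mismatches=1, mismatch_offset=0,
    )
    assert extend_once([rec], g, 1000) == []


def test_extension_requires_room_in_the_spacer():
    seq = "AACCGGTAACCGGTA"
    rec = IRSRecord(
        chrom="chrT", k=7, start1=0, start2=7, seq1="AACCGGT", seq2="AACCGGT",
        mismatches=0,
    )
    assert rec.spacer == 0
    assert extend_once([rec], _genome(seq), 1000) == []


def test_extension_rejects_mixed_lengths():
    r7 = IRSRecord("chrT", 7, 0, 8, "AAAAAAA", "AAAAAAA", 0)
    r8 = IRSRecord("chrT", 8, 0, 9, "AAAAAAAA", "AAAAAAAA", 0)
    with pytest.raises(ValueError):
        extend_once([r7, r8], _genome("A" * 20), 1000)


def test_degenerate_build_equals_seed_pairing_plus_filter(std_fixture):
    genome, transcripts, _, _ = std_fixture
    db = build_database(genome, transcripts, kmin=7, kmax=7)
    seed = pair_windows(scan_windows(genome, 7), 7, 1000, True, chrom=genome.name)
    direct = assign_genes(seed, transcripts)
    assert set(db.records) == set(direct.records)


def test_build_rejects_unknown_annotation_contig():
    t = TranscriptModel("G", "T1", "chrMissing", "+", 0, 100, ((0, 100),))
    with pytest.raises(InputError):
        build_database(_genome("ACGT" * 10), [t])


def test_unrepeated_genome_yields_empty_table():
    # the only two N-free windows are far beyond Hamming distance 1
    seq = "ACGTACG" + "N" + "CCTTGAC"
    t = TranscriptModel("G", "T1", "chrT", "+", 0, len(seq), ((0, len(seq)),))
    db = build_database(_genome(seq), [t], kmin=7, kmax=20)
    assert len(db) == 0


def test_mismatches_never_decrease_along_extension_chains(std_fixture):
    genome, _, _, _ = std_fixture
    prev = None
    for _, cands in iter_levels(genome, 7, 10):
        state = {(r.start1, r.start2): r.mismatches for r in cands}
        if prev is not None:
            for coords, mism in state.items():
                assert mism >= prev[coords]
                assert mism <= 1
        prev = state


def test_candidate_start_pairs_shrink_with_length(std_fixture):
    genome, _, _, _ = std_fixture
    prev = None
    for _, cands in iter_levels(genome, 7, 12):
        pairs = {(r.start1, r.start2) for r in cands}
        if prev is not None:
            assert pairs <= prev
        prev = pairs


def test_seed_level_filtering_is_a_strict_compatibility_mode(std_fixture):
    """Filtering once at the seed length can only lose records vs per-level."""
    genome, transcripts, _, _ = std_fixture
    per_level = build_database(genome, transcripts, kmin=7, kmax=10)
    at_seed = build_database(
        genome, transcripts, kmin=7, kmax=10, filter_per_level=False
    )
    assert set(at_seed.records) <= set(per_level.records)
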