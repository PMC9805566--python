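"""Seed-level detection of interspersed repeat structures.

An interspersed repeat structure (IRS) is a pair of same-length direct
repeats, identical or differing at exactly one position, separated by a
spacer of bounded length. This module enumerates the k-mer seed space,
indexes a contig's windows by their k-mer, and pairs window occurrences
into IRS candidates under the Hamming and spacer constraints.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from typing import Iterator, Mapping, Sequence, Union

from .models import GenomeSequence, IRSRecord

BASES = "ACGT"


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length base strings differ.

    Both strings must be over {A,C,G,T}; windows containing N never enter
    repeat comparisons.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming() requires equal lengths, got {len(a)} and {len(b)}")
    if "N" in a or "N" in b:
        raise ValueError("hamming() operands must not contain N")
    return sum(x != y for x, y in zip(a, b))


def kmer_space_size(k: int) -> int:
    """Closed-form count of distinct k-length sequences over {A,C,G,T}."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 4**k


def enumerate_kmers(k: int) -> list[str]:
    """All 4^k base strings of length k, in lexicographic order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def hamming1_neighbors(kmer: str) -> Iterator[tuple[str, int]]:
    """Yield the 3k strings at Hamming distance exactly 1, with the differing offset."""
    for i, base in enumerate(kmer):
        for sub in BASES:
            if sub != base:
                yield kmer[:i] + sub + kmer[i + 1 :], i


def scan_windows(
    genome: Union[GenomeSequence, str], k: int
) -> dict[str, list[int]]:
    """Index every N-free k-window of a contig by its k-mer.

    Returns a mapping from k-mer to the ascending list of 0-based start
    offsets; windows containing N are absent from every bucket.
    """
    seq = genome.seq if isinstance(genome, GenomeSequence) else genome
    n = len(seq)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds contig length {n}")
    index: dict[str, list[int]] = {}
    # next_n[i] = smallest j >= i with seq[j] == 'N' (n if none): a window at
    # i is valid iff next_n[i] >= i + k.
    next_n = n
    starts_valid = [False] * (n - k + 1)
    for i in range(n - 1, -1, -1):
        if seq[i] == "N":
            next_n = i
        if i <= n - k:
            starts_valid[i] = next_n >= i + k
    for i in range(n - k + 1):
        if starts_valid[i]:
            index.setdefault(seq[i : i + k], []).append(i)
    return index


def pair_windows(
    index: Mapping[str, Sequence[int]],
    k: int,
    max_spacer: int,
    allow_mismatch: bool = True,
    chrom: str = "",
) -> list[IRSRecord]:
    """Pair indexed window occurrences into unannotated IRS records.

    Exact pairs come from within one k-mer bucket. Mismatch pairs come from
    joining buckets of k-mers at Hamming distance exactly 1; to emit each
    coordinate pair once, a cross-bucket join is performed only from the
    lexicographically smaller of the two k-mers. Copies never overlap
    (spacer >= 0) and a window is never paired with itself.
    """
    if max_spacer < 0:
        raise ValueError("max_spacer must be >= 0")
    out: list[IRSRecord] = []

    def emit(s1: int, s2: int, q1: str, q2: str, mism: int, off: int | None) -> None:
        out.append(
            IRSRecord(
                chrom=chrom,
                k=k,
                start1=s1,
                start2=s2,
                seq1=q1,
                seq2=q2,
                mismatches=mism,
                mismatch_offset=off,
            )
        )

    for kmer in index:
        positions = index[kmer]
        for i, p in enumerate(positions):
            lo = p + k
            hi = p + k + max_spacer
            for q in positions[i + 1 :]:
                if q > hi:
                    break
                if q >= lo:
                    emit(p, q, kmer, kmer, 0, None)

    if allow_mismatch:
        for kmer in index:
            a_positions = index[kmer]
            for neighbor, offset in hamming1_neighbors(kmer):
                if neighbor <= kmer:
                    continue  # canonical-bucket rule: emit from the smaller k-mer
                b_positions = index.get(neighbor)
                if not b_positions:
                    continue
                for p in a_positions:
                    lo = bisect_left(b_positions, p + k)
                    hi = bisect_right(b_positions, p + k + max_spacer)
                    for q in b_positions[lo:hi]:
                        emit(p, q, kmer, neighbor, 1, offset)
                for q in b_positions:
                    lo = bisect_left(a_positions, q + k)
                    hi = bisect_right(a_positions, q + k + max_spacer)
                    for p in a_positions[lo:hi]:
                        emit(q, p, neighbor, kmer, 1, offset)

    out.sort(key=lambda r: (r.start1, r.start2))
    return out
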