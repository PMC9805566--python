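"""Brute-force ground truth for repeat-pair detection.

This module recomputes, for a single repeat length, the exact set of repeat
pairs by directly comparing every pair of windows at every admissible
separation, and re-applies the exome selection rule by naive interval
arithmetic. It deliberately shares no pairing or classification logic with
:mod:`irscan.core`, :mod:`irscan.extension` or :mod:`irscan.exome`: it is the
independent oracle those modules are tested against, and is only usable at
desk scale (a hard size guard refuses contigs above 100 kb).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import OracleGuardError
from .models import GenomeSequence, IRSRecord, IRSTable, TranscriptModel

#: Largest contig the O(n * max_spacer * k) scan will accept.
ORACLE_MAX_BP = 100_000


def brute_force_pairs(
    seq: str,
    k: int,
    max_spacer: int = 1000,
    allow_mismatch: bool = True,
    chrom: str = "",
) -> list[IRSRecord]:
    """All repeat pairs at one length by direct window-vs-window comparison.

    For every start separation ``d`` in ``[k, k + max_spacer]`` the two window
    diagonals are compared base by base (vectorized over start position);
    windows containing N are masked out.
    """
    n = len(seq)
    if n > ORACLE_MAX_BP:
        raise OracleGuardError(
            f"brute-force oracle refuses contigs over {ORACLE_MAX_BP} bp (got {n})"
        )
    if k < 1 or k > n:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    ncum = np.concatenate(([0], np.cumsum(is_n)))
    valid = (ncum[k:] - ncum[:-k]) == 0  # valid[i]: window at i is N-free
    limit = 1 if allow_mismatch else 0
    out: list[IRSRecord] = []
    for d in range(k, k + max_spacer + 1):
        nstarts = n - d - k + 1
        if nstarts <= 0:
            break
        mism = np.zeros(nstarts, dtype=np.int16)
        for o in range(k):
            mism += arr[o : o + nstarts] != arr[d + o : d + o + nstarts]
        ok = (mism <= limit) & valid[:nstarts] & valid[d : d + nstarts]
        for i in np.flatnonzero(ok):
            i = int(i)
            s1, s2 = i, i + d
            q1, q2 = seq[s1 : s1 + k], seq[s2 : s2 + k]
            diff = [p for p in range(k) if q1[p] != q2[p]]
            out.append(
                IRSRecord(
                    chrom=chrom,
                    k=k,
                    start1=s1,
                    start2=s2,
                    seq1=q1,
                    seq2=q2,
                    mismatches=len(diff),
                    mismatch_offset=diff[0] if diff else None,
                )
            )
    out.sort(key=lambda r: (r.start1, r.start2))
    return out


def _classify_naive(rec: IRSRecord, t: TranscriptModel) -> Optional[str]:
    """Selection rule by plain loops, written independently of the production filter."""
    wins = [(rec.start1, rec.start1 + rec.k), (rec.start2, rec.start2 + rec.k)]
    if any(s < t.start or e > t.end for s, e in wins):
        return None
    for s, e in wins:
        for es, ee in t.exons:
            if max(s, es) < min(e, ee):
                return "exon_overlap"
    intron_of = []
    introns = list(t.introns)
    for s, e in wins:
        hit = None
        for j, (is_, ie) in enumerate(introns):
            if is_ <= s and e <= ie:
                hit = j
        intron_of.append(hit)
    a, b = intron_of
    if a is not None and b is not None and a != b:
        return "intron_flanking"
    return None


def brute_force_irs(
    genome: GenomeSequence,
    transcripts: Sequence[TranscriptModel],
    k: int,
    max_spacer: int = 1000,
    allow_mismatch: bool = True,
) -> IRSTable:
    """Ground-truth exome-filtered IRS table at a single repeat length."""
    pairs = brute_force_pairs(
        genome.seq, k, max_spacer, allow_mismatch, chrom=genome.name
    )
    annotated: list[IRSRecord] = []
    for rec in pairs:
        assignments = []
        for t in transcripts:
            if t.chrom != rec.chrom:
                continue
            cls = _classify_naive(rec, t)
            if cls is not None:
                assignments.append((t.gene, t.transcript_id, cls))
        genes_done: set[str] = set()
        for gene, tx, cls in sorted(assignments):
            if gene in genes_done:
                continue
            genes_done.add(gene)
            annotated.append(rec.annotated(gene, tx, cls))
    return IRSTable.from_records(
        annotated,
        {"k": k, "max_spacer": max_spacer, "allow_mismatch": allow_mismatch},
    )
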