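"""Inductive extension of repeat length.

Directly enumerating all 4^k seeds becomes infeasible long before k = 20
(4^20 > 1e12). Instead, every (k+1)-repeat pair contains a k-repeat pair as
its prefix at the same start coordinates, so the k-level IRS set can be grown
one base at a time: both copies are extended one base rightward, start
positions anchored, and a pair survives iff the added bases keep the total
string distance at <= 1 and the shrinking spacer stays non-negative.

One boundary subtlety: a (k+1)-level pair with spacer s has a k-level parent
with spacer s+1, so a parent sitting exactly at the spacer cap would be
pruned and its child missed. Internal candidate generation therefore relaxes
the spacer bound by the number of extension steps still to come, and the
strict cap is applied per level at emission.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Iterator, Optional, Sequence, Union

from .core import pair_windows, scan_windows
from .errors import InputError
from .models import GenomeSequence, IRSRecord, IRSTable, TranscriptModel
from .exome import annotate_records


def extend_once(
    records: Sequence[IRSRecord],
    genome: GenomeSequence,
    max_spacer: int = 1000,
) -> list[IRSRecord]:
    """Derive the (k+1)-level candidate set from a uniform k-level set.

    A record extends iff the two added bases exist and are non-N, the added
    bases are equal whenever the record already carries a mismatch (a first
    mismatch is absorbed, a second is forbidden), and the spacer, which
    shrinks by one, stays within [0, max_spacer].
    """
    ks = {r.k for r in records}
    if len(ks) > 1:
        raise ValueError(f"extend_once requires a uniform repeat length, got {sorted(ks)}")
    seq = genome.seq
    n = len(seq)
    out: list[IRSRecord] = []
    for r in records:
        if r.start2 + r.k >= n:
            continue
        if r.spacer - 1 < 0 or r.spacer - 1 > max_spacer:
            continue
        b1 = seq[r.start1 + r.k]
        b2 = seq[r.start2 + r.k]
        if b1 == "N" or b2 == "N":
            continue
        if b1 != b2:
            if r.mismatches == 1:
                continue
            mism, off = 1, r.k
        else:
            mism, off = r.mismatches, r.mismatch_offset
        out.append(
            IRSRecord(
                chrom=r.chrom,
                k=r.k + 1,
                start1=r.start1,
                start2=r.start2,
                seq1=r.seq1 + b1,
                seq2=r.seq2 + b2,
                mismatches=mism,
                mismatch_offset=off,
            )
        )
    return out


def iter_levels(
    genome: GenomeSequence,
    kmin: int = 7,
    kmax: int = 20,
    max_spacer: int = 1000,
    allow_mismatch: bool = True,
    seed_candidates: Optional[Sequence[IRSRecord]] = None,
) -> Iterator[tuple[int, list[IRSRecord]]]:
    """Yield (k, candidates) for k = kmin..kmax on one contig.

    Candidates at level k are generated under the relaxed spacer bound
    ``max_spacer + (kmax - k)``; callers must apply the strict
    ``spacer <= max_spacer`` filter when emitting a level.
    """
    if kmin < 1 or kmax < kmin:
        raise ValueError("require 1 <= kmin <= kmax")
    if seed_candidates is None:
        index = scan_windows(genome, kmin)
        cands = pair_windows(
            index, kmin, max_spacer + (kmax - kmin), allow_mismatch, chrom=genome.name
        )
    else:
        cands = list(seed_candidates)
    k = kmin
    while True:
        yield k, cands
        if k == kmax:
            return
        cands = extend_once(cands, genome, max_spacer + (kmax - k - 1))
        if not allow_mismatch:
            # extension may absorb a first mismatch; in exact mode such
            # records are dropped (an exact pair always has an exact prefix,
            # so nothing downstream is lost)
            cands = [r for r in cands if r.mismatches == 0]
        k += 1


def _digest(parts: Iterable[str]) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p.encode())
        h.update(b"\x00")
    return h.hexdigest()[:16]


def build_database(
    genomes: Union[GenomeSequence, Sequence[GenomeSequence]],
    transcripts: Sequence[TranscriptModel],
    kmin: int = 7,
    kmax: int = 20,
    max_spacer: int = 1000,
    allow_mismatch: bool = True,
    filter_per_level: bool = True,
) -> IRSTable:
    """Build the exome-filtered IRS table for every repeat length in [kmin, kmax].

    With ``filter_per_level`` (the default) the exome selection rule is
    re-applied at every emitted length, so the per-k output is identical to a
    direct per-k scan followed by the filter. With it off, the selection is
    applied once to the seed-length candidates and only the survivors are
    extended — the behaviour of filtering at the seed length before extension,
    which can miss structures whose windows only satisfy the rule after they
    have grown.
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    contig_names = {g.name for g in genomes}
    missing = {t.chrom for t in transcripts} - contig_names
    if missing:
        raise InputError(
            f"annotation references contigs absent from the genome: {sorted(missing)}"
        )
    params = {
        "kmin": kmin,
        "kmax": kmax,
        "max_spacer": max_spacer,
        "allow_mismatch": allow_mismatch,
        "filter_per_level": filter_per_level,
        "genome_digest": _digest(f"{g.name}:{g.seq}" for g in genomes),
        "annotation_digest": _digest(repr(t) for t in sorted(
            transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))),
    }
    annotated: list[IRSRecord] = []
    for genome in genomes:
        if len(genome.seq) < kmin:
            continue
        seed: Optional[list[IRSRecord]] = None
        if not filter_per_level:
            index = scan_windows(genome, kmin)
            raw = pair_windows(index, kmin, max_spacer, allow_mismatch, chrom=genome.name)
            kept = {
                (r.start1, r.start2) for r in annotate_records(raw, transcripts)
            }
            seed = [r for r in raw if (r.start1, r.start2) in kept]
        for _, cands in iter_levels(
            genome, kmin, kmax, max_spacer, allow_mismatch, seed_candidates=seed
        ):
            emitted = [r for r in cands if r.spacer <= max_spacer]
            annotated.extend(annotate_records(emitted, transcripts))
    return IRSTable.from_records(annotated, params)
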