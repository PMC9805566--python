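"""Exome selection rules.

A structure is tied to a gene when at least one repeat copy overlaps an
exon of that gene's transcript (by >= 1 bp), or when both copies lie fully
inside different introns, so that at least one exon sits between them and a
recombination between the copies would remove coding sequence. Everything
else — both copies in the same intron, copies outside the transcript span,
intergenic structures — is discarded.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .models import (
    EXON_OVERLAP,
    INTRON_FLANKING,
    REJECTED,
    IRSRecord,
    IRSTable,
    TranscriptModel,
)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _contained(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return b_start <= a_start and a_end <= b_end


def classify_irs(record: IRSRecord, transcript: TranscriptModel) -> str:
    """Classify one record against one transcript.

    Returns ``exon_overlap``, ``intron_flanking`` or ``rejected``. A window
    partially covering an exon counts as exonic ("located in an exon" is read
    as >= 1 bp overlap); "situated in an intron" requires full containment.
    Records with any window outside the transcript span are rejected.
    """
    if record.chrom != transcript.chrom:
        raise ValueError(
            f"record on {record.chrom} classified against transcript on "
            f"{transcript.chrom}"
        )
    windows = ((record.start1, record.end1), (record.start2, record.end2))
    for ws, we in windows:
        if not _contained(ws, we, transcript.start, transcript.end):
            return REJECTED
    for ws, we in windows:
        for es, ee in transcript.exons:
            if _overlaps(ws, we, es, ee):
                return EXON_OVERLAP
    introns = transcript.introns
    homes = []
    for ws, we in windows:
        home = None
        for idx, (is_, ie) in enumerate(introns):
            if _contained(ws, we, is_, ie):
                home = idx
                break
        homes.append(home)
    if homes[0] is not None and homes[1] is not None and homes[0] != homes[1]:
        return INTRON_FLANKING
    return REJECTED


def annotate_records(
    records: Iterable[IRSRecord], transcripts: Sequence[TranscriptModel]
) -> list[IRSRecord]:
    """Annotate each record with every gene whose selection rule it satisfies.

    A record satisfying the rule for several overlapping genes is duplicated,
    once per gene; within one gene, ties between transcripts are broken by
    transcript_id so the assignment is deterministic.
    """
    trees: dict[str, IntervalTree] = {}
    for t in sorted(transcripts, key=lambda t: (t.gene, t.transcript_id)):
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t)
    out: list[IRSRecord] = []
    for rec in records:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        hits = []
        for iv in tree.overlap(rec.start1, rec.end2):
            t = iv.data
            cls = classify_irs(rec, t)
            if cls != REJECTED:
                hits.append((t.gene, t.transcript_id, cls))
        seen_genes: set[str] = set()
        for gene, tx, cls in sorted(hits):
            if gene in seen_genes:
                continue
            seen_genes.add(gene)
            out.append(rec.annotated(gene, tx, cls))
    return out


def assign_genes(
    records: Iterable[IRSRecord],
    transcripts: Sequence[TranscriptModel],
    params: Optional[Mapping[str, object]] = None,
) -> IRSTable:
    """Annotate records against the transcript set and build a deduplicated table."""
    return IRSTable.from_records(annotate_records(records, transcripts), params)
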