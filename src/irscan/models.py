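"""Core data model.

Coordinates are 0-based half-open everywhere in memory; conversion to the
1-based inclusive convention happens only when tables are written out
(see :mod:`irscan.genome_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional

#: Selection classes assigned by the exome filter.
EXON_OVERLAP = "exon_overlap"
INTRON_FLANKING = "intron_flanking"
REJECTED = "rejected"

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True, slots=True)
class GenomeSequence:
    """A named contig over the normalized alphabet {A, C, G, T, N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("contig name must be non-empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.name!r} contains unnormalized characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, slots=True)
class TranscriptModel:
    """A gene's canonical transcript: genomic span plus ordered exon blocks.

    Introns are derived from consecutive exon pairs and never stored.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"exon [{s}, {e}) not contained in span "
                    f"[{self.start}, {self.end}) of {self.transcript_id}"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, in order."""
        pairs = zip(self.exons, self.exons[1:])
        return tuple(
            (a_end, b_start) for (_, a_end), (b_start, _) in pairs if a_end < b_start
        )

    @property
    def span_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class RepeatWindow:
    """One repeat copy: a k-base window on a contig."""

    chrom: str
    start: int
    k: int
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != self.k:
            raise ValueError("window sequence length must equal k")
        if "N" in self.seq:
            raise ValueError("repeat windows may not contain N")

    @property
    def end(self) -> int:
        return self.start + self.k


@dataclass(frozen=True, slots=True)
class IRSRecord:
    """One interspersed repeat structure.

    Two same-length direct-repeat copies (``start1 < start2``) separated by a
    spacer; the copies are identical or differ at exactly one position.
    ``gene``, ``transcript_id`` and ``selection`` are absent until the exome
    filter assigns them.
    """

    chrom: str
    k: int
    start1: int
    start2: int
    seq1: str
    seq2: str
    mismatches: int
    mismatch_offset: Optional[int] = None
    gene: Optional[str] = None
    transcript_id: Optional[str] = None
    selection: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq1) != self.k or len(self.seq2) != self.k:
            raise ValueError("repeat sequences must have length k")
        if self.start1 >= self.start2:
            raise ValueError("start1 must precede start2")
        if self.spacer < 0:
            raise ValueError("repeat copies must not overlap")
        if self.mismatches not in (0, 1):
            raise ValueError("mismatches must be 0 or 1")
        diff = [i for i in range(self.k) if self.seq1[i] != self.seq2[i]]
        if len(diff) != self.mismatches:
            raise ValueError(
                f"declared {self.mismatches} mismatches but sequences differ at {diff}"
            )
        if self.mismatches == 1 and self.mismatch_offset != diff[0]:
            raise ValueError("mismatch_offset inconsistent with sequences")
        if self.mismatches == 0 and self.mismatch_offset is not None:
            raise ValueError("mismatch_offset must be absent for exact repeats")

    @property
    def end1(self) -> int:
        return self.start1 + self.k

    @property
    def end2(self) -> int:
        return self.start2 + self.k

    @property
    def spacer(self) -> int:
        """Gap in bp between the end of copy 1 and the start of copy 2."""
        return self.start2 - self.start1 - self.k

    @property
    def w1(self) -> RepeatWindow:
        return RepeatWindow(self.chrom, self.start1, self.k, self.seq1)

    @property
    def w2(self) -> RepeatWindow:
        return RepeatWindow(self.chrom, self.start2, self.k, self.seq2)

    def annotated(self, gene: str, transcript_id: str, selection: str) -> "IRSRecord":
        return replace(
            self, gene=gene, transcript_id=transcript_id, selection=selection
        )

    def identity(self) -> tuple:
        """Deduplication key within a table."""
        return (self.chrom, self.k, self.start1, self.start2, self.gene)

    def sort_key(self) -> tuple:
        return (self.chrom, self.gene or "", self.k, self.start1, self.start2)


@dataclass(frozen=True, slots=True)
class IRSTable:
    """Deduplicated, sorted collection of IRS records plus build parameters."""

    records: tuple[IRSRecord, ...]
    params: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Iterable[IRSRecord], params: Optional[Mapping[str, object]] = None
    ) -> "IRSTable":
        ordered = sorted(records, key=lambda r: (r.sort_key(), r.transcript_id or ""))
        seen: set[tuple] = set()
        kept: list[IRSRecord] = []
        for rec in ordered:
            key = rec.identity()
            if key in seen:
                continue
            seen.add(key)
            kept.append(rec)
        return cls(records=tuple(kept), params=dict(params or {}))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IRSRecord]:
        return iter(self.records)

    def at_length(self, k: int) -> tuple[IRSRecord, ...]:
        return tuple(r for r in self.records if r.k == k)

    def for_gene(self, gene: str) -> tuple[IRSRecord, ...]:
        return tuple(r for r in self.records if r.gene == gene)


@dataclass(frozen=True, slots=True)
class QueryParams:
    """Parameters of a per-gene lookup."""

    gene: str
    lengths: tuple[int, ...]
    min_dist: int = 0
    max_dist: int = 1000
    allow_mismatch: bool = True

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("at least one repeat length must be requested")
        if self.min_dist < 0:
            raise ValueError("min_dist must be >= 0")
        if self.min_dist > self.max_dist:
            raise ValueError("min_dist must not exceed max_dist")


@dataclass(frozen=True, slots=True)
class GeneSummaryRow:
    """Per-gene, per-repeat-length summary of retained structures."""

    gene: str
    repeat_length: int
    n_irs: int
    mean_distance: Optional[float]
    irs_per_mb: float
    has_mismatch: bool
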