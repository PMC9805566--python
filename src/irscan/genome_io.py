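"""Reading genomes and annotations; writing IRS tables.

Input carriers are plain-text FASTA and BED12 (one transcript per line, gene
symbol and transcript id joined as ``GENE|TRANSCRIPT`` in the name field).
Tables are written deterministically: identical tables produce byte-identical
files. Internal coordinates are 0-based half-open; TSV/CSV output uses the
1-based fully-closed convention of the genome browsers, converted only here
at the write/read boundary.
"""

from __future__ import annotations

import csv
import os
import re
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .errors import FormatError
from .models import GenomeSequence, IRSRecord, IRSTable, TranscriptModel

#: Column dictionary of the TSV/CSV table output.
TABLE_COLUMNS = (
    "chrom",
    "gene",
    "transcript",
    "repeat_length",
    "repeat1_start",
    "repeat1_end",
    "repeat2_start",
    "repeat2_end",
    "repeat1_seq",
    "repeat2_seq",
    "spacer_bp",
    "mismatch",
    "class",
)

_NON_ACGT = re.compile(r"[^ACGT]")


def normalize_sequence(raw: str) -> str:
    """Uppercase and collapse every non-ACGT character (IUPAC codes etc.) to N."""
    return _NON_ACGT.sub("N", raw.upper())


def read_fasta(path: str) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into normalized GenomeSequence records, in file order."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file, expected FASTA")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1 does not start with '>', not FASTA")
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        out.append(GenomeSequence(name=rec.id, seq=normalize_sequence(str(rec.seq))))
    return out


def write_fasta(genomes: Sequence[GenomeSequence], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, g.length, width):
                fh.write(g.seq[i : i + width] + "\n")


def read_annotation(path: str) -> list[TranscriptModel]:
    """Read BED12 transcript models.

    The name field is split on the first ``|`` into gene symbol and transcript
    id; a name without ``|`` serves as both. Exon intervals are reconstructed
    from blockStarts/blockSizes and kept 0-based half-open.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"{path}:{lineno}: blockCount={block_count} inconsistent with "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            name = fields[3]
            gene, _, tx = name.partition("|")
            if not tx:
                tx = gene
            exons = tuple(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            for es, ee in exons:
                if ee > end or es < start:
                    raise FormatError(
                        f"{path}:{lineno}: exon [{es},{ee}) extends beyond span "
                        f"[{start},{end})"
                    )
            try:
                out.append(
                    TranscriptModel(
                        gene=gene,
                        transcript_id=tx,
                        chrom=chrom,
                        strand=strand,
                        start=start,
                        end=end,
                        exons=exons,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_annotation(transcripts: Sequence[TranscriptModel], path: str) -> None:
    """Write transcript models as BED12 with GENE|TRANSCRIPT names."""
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.start) for s, e in t.exons)
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        f"{t.gene}|{t.transcript_id}",
                        "0",
                        t.strand,
                        str(t.start),
                        str(t.end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def _record_row(r: IRSRecord) -> list[str]:
    # 1-based inclusive coordinates in user-facing output.
    return [
        r.chrom,
        r.gene or "",
        r.transcript_id or "",
        str(r.k),
        str(r.start1 + 1),
        str(r.end1),
        str(r.start2 + 1),
        str(r.end2),
        r.seq1,
        r.seq2,
        str(r.spacer),
        str(r.mismatches),
        r.selection or "",
    ]


def write_irs_table(table: IRSTable, path: str, format: str = "tsv") -> None:
    """Write an IRS table as tsv, csv, or BED6 (one line per repeat window).

    Output is deterministic: the same table always produces the same bytes.
    """
    if format in ("tsv", "csv"):
        delim = "\t" if format == "tsv" else ","
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
            writer.writerow(TABLE_COLUMNS)
            for r in table:
                writer.writerow(_record_row(r))
    elif format == "bed":
        with open(path, "w") as fh:
            for r in table:
                base = f"{r.gene or '.'}|k{r.k}|{r.selection or '.'}"
                for tag, s, e, mate in (
                    ("r1", r.start1, r.end1, r.start2),
                    ("r2", r.start2, r.end2, r.start1),
                ):
                    name = f"{base}|{tag}|mate:{mate + 1}"
                    fh.write(
                        f"{r.chrom}\t{s}\t{e}\t{name}\t{r.mismatches}\t+\n"
                    )
    else:
        raise ValueError(f"unknown table format: {format!r}")


def read_irs_table(path: str, format: str = "tsv") -> IRSTable:
    """Re-parse a tsv/csv table written by :func:`write_irs_table`."""
    delim = "\t" if format == "tsv" else ","
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader, None)
        if header is None or tuple(header) != TABLE_COLUMNS:
            raise FormatError(f"{path}: missing or unexpected table header")
        for row in reader:
            if len(row) != len(TABLE_COLUMNS):
                raise FormatError(f"{path}: row with {len(row)} columns")
            (chrom, gene, tx, k, s1, e1, s2, e2, q1, q2, spacer, mism, cls) = row
            k = int(k)
            diff = [i for i in range(k) if q1[i] != q2[i]]
            records.append(
                IRSRecord(
                    chrom=chrom,
                    k=k,
                    start1=int(s1) - 1,
                    start2=int(s2) - 1,
                    seq1=q1,
                    seq2=q2,
                    mismatches=int(mism),
                    mismatch_offset=diff[0] if diff else None,
                    gene=gene or None,
                    transcript_id=tx or None,
                    selection=cls or None,
                )
            )
    return IRSTable.from_records(records)
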