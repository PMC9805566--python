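"""Per-gene lookup over a built IRS table.

Mirrors the interactive query layer: filter the table by gene, repeat
length, spacer-distance bounds and mismatch toggle, and report one summary
row per requested length (count, mean spacer, structures per megabase of the
transcript's genomic span, mismatch flag) alongside the detailed records.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .models import (
    GeneSummaryRow,
    IRSRecord,
    IRSTable,
    QueryParams,
    TranscriptModel,
)


def gene_lookup(
    db: IRSTable,
    transcripts: Sequence[TranscriptModel],
    params: QueryParams,
) -> tuple[list[GeneSummaryRow], list[IRSRecord]]:
    """Summary rows and detail records for one gene.

    An unknown gene raises ``LookupError`` (distinct from a gene with no
    structures, which yields zero-count rows). The per-megabase density is
    normalized by the genomic span of the gene's canonical transcript.
    """
    gene_txs = sorted(
        (t for t in transcripts if t.gene == params.gene),
        key=lambda t: t.transcript_id,
    )
    if not gene_txs:
        raise LookupError(f"unknown gene: {params.gene!r}")
    krange = None
    if "kmin" in db.params and "kmax" in db.params:
        krange = (int(db.params["kmin"]), int(db.params["kmax"]))
        for k in params.lengths:
            if not (krange[0] <= k <= krange[1]):
                raise ValueError(
                    f"repeat length {k} outside the built range {krange}"
                )
    if "max_spacer" in db.params and params.max_dist > int(db.params["max_spacer"]):
        raise ValueError(
            f"max_dist {params.max_dist} exceeds the build spacer cap "
            f"{db.params['max_spacer']}"
        )
    wanted = set(params.lengths)
    details = [
        r
        for r in db
        if r.gene == params.gene
        and r.k in wanted
        and params.min_dist <= r.spacer <= params.max_dist
        and (params.allow_mismatch or r.mismatches == 0)
    ]
    details.sort(key=lambda r: (r.k, r.start1, r.start2))
    span_bp = gene_txs[0].span_bp
    summary = []
    for k in sorted(wanted):
        recs = [r for r in details if r.k == k]
        n = len(recs)
        summary.append(
            GeneSummaryRow(
                gene=params.gene,
                repeat_length=k,
                n_irs=n,
                mean_distance=(sum(r.spacer for r in recs) / n) if n else None,
                irs_per_mb=n / (span_bp / 1e6),
                has_mismatch=any(r.mismatches == 1 for r in recs),
            )
        )
    return summary, details


def summary_frame(rows: Sequence[GeneSummaryRow]) -> pd.DataFrame:
    """Summary rows as a DataFrame; mean distances rounded to 2 dp for display."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "repeat_length": [r.repeat_length for r in rows],
            "n_irs": [r.n_irs for r in rows],
            "mean_distance": [
                None if r.mean_distance is None else round(r.mean_distance, 2)
                for r in rows
            ],
            "irs_per_mb": [round(r.irs_per_mb, 4) for r in rows],
            "has_mismatch": [r.has_mismatch for r in rows],
        }
    )
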