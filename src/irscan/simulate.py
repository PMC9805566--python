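"""Synthetic genomes with planted interspersed repeat structures.

The generator emits a random background sequence (i.i.d. bases at a chosen
GC fraction), plants repeat pairs at requested positions, and builds a
matching transcript annotation so that each plant realizes one of the
selection contexts: overlapping an exon, flanking an exon from two introns,
sitting inside a single intron (and therefore rejected), or intergenic.

Three measures keep the returned ``expected`` list exact rather than merely
likely. First, each planted copy is flanked by a single N guard base (before
copy 1, at the first and last spacer position, after copy 2): windows
straddling a copy boundary then contain an N and are excluded by definition,
killing the otherwise-unavoidable shifted pairs that share k-1 repeat bases.
N inside a spacer is legal — only the repeat windows themselves must be
N-free. Second, background windows in a neighborhood of each plant are
rejection-resampled so that no background 7-mer falls within Hamming
distance 1 of any 7-mer of the planted copies — chance partners for a
planted repeat cannot arise at any length (a longer near-match would contain
an aligned 7 bp near-match). Third, the neighborhood is re-scanned with the
brute-force oracle and the generator resamples until the repeat pairs
touching the planted copies are exactly the constructed ones at every length
up to one past the plant's own (so no accidental over-extension exists
either). Chance repeat structures elsewhere in the background are left
alone; they are legitimate detections and are covered by oracle-agreement
testing, not by the expected list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import hamming1_neighbors
from .models import (
    EXON_OVERLAP,
    INTRON_FLANKING,
    GenomeSequence,
    IRSRecord,
    IRSTable,
    TranscriptModel,
)
from .oracle import brute_force_pairs

#: Gene contexts a plant can be placed in.
CTX_EXONIC = "exonic"
CTX_INTRON_FLANKING = "intron_flanking"
CTX_SAME_INTRON = "same_intron"
CTX_INTERGENIC = "intergenic"
CONTEXTS = (CTX_EXONIC, CTX_INTRON_FLANKING, CTX_SAME_INTRON, CTX_INTERGENIC)

_BASES = "ACGT"
_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}

#: Sequence cleaned on each side of a plant: nothing outside this distance
#: can pair with a planted window at spacers up to 1000 and lengths up to 20.
REGION_PAD = 1020
_TRANSCRIPT_MARGIN = 300
_SEED_K = 7


@dataclass(frozen=True, slots=True)
class PlantSpec:
    """One planted repeat pair: two copies of ``repeat_seq`` around a spacer.

    ``mismatch_offset``, if given, mutates that position of the second copy.
    ``gene_context`` controls the transcript built around the plant and hence
    the expected selection class (or rejection).
    """

    repeat_seq: str
    spacer_len: int
    insert_at: int
    gene_context: str
    mismatch_offset: Optional[int] = None

    def __post_init__(self) -> None:
        L = len(self.repeat_seq)
        if not (7 <= L <= 20):
            raise ValueError("repeat_seq must be 7-20 bp")
        if set(self.repeat_seq) - set(_BASES):
            raise ValueError("repeat_seq must be over {A,C,G,T}")
        if self.spacer_len < 2:
            # the first and last spacer bases become N guards
            raise ValueError("planted spacers must be >= 2 bp")
        if self.gene_context not in CONTEXTS:
            raise ValueError(f"unknown gene_context {self.gene_context!r}")
        if self.gene_context == CTX_INTRON_FLANKING and self.spacer_len < 40:
            raise ValueError("intron_flanking plants need spacer_len >= 40")
        if self.mismatch_offset is not None and not (0 <= self.mismatch_offset < L):
            raise ValueError("mismatch_offset out of range")

    @property
    def length(self) -> int:
        return len(self.repeat_seq)

    @property
    def copy2_seq(self) -> str:
        if self.mismatch_offset is None:
            return self.repeat_seq
        i = self.mismatch_offset
        return (
            self.repeat_seq[:i]
            + _NEXT_BASE[self.repeat_seq[i]]
            + self.repeat_seq[i + 1 :]
        )

    @property
    def copy1_start(self) -> int:
        return self.insert_at

    @property
    def copy2_start(self) -> int:
        return self.insert_at + self.length + self.spacer_len

    @property
    def end(self) -> int:
        return self.copy2_start + self.length


def _check_self_similarity(plant: PlantSpec) -> None:
    """Reject repeat sequences whose sub-windows could pair with each other.

    Any two distinct same-length sub-windows (within or across the two
    copies) must be at Hamming distance >= 2, otherwise the plant itself
    would spawn repeat pairs beyond the constructed offset-aligned ones.
    """
    c1, c2 = plant.repeat_seq, plant.copy2_seq
    L = plant.length
    for k in range(_SEED_K, L + 1):
        for i in range(L - k + 1):
            for j in range(L - k + 1):
                pairs = []
                if i < j:
                    pairs += [(c1, i, c1, j), (c2, i, c2, j)]
                if i != j:
                    pairs.append((c1, i, c2, j))
                for sa, ia, sb, ib in pairs:
                    wa, wb = sa[ia : ia + k], sb[ib : ib + k]
                    if sum(x != y for x, y in zip(wa, wb)) <= 1:
                        raise ValueError(
                            f"repeat_seq {plant.repeat_seq!r} is self-similar at "
                            f"length {k} (offsets {ia}/{ib}); choose a less "
                            "repetitive sequence"
                        )


def _plant_neighborhood_kmers(plant: PlantSpec) -> frozenset[str]:
    """7-mers of both copies plus their full Hamming-1 neighborhoods."""
    out: set[str] = set()
    for copy in (plant.repeat_seq, plant.copy2_seq):
        for i in range(len(copy) - _SEED_K + 1):
            kmer = copy[i : i + _SEED_K]
            out.add(kmer)
            out.update(nb for nb, _ in hamming1_neighbors(kmer))
    return frozenset(out)


def _expected_for_plant(
    plant: PlantSpec, chrom: str, gene: Optional[str], tx: Optional[str]
) -> list[IRSRecord]:
    if plant.gene_context in (CTX_SAME_INTRON, CTX_INTERGENIC):
        return []
    selection = EXON_OVERLAP if plant.gene_context == CTX_EXONIC else INTRON_FLANKING
    c1, c2 = plant.repeat_seq, plant.copy2_seq
    L, mo = plant.length, plant.mismatch_offset
    out = []
    for k in range(_SEED_K, L + 1):
        for i in range(L - k + 1):
            has_mm = mo is not None and i <= mo < i + k
            out.append(
                IRSRecord(
                    chrom=chrom,
                    k=k,
                    start1=plant.copy1_start + i,
                    start2=plant.copy2_start + i,
                    seq1=c1[i : i + k],
                    seq2=c2[i : i + k],
                    mismatches=1 if has_mm else 0,
                    mismatch_offset=(mo - i) if has_mm else None,
                    gene=gene,
                    transcript_id=tx,
                    selection=selection,
                )
            )
    return out


def _build_transcript(
    plant: PlantSpec, idx: int, chrom: str, length: int
) -> Optional[TranscriptModel]:
    if plant.gene_context == CTX_INTERGENIC:
        return None
    a, L = plant.copy1_start, plant.length
    t_start = max(0, a - _TRANSCRIPT_MARGIN)
    t_end = min(length, plant.end + _TRANSCRIPT_MARGIN)
    if plant.gene_context == CTX_EXONIC:
        exons = ((max(t_start, a - 4), min(t_end, a + L + 4)),)
    elif plant.gene_context == CTX_INTRON_FLANKING:
        exons = (
            (t_start, t_start + 20),
            (a + L + 20, a + L + 40),
            (t_end - 20, t_end),
        )
    else:  # same_intron: exons only at the edges, both copies in one intron
        exons = ((t_start, t_start + 20), (t_end - 20, t_end))
    return TranscriptModel(
        gene=f"GENE{idx + 1}",
        transcript_id=f"TX{idx + 1}",
        chrom=chrom,
        strand="+",
        start=t_start,
        end=t_end,
        exons=exons,
    )


def _clean_region(
    arr: list[str],
    rs: int,
    re_: int,
    forbidden: frozenset[str],
    immutable: set[int],
    rng: np.random.Generator,
) -> None:
    """Resample mutable bases until no free-standing 7-mer collides with the plant."""
    for _ in range(200):
        dirty = False
        for p in range(rs, re_ - _SEED_K + 1):
            span = range(p, p + _SEED_K)
            if any(q in immutable for q in span):
                continue
            w = "".join(arr[p : p + _SEED_K])
            if "N" in w or w not in forbidden:
                continue
            dirty = True
            # window is fully mutable; resample a random position so any
            # single-offset difference from the plant can be escaped
            q = p + int(rng.integers(_SEED_K))
            arr[q] = _BASES[rng.integers(4)]
        if not dirty:
            return
    raise RuntimeError("plant neighborhood cleaning did not converge")


def _validate_plant(
    arr: list[str], plant: PlantSpec, rs: int, re_: int, max_spacer: int
) -> bool:
    """Check that repeat pairs touching the copies are exactly the constructed ones."""
    region = "".join(arr[rs:re_])
    L = plant.length
    c1s, c2s = plant.copy1_start - rs, plant.copy2_start - rs

    def touches(s: int, k: int) -> bool:
        return (s < c1s + L and c1s < s + k) or (s < c2s + L and c2s < s + k)

    for k in range(_SEED_K, min(L + 1, 20) + 1):
        found = {
            (r.start1, r.start2, r.mismatches)
            for r in brute_force_pairs(region, k, max_spacer, True)
            if touches(r.start1, k) or touches(r.start2, k)
        }
        if k <= L:
            mo = plant.mismatch_offset
            want = {
                (c1s + i, c2s + i, 1 if (mo is not None and i <= mo < i + k) else 0)
                for i in range(L - k + 1)
            }
        else:
            want = set()
        if found != want:
            return False
    return True


def generate_genome(
    length: int,
    gc: float = 0.41,
    seed: int = 0,
    plants: Sequence[PlantSpec] = (),
    chrom: str = "chrSim",
    max_spacer: int = 1000,
) -> tuple[GenomeSequence, list[TranscriptModel], list[IRSRecord]]:
    """Generate a genome with planted IRS, its annotation, and the exact expected records.

    Deterministic for a fixed seed. Plants must be far enough apart that
    their cleaned neighborhoods (±REGION_PAD bp) do not overlap.
    """
    if length < 1:
        raise ValueError("length must be positive")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    plants = sorted(plants, key=lambda p: p.insert_at)
    prev_end = None
    for p in plants:
        _check_self_similarity(p)
        if p.insert_at < 0 or p.end > length:
            raise ValueError(f"plant at {p.insert_at} does not fit in {length} bp")
        if prev_end is not None and p.insert_at - prev_end < 2 * REGION_PAD:
            raise ValueError(
                f"plants too close: need >= {2 * REGION_PAD} bp between them"
            )
        prev_end = p.end

    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = list(rng.choice(list("ACGT"), size=length, p=probs))

    immutable: set[int] = set()
    for p in plants:
        for offset, copy in ((p.copy1_start, p.repeat_seq), (p.copy2_start, p.copy2_seq)):
            for i, base in enumerate(copy):
                arr[offset + i] = base
                immutable.add(offset + i)
        # N guards flanking each copy: no valid window can straddle a copy edge
        guards = [
            p.copy1_start - 1,
            p.copy1_start + p.length,
            p.copy2_start - 1,
            p.copy2_start + p.length,
        ]
        for q in guards:
            if 0 <= q < length:
                arr[q] = "N"
                immutable.add(q)

    for p in plants:
        rs = max(0, p.insert_at - REGION_PAD)
        re_ = min(length, p.end + REGION_PAD)
        forbidden = _plant_neighborhood_kmers(p)
        for _attempt in range(30):
            _clean_region(arr, rs, re_, forbidden, immutable, rng)
            if _validate_plant(arr, p, rs, re_, max_spacer):
                break
            for q in range(rs, re_):
                if q not in immutable:
                    arr[q] = _BASES[rng.integers(4)]
        else:
            raise RuntimeError(
                f"could not isolate plant at {p.insert_at} from chance repeats"
            )

    transcripts: list[TranscriptModel] = []
    expected: list[IRSRecord] = []
    for idx, p in enumerate(plants):
        t = _build_transcript(p, idx, chrom, length)
        if t is not None:
            transcripts.append(t)
        gene = t.gene if t is not None else None
        tx = t.transcript_id if t is not None else None
        expected.extend(_expected_for_plant(p, chrom, gene, tx))

    genome = GenomeSequence(name=chrom, seq="".join(arr))
    return genome, transcripts, expected


def planted_locus_records(
    records: Iterable[IRSRecord], plants: Sequence[PlantSpec]
) -> list[IRSRecord]:
    """Records with at least one window intersecting a planted repeat copy."""
    copies = []
    for p in plants:
        copies.append((p.copy1_start, p.copy1_start + p.length))
        copies.append((p.copy2_start, p.copy2_start + p.length))

    def touches(rec: IRSRecord) -> bool:
        for s, e in ((rec.start1, rec.end1), (rec.start2, rec.end2)):
            for cs, ce in copies:
                if s < ce and cs < e:
                    return True
        return False

    return [r for r in records if touches(r)]


def planted_recovery(
    db: IRSTable,
    expected: Sequence[IRSRecord],
    plants: Sequence[PlantSpec],
    allow_mismatch: bool = True,
) -> tuple[float, float]:
    """(precision, recall) of the expected planted records.

    Precision is evaluated over database records touching a planted copy;
    chance structures elsewhere are background, not false positives.
    """
    want = {r for r in expected if allow_mismatch or r.mismatches == 0}
    got = set(planted_locus_records(db.records, plants))
    if not got and not want:
        return 1.0, 1.0
    tp = len(got & want)
    precision = tp / len(got) if got else 1.0
    recall = tp / len(want) if want else 1.0
    return precision, recall


def standard_plants() -> list[PlantSpec]:
    """Mixed roster: all four gene contexts, lengths 7-11 bp, one mismatch plant."""
    return [
        PlantSpec("CCCCGTG", 100, 1500, CTX_EXONIC),
        PlantSpec("GATTACAAG", 60, 5200, CTX_INTRON_FLANKING),
        PlantSpec("ACGTTGCATC", 200, 9000, CTX_EXONIC, mismatch_offset=4),
        PlantSpec("TTGACCAA", 30, 13000, CTX_SAME_INTRON),
        PlantSpec("CAGGTCATAAC", 500, 16200, CTX_INTERGENIC),
    ]


def standard_fixture(
    seed: int, length: int = 20000, gc: float = 0.41
) -> tuple[GenomeSequence, list[TranscriptModel], list[IRSRecord], list[PlantSpec]]:
    """The default 20 kb study fixture at a given seed."""
    plants = standard_plants()
    genome, transcripts, expected = generate_genome(
        length, gc=gc, seed=seed, plants=plants
    )
    return genome, transcripts, expected, plants


def summary_demo_fixture() -> tuple[GenomeSequence, list[TranscriptModel]]:
    """A fully deterministic 50 kb gene with exactly five 7 bp structures.

    The background is all-N, so the only valid repeat windows are the planted
    islands; each island is a 7 bp repeat pair around an N spacer (N is legal
    inside a spacer — only the repeat windows themselves must be N-free), so
    nothing extends past 7 bp and the gene contains exactly five structures
    with spacers 10, 20, 30, 40 and 50 bp.
    """
    length = 50_000
    chrom = "chrDemo"
    repeats = ["CCCCGTG", "GATTACA", "TTGCAAC", "ACCGTTA", "GTGTCAC"]
    starts = [2000, 12000, 22000, 32000, 42000]
    spacers = [10, 20, 30, 40, 50]
    arr = ["N"] * length
    exons = []
    for rep, a, sp in zip(repeats, starts, spacers):
        b = a + 7 + sp
        arr[a : a + 7] = list(rep)
        arr[b : b + 7] = list(rep)
        exons.append((a, b + 7))
    transcript = TranscriptModel(
        gene="DEMO1",
        transcript_id="TX_DEMO1",
        chrom=chrom,
        strand="+",
        start=0,
        end=length,
        exons=tuple(exons),
    )
    return GenomeSequence(name=chrom, seq="".join(arr)), [transcript]
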