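# Methods

This document records the model implemented by `irscan`, the assumptions and
parameter choices baked into it, what the synthetic data generator does and
does not emulate, and the package's known limitations. It makes no empirical
claims beyond what the test suite and `scripts/acceptance.py` compute.

## 1. The repeat-structure model

An **interspersed repeat structure (IRS)** on a contig is an ordered pair of
k bp windows, `start1 < start2`, such that:

- `7 ≤ k ≤ 20`;
- the two windows do not overlap (`start2 ≥ start1 + k`); abutting copies
  (spacer 0) are allowed;
- the **spacer** — the gap between the end of copy 1 and the start of
  copy 2, `start2 − (start1 + k)` — is at most 1000 bp;
- the copies are identical (exact mode) or differ by at most one
  substitution (mismatch mode, the default); insertions and deletions
  between copies are not modelled;
- neither window contains an ambiguous base. Every non-`ACGT` input
  character is normalized to `N`, and any window containing `N` is excluded
  from indexing. An `N` *inside the spacer* is legal.

Only **direct repeats on the forward strand** are considered: both copies are
read left to right on the same strand. Inverted or reverse-complement repeats
are out of scope. By symmetry of the definition, scanning the reverse
complement of a contig yields the mirrored coordinate set (this is verified
by a property test), so no information is lost by scanning one strand.

Coordinates are 0-based half-open internally and converted to 1-based
inclusive only at the I/O boundary (TSV/CSV output, BED output uses native
BED conventions).

## 2. Seed detection at k = 7

There are exactly 4⁷ = 16 384 distinct 7-mers. The scanner builds a bucket
index mapping each 7-mer to the sorted list of its occurrence positions.
Exact pairs are read off within buckets. One-mismatch pairs are found by
joining each bucket against the buckets of its 21 Hamming-distance-1
neighbours (3 substitutions × 7 offsets); to avoid emitting each pair twice
— once from each of the two buckets that can reach it — a pair is emitted
only from the lexicographically smaller k-mer's bucket. Within buckets,
partners inside the spacer limit are located by binary search over the sorted
position lists. A property test checks that this bucketed pairing equals a
naive all-pairs predicate scan on random sequences.

## 3. Inductive extension to k = 8 … 20

Direct seed enumeration beyond 7 bp is intractable in general (4²⁰ > 10¹²),
so longer repeats are derived inductively. Every (k+1) bp repeat pair
contains, at the same start coordinates, a k bp pair that satisfies all the
constraints except possibly the spacer bound — extending both copies one base
rightward shrinks the spacer by exactly 1. The induction is therefore:

1. keep candidates at level k under a **relaxed** spacer bound
   `max_spacer + (kmax − k)`, so that a pair whose spacer is slightly over
   the limit at k = 7 can still produce legal descendants at larger k;
2. extend a candidate to k+1 when both next bases exist, neither is `N`,
   the running mismatch count stays ≤ 1 (a first mismatch is absorbed and
   its offset recorded; a second terminates the lineage), and the shrunken
   spacer is still within the relaxed bound;
3. apply the **strict** bound `spacer ≤ max_spacer` only when emitting
   records at each level.

Step 1 is what makes the induction complete at the boundary; without it,
records at larger k whose 7 bp ancestors had spacers of 1001–1013 bp would
be lost. Acceptance tests compare every level of the inductive engine against
an independent brute-force oracle and require set equality.

**Exact mode.** Extension always absorbs a first mismatch; when mismatches
are disallowed, candidates with one mismatch are dropped after each
extension step. This loses nothing, because an exact pair at k+1 always has
an exact prefix at k; it keeps a single extension code path for both modes.

Two consequences of the induction are verified as properties: the start-pair
set at each level is a subset of the previous level's, and a candidate's
mismatch count never decreases along its lineage.

## 4. Exome selection rules

Given a set of transcript models (BED12: gene and transcript id, span, exon
blocks), each repeat pair is tested against every transcript whose genomic
span it touches (an interval tree over spans makes this lookup fast):

1. if either window falls partly outside the transcript span, the pair is
   **rejected** for that transcript;
2. else, if either window overlaps any exon by ≥ 1 bp, the pair is kept as
   `exon_overlap`;
3. else, if the two windows are each fully contained in an intron and those
   introns are *different*, the pair is kept as `intron_flanking` (both
   copies bracket at least one exon, so a deletion between them removes
   exonic sequence);
4. otherwise (both copies in the same intron) it is rejected.

A pair overlapping several genes yields one record per gene; duplicates
within a gene are removed on the key `(chrom, k, start1, start2, gene)`.

**Per-level vs at-seed filtering.** The default filters candidates at every
length. A compatibility flag (`--filter-at-seed`) instead restricts the seed
level to pairs that already pass the spacer bound and the selection rules and
then extends only those. At-seed filtering can only lose records relative to
per-level filtering — an extension can move a window into an exon, and a
seed-level spacer may exceed the limit while its descendants' spacers do
not — so per-level is the correct default; the subset relation is asserted by
a test.

## 5. Queries and summary statistics

`gene_lookup` returns, per requested repeat length, the detail records for a
gene plus a summary row with:

- `n_irs` — number of records after the distance filter;
- `mean_distance` — mean spacer in bp (the *gap* between copies, not a
  midpoint distance);
- `irs_per_mb` — `n_irs / (span_bp / 1e6)`, where `span_bp` is the genomic
  span of the gene's transcript (first by transcript id when several exist);
- `has_mismatch` — whether any returned record used the mismatch allowance.

Requesting an unknown gene is an error (exit code 1 from the CLI), as is a
repeat length outside the range the database was built for or a distance
bound above the database's spacer limit. Mean values are rounded to two
decimals and densities to four only for display; JSON/TSV outputs carry the
same rounded values deterministically.

## 6. The independent oracle

`irscan.oracle` re-derives the answer for one repeat length with none of the
production machinery: the sequence becomes a numpy byte array, and for every
separation `d` in `[k, k + max_spacer]` the window-wise mismatch counts
between the sequence and its `d`-shifted copy are accumulated
offset-by-offset; `N` positions are masked via a cumulative-sum validity
check. Gene assignment in the oracle is a separate plain-loop classifier.
The oracle is O(n · max_spacer · k) and guarded to inputs ≤ 100 kb; it
exists for verification, not production use.

## 7. The synthetic data generator

`irscan.simulate` produces fixtures whose exact expected output is known by
construction, so recovery can be scored as precision/recall without
tolerance. Its design:

- **Background**: i.i.d. bases at a fixed GC content (default 0.41, a
  human-like overall value). This emulates only base composition — not
  repeat families, isochore structure, tandem repeats, or any positional
  correlation of a real genome.
- **Plants**: each planted structure is a repeat sequence (7–20 bp), a
  spacer length, an insertion point, a gene context (exonic,
  intron-flanking, same-intron, or intergenic), and optionally a single
  mismatch position for the second copy. Plant regions must be ≥ 2040 bp
  apart so their neighbourhoods cannot interact.
- **Exactness guarantees**: a single `N` guard base flanks each planted copy,
  which kills every window straddling a copy boundary (an `N` in the spacer
  is legal, so the planted records survive); background windows within
  ±1020 bp of a plant are rejection-resampled until no 7 bp window lies
  within Hamming distance 1 of any window of the planted copies (a longer
  chance near-match would contain an aligned 7 bp near-match, so cleaning at
  7 bp suffices for all k); the planted repeat itself must have no
  self-similar sub-windows. After construction, the brute-force oracle
  validates that the records touching the planted copies equal the
  constructed expectation at every k up to the plant length and are empty
  one base beyond it; on failure the region is resampled (up to 30
  attempts).
- **Gene models** are minimal transcripts realizing each context, e.g. a
  three-exon transcript whose middle exon sits between the two copies for
  the intron-flanking context.
- **Demo fixture**: `summary_demo_fixture` places five 7 bp repeat islands
  with spacers 10–50 bp on an otherwise all-`N` 50 kb contig inside one
  50 kb gene, making the summary row (5 records, mean 30 bp, 100 per Mb)
  hand-checkable and immune to chance background hits.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical fixtures.

## 8. Problem sizes and numerical choices

Verification runs use twenty seeded 20 kb fixtures at repeat lengths 7–12 in
both mismatch modes. These sizes are this package's own choice: they keep the
quadratic brute-force oracle fast enough to check *every* level exhaustively
in minutes while exercising all code paths (the engine itself handles the
full 7–20 range, as the demo fixture's build does). Genome-scale runs on a
real assembly are architecturally supported (per-contig streaming, bucketed
pairing) but are not performed or claimed anywhere in this repository.

Determinism and tie-breaking: records sort by
`(chrom, k, start1, start2, gene)`; output files are written with `\n` line
endings and fixed column order; database directories store build parameters
and input digests (`params.txt`) so a query can refuse mismatched inputs.

## 9. Limitations

- Substitution-only mismatch model: one substitution at most, no indels
  between copies.
- Direct repeats only; inverted repeats are not detected.
- The selection rules use transcript spans and exon blocks only; no
  awareness of UTRs vs CDS, strand-specific biology, or overlapping exon
  structures beyond per-gene duplication.
- The generator's background is i.i.d.; recovery statistics on it say
  nothing about false-positive rates in real genomes, where repeat families
  inflate hit counts by design.
- The brute-force oracle is deliberately capped at 100 kb inputs.
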