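# irscan — interspersed repeat structures in exomes

`irscan` finds **interspersed repeat structures (IRS)**: two short direct
repeats — identical copies of a 7–20 bp sequence, or copies differing by at
most one substitution — separated by a spacer of up to 1000 bp on the same
strand. Such structures matter because the repeated copies provide
microhomology: replication slippage or microhomology-mediated repair between
the two copies can delete the intervening sequence, and when one copy sits in
or near an exon this produces a clean, clinically relevant exonic deletion.
Cataloguing where these structures fall relative to gene models turns a raw
genome into a per-gene lookup of deletion-prone sites.

The package builds that catalogue and answers per-gene queries over it.

## The method in one paragraph

Enumerating candidate repeats directly is only feasible for the shortest
length: there are exactly 4⁷ = 16 384 distinct 7-mers, but 4²⁰ ≈ 1.1 × 10¹²
distinct 20-mers — direct enumeration at 20 bp is out of reach. `irscan`
therefore works **inductively**: it indexes every 7 bp window of the genome,
pairs windows that lie within the spacer limit and are within Hamming
distance 1 of each other, and then grows each surviving pair one base to the
right at a time, 8 bp, 9 bp, … up to 20 bp. A pair can absorb its single
allowed mismatch during growth; a second mismatch, an `N`, or an exhausted
spacer terminates it. Because every (k+1) bp repeat pair contains a k bp
repeat pair as a prefix, this induction is *complete*: it finds exactly what
an all-pairs scan at each length would find, without ever touching the
exponential seed space beyond 7 bp. At each length the candidate pairs are
filtered against a transcript annotation, keeping a pair only if it overlaps
an exon by at least one base (`exon_overlap`) or if its two copies lie fully
inside two *different* introns of the same transcript (`intron_flanking`).

## Worked example

The package ships a deterministic simulator that writes a small genome with
planted repeat structures in known gene contexts, together with a BED12
annotation and the list of expected records:

```
$ irscan simulate --length 20000 --seed 7 --out demo/sim
20000 bp genome, 4 transcript(s), 17 expected record(s) -> demo/sim

$ irscan build --fasta demo/sim/genome.fa --annotation demo/sim/annotation.bed \
      --kmin 7 --kmax 12 --out demo/db
341 records across 1 contig(s) -> demo/db
```

Query one gene for 9 bp exact repeats (coordinates in the output are 1-based
inclusive):

```
$ irscan query --db demo/db --gene GENE2 --length 9 --no-mismatch
## summary
gene	repeat_length	n_irs	mean_distance	irs_per_mb	has_mismatch
GENE2	9	3	418.0	4424.7788	False

## details
chrom	gene	transcript	repeat_length	repeat1_start	repeat1_end	repeat2_start	repeat2_end	repeat1_seq	repeat2_seq	spacer_bp	mismatch	class
chrSim	GENE2	TX2	9	4934	4942	5540	5548	TGAAAGTTA	TGAAAGTTA	597	0	intron_flanking
chrSim	GENE2	TX2	9	4935	4943	5541	5549	GAAAGTTAA	GAAAGTTAA	597	0	intron_flanking
chrSim	GENE2	TX2	9	5201	5209	5270	5278	GATTACAAG	GATTACAAG	60	0	intron_flanking
```

The third record is the simulator's planted 9 bp repeat `GATTACAAG` with a
60 bp spacer, recovered in the intron-flanking class it was planted in; the
first two are chance background repeats, which are legitimate hits. With the
mismatch-tolerant default and several lengths at once:

```
$ irscan query --db demo/db --gene GENE2 --length 7,8,9
## summary
gene	repeat_length	n_irs	mean_distance	irs_per_mb	has_mismatch
GENE2	7	204	309.26	300884.9558	True
GENE2	8	59	326.93	87020.649	True
GENE2	9	22	346.95	32448.3776	True
...
```

The same pipeline is available as a library:

```python
from irscan import build_database, gene_lookup, summary_demo_fixture, QueryParams
from irscan.query import summary_frame

genome, transcripts = summary_demo_fixture()
db = build_database(genome, transcripts, kmin=7, kmax=20)
summary, details = gene_lookup(db, transcripts, QueryParams("DEMO1", lengths=(7,)))
print(summary_frame(summary).to_string(index=False))
```

```
 gene  repeat_length  n_irs  mean_distance  irs_per_mb  has_mismatch
DEMO1              7      5           30.0       100.0         False
```

This demo fixture is built so the answer is hand-checkable: five 7 bp repeat
pairs with spacers 10, 20, 30, 40 and 50 bp inside a 50 kb gene give a mean
distance of 30 bp and 5 / 0.05 Mb = 100 structures per megabase.

An `irscan oracle-check` subcommand re-derives the database for one repeat
length with an independent brute-force scan and exits nonzero on any
disagreement.

## Layout

- `src/irscan/core.py` — window indexing and seed-level pairing
- `src/irscan/extension.py` — inductive length growth and database build
- `src/irscan/exome.py` — selection rules against transcript models
- `src/irscan/query.py` — per-gene summaries and detail views
- `src/irscan/genome_io.py` — FASTA / BED12 / TSV-CSV-BED readers and writers
- `src/irscan/simulate.py` — deterministic fixture generator with planted truth
- `src/irscan/oracle.py` — independent brute-force reference implementation
- `src/irscan/cli.py` — `irscan` command-line interface
- `docs/methods.md` — model, assumptions, and numerical choices
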