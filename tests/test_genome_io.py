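"""FASTA and BED12 input, table output, coordinate-convention round trips."""

import pytest

from irscan import (
    GenomeSequence,
    IRSRecord,
    IRSTable,
    read_annotation,
    read_fasta,
    read_irs_table,
    write_annotation,
    write_fasta,
    write_irs_table,
)
from irscan.errors import FormatError
from irscan.genome_io import TABLE_COLUMNS, normalize_sequence


def test_fasta_parse_and_normalization(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">chrT\nACGTACGT\n>chr2\nacgtRacgt\n")
    genomes = read_fasta(str(p))
    assert [g.name for g in genomes] == ["chrT", "chr2"]
    assert genomes[0].seq == "ACGTACGT" and genomes[0].length == 8
    assert genomes[1].seq == "ACGTNACGT"  # lowercase uppercased, IUPAC R -> N


def test_normalize_maps_every_non_acgt_to_n():
    assert normalize_sequence("acgtRYKMswn-") == "ACGTNNNNNNNN"


def test_fasta_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_fasta(str(tmp_path / "missing.fa"))
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(FormatError):
        read_fasta(str(empty))
    bad = tmp_path / "bad.fa"
    bad.write_text("ACGT\n>chrT\nACGT\n")
    with pytest.raises(FormatError, match="line 1"):
        read_fasta(str(bad))


def test_fasta_round_trip(tmp_path):
    g = GenomeSequence("chrT", "ACGTN" * 50)
    path = tmp_path / "rt.fa"
    write_fasta([g], str(path))
    assert read_fasta(str(path)) == [g]


def test_bed12_block_arithmetic(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text(
        "chrT\t100\t1100\tGAA|NM_000152.4\t0\t+\t100\t1100\t0\t2\t200,200\t0,800\n"
    )
    (t,) = read_annotation(str(p))
    assert (t.gene, t.transcript_id) == ("GAA", "NM_000152.4")
    assert t.exons == ((100, 300), (900, 1100))
    assert t.introns == ((300, 900),)


def test_bed12_name_without_separator_is_both_gene_and_transcript(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chrT\t0\t500\tMYGENE\t0\t+\t0\t500\t0\t1\t500\t0\n")
    (t,) = read_annotation(str(p))
    assert t.gene == t.transcript_id == "MYGENE"
    assert t.introns == ()


@pytest.mark.parametrize(
    "line",
    [
        # blockCount says 2 but one block listed
        "chrT\t0\t500\tG|T\t0\t+\t0\t500\t0\t2\t100\t0\n",
        # exon extends beyond span
        "chrT\t0\t500\tG|T\t0\t+\t0\t500\t0\t1\t600\t0\n",
        # too few fields
        "chrT\t0\t500\tG|T\t0\t+\n",
    ],
)
def test_bed12_format_errors(tmp_path, line):
    p = tmp_path / "bad.bed"
    p.write_text(line)
    with pytest.raises(FormatError):
        read_annotation(str(p))


def test_annotation_round_trip(tmp_path, std_fixture):
    _, transcripts, _, _ = std_fixture
    p = tmp_path / "t.bed"
    write_annotation(transcripts, str(p))
    assert read_annotation(str(p)) == transcripts


def _table():
    recs = [
        IRSRecord("chrT", 7, 0, 17, "CCCCGTG", "CCCCGTG", 0,
                  gene="GAA", transcript_id="NM_1", selection="exon_overlap"),
        IRSRecord("chrT", 7, 30, 44, "AAAAAAC", "AAAAAAT", 1, mismatch_offset=6,
                  gene="GAA", transcript_id="NM_1", selection="intron_flanking"),
    ]
    return IRSTable.from_records(recs, {"kmin": 7, "kmax": 7})


def test_table_tsv_schema_and_coordinates(tmp_path):
    path = tmp_path / "t.tsv"
    write_irs_table(_table(), str(path), "tsv")
    lines = path.read_text().splitlines()
    assert lines[0].split("\t") == list(TABLE_COLUMNS)
    assert len(lines) == 3
    first = lines[1].split("\t")
    # 0-based half-open [0, 7) becomes 1-based inclusive 1..7
    assert first[4:8] == ["1", "7", "18", "24"]


def test_table_round_trip_and_determinism(tmp_path):
    table = _table()
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_irs_table(table, str(p1), "tsv")
    write_irs_table(table, str(p2), "tsv")
    assert p1.read_bytes() == p2.read_bytes()
    back = read_irs_table(str(p1), "tsv")
    assert back.records == table.records
    csvp = tmp_path / "a.csv"
    write_irs_table(table, str(csvp), "csv")
    assert read_irs_table(str(csvp), "csv").records == table.records


def test_empty_table_is_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    write_irs_table(IRSTable.from_records([]), str(path), "tsv")
    assert path.read_text().splitlines() == ["\t".join(TABLE_COLUMNS)]


def test_bed_output_one_line_per_window(tmp_path):
    path = tmp_path / "t.bed"
    write_irs_table(_table(), str(path), "bed")
    lines = path.read_text().splitlines()
    assert len(lines) == 4  # two windows per record
    chrom, start, end, name, score, strand = lines[0].split("\t")
    assert (chrom, start, end, strand) == ("chrT", "0", "7", "+")
    assert "mate:" in name
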