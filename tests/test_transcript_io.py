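"""FASTA/GFF3/BED/TSV round trips and the record loaders."""

import numpy as np
import pytest

from leaderscan import (
    OrfClass,
    UpstreamOrfCall,
    extract_records_from_genome,
    read_abundance_table,
    read_orf_table,
    read_tl_table,
    read_transcript_fasta,
    reverse_complement,
    scan_transcript,
    write_orf_table,
    write_transcript_fasta,
)
from leaderscan.synthetic_data import generate_cohort


@pytest.fixture
def fasta_file(tmp_path):
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    seq = seq[:100] + "ATG" + seq[103:]  # CDS starts at 1-based 101
    path = tmp_path / "transcripts.fasta"
    path.write_text(
        f">g1 cds_start=101 tl_length=49 species=yeast\n{seq}\n"
        f">g2 cds_start=101\n{seq}\n"          # TL length must come from the table
        f">g3 cds_start=101\n{seq}\n"          # absent from the table -> skipped
        f">g4 cds_start=101 tl_length=150\n{seq[:200]}\n"  # TL longer than upstream
    )
    return path, seq


class TestReadTranscriptFasta:
    def test_header_metadata_slicing(self, fasta_file):
        path, seq = fasta_file
        res = read_transcript_fasta(path, tl_table={"g2": 30})
        rec = res[0]
        assert rec.gene_id == "g1"
        assert rec.tl_length == 49 and rec.window == 300
        assert rec.tl_seq == seq[51:100]
        assert rec.downstream_seq == seq[100:]
        assert rec.species_label == "yeast"
        assert res[1].tl_length == 30  # from tl_table

    def test_skip_reasons(self, fasta_file):
        path, _ = fasta_file
        res = read_transcript_fasta(path, tl_table={"g2": 30})
        assert res.skip_counts == {"no_tl_length": 1, "tl_longer_than_upstream": 1}
        assert ("g3", "no_tl_length") in res.skipped
        assert ("g4", "tl_longer_than_upstream") in res.skipped

    def test_round_trip(self, tmp_path):
        records, _ = generate_cohort(25, mode="iid", seed=2)
        out = tmp_path / "rt.fasta"
        write_transcript_fasta(records, out)
        back = list(read_transcript_fasta(out))
        assert [(r.gene_id, r.tl_seq, r.downstream_seq) for r in back] == [
            (r.gene_id, r.tl_seq, r.downstream_seq) for r in records
        ]


@pytest.fixture
def genome_files(tmp_path):
    rng = np.random.default_rng(3)
    contig = "".join(rng.choice(list("ACGT"), size=1400))
    contig = contig[:1000] + "ATG" + contig[1003:]  # plus-strand CDS at 1001
    genome = tmp_path / "genome.fasta"
    genome.write_text(f">chr1\n{contig}\n")
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1001\t1300\t.\t+\t.\tID=plus_gene\n"
        "chr1\tsrc\tgene\t401\t700\t.\t-\t.\tID=minus_gene\n"
    )
    bed = tmp_path / "genes.bed"
    bed.write_text(
        "chr1\t1000\t1300\tplus_gene\t0\t+\n"
        "chr1\t400\t700\tminus_gene\t0\t-\n"
    )
    return genome, gff, bed, contig


class TestGenomeExtraction:
    def test_plus_strand_coordinates(self, genome_files):
        genome, gff, _, contig = genome_files
        res = extract_records_from_genome(genome, gff, {"plus_gene": 10}, window=300)
        rec = next(r for r in res if r.gene_id == "plus_gene")
        assert rec.tl_seq == contig[990:1000]
        assert rec.downstream_seq == contig[1000:1300]
        assert rec.downstream_seq.startswith("ATG")

    def test_minus_strand_is_reverse_complemented(self, genome_files):
        genome, gff, _, contig = genome_files
        res = extract_records_from_genome(genome, gff, {"minus_gene": 10}, window=120)
        rec = next(r for r in res if r.gene_id == "minus_gene")
        assert rec.tl_seq == reverse_complement(contig[700:710])
        assert rec.downstream_seq == reverse_complement(contig[580:700])

    def test_bed_dialect_agrees_with_gff3(self, genome_files):
        genome, gff, bed, _ = genome_files
        table = {"plus_gene": 10, "minus_gene": 10}
        a = extract_records_from_genome(genome, gff, table)
        b = extract_records_from_genome(genome, bed, table)
        assert [(r.gene_id, r.tl_seq, r.downstream_seq) for r in a] == [
            (r.gene_id, r.tl_seq, r.downstream_seq) for r in b
        ]

    def test_out_of_range_and_missing_tl_are_skipped(self, genome_files):
        genome, gff, _, _ = genome_files
        res = extract_records_from_genome(genome, gff, {"plus_gene": 2000})
        assert ("plus_gene", "coordinates_outside_contig") in res.skipped
        assert ("minus_gene", "no_tl_length") in res.skipped
        assert len(res) == 0

    def test_unknown_strand_rejected(self, genome_files, tmp_path):
        genome, _, _, _ = genome_files
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t1000\t1300\tg\t0\t?\n")
        with pytest.raises(ValueError, match="strand"):
            extract_records_from_genome(genome, bad, {"g": 10})


class TestOrfTable:
    def test_write_read_round_trip(self, tmp_path, make_record):
        rec = make_record("ATGTAACCCATGCC", ds="ATGACCCGGGTAA")
        calls = scan_transcript(rec)
        assert calls  # sanity
        calls = calls + [UpstreamOrfCall("g1", -12, None, None, 1, OrfClass.NO_STOP)]
        path = tmp_path / "calls.tsv"
        write_orf_table(calls, path)
        assert read_orf_table(path) == calls  # file order preserved

    def test_missing_stop_written_as_na(self, tmp_path):
        call = UpstreamOrfCall("g1", -8, None, None, 2, OrfClass.NO_STOP)
        path = tmp_path / "calls.tsv"
        write_orf_table([call], path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["gene", "start", "stop", "class", "length_aa", "frame_offset"]
        assert lines[1].split("\t")[2] == "NA"

    def test_empty_call_list_gives_header_only(self, tmp_path):
        path = tmp_path / "calls.tsv"
        write_orf_table([], path)
        assert path.read_text().splitlines() == ["gene\tstart\tstop\tclass\tlength_aa\tframe_offset"]


class TestTables:
    def test_abundance_basic(self, tmp_path):
        p = tmp_path / "ab.tsv"
        p.write_text("g1\t100\ng2\t5\n")
        table, dropped = read_abundance_table(p)
        assert table == {"g1": 100.0, "g2": 5.0} and dropped == 0

    def test_abundance_na_dropped_and_counted(self, tmp_path):
        p = tmp_path / "ab.tsv"
        p.write_text("g1\t100\ng3\tNA\n")
        table, dropped = read_abundance_table(p)
        assert table == {"g1": 100.0} and dropped == 1

    def test_abundance_duplicate_last_wins(self, tmp_path):
        p = tmp_path / "ab.tsv"
        p.write_text("g1\t100\ng1\t7\n")
        table, _ = read_abundance_table(p)
        assert table == {"g1": 7.0}

    def test_abundance_empty_rejected(self, tmp_path):
        p = tmp_path / "ab.tsv"
        p.write_text("g1\tNA\n")
        with pytest.raises(ValueError, match="empty abundance table"):
            read_abundance_table(p)

    def test_tl_table(self, tmp_path):
        p = tmp_path / "tl.tsv"
        p.write_text("gene\tlength\ng1\t49\ng2\t173\n")
        assert read_tl_table(p) == {"g1": 49, "g2": 173}
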