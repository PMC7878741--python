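"""Table dialect parsing, sign conventions, and byte-level round trips."""

import gzip

import pytest

from aluterm.ucsc_io import (ApaRecord, TableFormatError, read_genepred,
                             read_rmsk, read_tapas, write_genepred,
                             write_rmsk, write_tapas)
from helpers import make_rmsk

REFGENE_ROW = ("585\tNM_000001\tchr1\t+\t100\t900\t200\t700\t2\t"
               "100,500,\t300,900,\t0\tG1\tcmpl\tcmpl\t-1,-1,\n")


def test_refgene_16col_row_parses(tmp_path):
    p = tmp_path / "refGene.txt"
    p.write_text(REFGENE_ROW)
    (rec,) = read_genepred(p)
    assert rec.bin == 585 and rec.name == "NM_000001"
    assert rec.exonCount == 2
    assert rec.exon_blocks() == ((100, 300), (500, 900))
    assert rec.name2 == "G1"


def test_15col_row_parses_identically_without_bin(tmp_path):
    row15 = REFGENE_ROW.split("\t", 1)[1]
    p = tmp_path / "gp.txt"
    p.write_text(row15)
    (rec,) = read_genepred(p)
    assert rec.bin is None
    assert rec.name == "NM_000001" and rec.exonCount == 2


def test_refflat_symbol_column_lands_in_name2(tmp_path):
    p = tmp_path / "refFlat.txt"
    p.write_text("G1\tNM_000001\tchr1\t+\t100\t900\t200\t700\t2\t"
                 "100,500,\t300,900,\n")
    (rec,) = read_genepred(p)
    assert rec.name2 == "G1" and rec.name == "NM_000001"


def test_11col_bin_basic_distinguished_from_refflat(tmp_path):
    p = tmp_path / "gp.txt"
    p.write_text("585\tNM_000001\tchr1\t+\t100\t900\t200\t700\t2\t"
                 "100,500,\t300,900,\n")
    (rec,) = read_genepred(p)
    assert rec.bin == 585 and rec.name2 == ""


@pytest.mark.parametrize("mutation,field", [
    (lambda r: r.replace("\t2\t", "\t3\t"), "exonCount"),
    (lambda r: r.replace("\t+\t", "\t*\t"), "strand"),
    (lambda r: r.replace("\t200\t700\t", "\t950\t990\t"), "cds"),
])
def test_malformed_genepred_errors_carry_line_number(tmp_path, mutation,
                                                     field):
    p = tmp_path / "bad.txt"
    p.write_text(REFGENE_ROW + mutation(REFGENE_ROW))
    with pytest.raises(TableFormatError, match="line 2"):
        read_genepred(p)


def test_gzip_input_sniffed_by_magic_bytes(tmp_path):
    p = tmp_path / "refGene.nogz"  # deliberately unsuffixed
    with gzip.open(p, "wt") as fh:
        fh.write(REFGENE_ROW)
    (rec,) = read_genepred(p)
    assert rec.name == "NM_000001"


def test_genepred_roundtrip_byte_identical(fig7_fixture, tmp_path):
    files, _ = fig7_fixture
    records = read_genepred(files["refgene"])
    out = tmp_path / "again.txt"
    write_genepred(records, out, layout="refgene")
    assert out.read_bytes() == files["refgene"].read_bytes()


def test_refflat_roundtrip_byte_identical(fig7_fixture, tmp_path):
    files, _ = fig7_fixture
    records = read_genepred(files["refflat"])
    out = tmp_path / "again.txt"
    write_genepred(records, out, layout="refflat")
    assert out.read_bytes() == files["refflat"].read_bytes()


# -- rmsk -------------------------------------------------------------------

def test_rmsk_plus_strand_convention():
    rec = make_rmsk(strand="+", span=(1000, 1290), consensus_length=311)
    assert rec.sign_convention_ok()
    assert rec.repStart == 1 and rec.repEnd == 290 and rec.repLeft == -21
    assert (rec.consensus_start, rec.consensus_end) == (1, 290)


def test_rmsk_minus_strand_convention_recovers_consensus_span():
    rec = make_rmsk(strand="-", span=(1000, 1290), consensus_length=311)
    assert rec.sign_convention_ok()
    assert rec.repLeft == 1 and rec.repEnd == 290 and rec.repStart == -21
    assert (rec.consensus_start, rec.consensus_end) == (1, 290)
    assert rec.consensus_left == 21


def test_rmsk_roundtrip_byte_identical(fig7_fixture, tmp_path):
    files, _ = fig7_fixture
    records = read_rmsk(files["rmsk"])
    out = tmp_path / "again.txt"
    write_rmsk(records, out)
    assert out.read_bytes() == files["rmsk"].read_bytes()


def test_rmsk_sign_violation_flags_but_keeps_record(tmp_path):
    good = make_rmsk(strand="+", span=(0, 290))
    cols = [str(getattr(good, f)) for f in
            ("bin", "swScore", "milliDiv", "milliDel", "milliIns", "genoName",
             "genoStart", "genoEnd", "genoLeft")] + \
        ["+", "AluYRa1", "SINE", "Alu", "-5", "290", "1", "7"]
    p = tmp_path / "rmsk.txt"
    p.write_text("\t".join(cols) + "\n")
    with pytest.warns(UserWarning, match="sign convention"):
        (rec,) = read_rmsk(p)
    assert rec.flagged


def test_rmsk_wrong_column_count_is_located_error(tmp_path):
    p = tmp_path / "rmsk.txt"
    p.write_text("1\t2\t3\n")
    with pytest.raises(TableFormatError, match="line 1"):
        read_rmsk(p)


# -- TAPAS ------------------------------------------------------------------

def test_tapas_multisite_row(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("G1\tchr1\t+\t100,200,300\t1.5,2,0.5\t1234\n")
    (rec,) = read_tapas(p)
    assert rec.apa_sites == (100, 200, 300)
    assert rec.abundances == (1.5, 2.0, 0.5)


def test_tapas_whitespace_delimited_sites_accepted(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("G1\tchr1\t+\t100 200\t1 2\t10\n")
    (rec,) = read_tapas(p)
    assert rec.apa_sites == (100, 200)


def test_tapas_empty_site_list_is_not_an_error(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("G1\tchr1\t+\t\t\t0\n")
    (rec,) = read_tapas(p)
    assert rec.apa_sites == () and rec.abundances == ()


def test_tapas_length_mismatch_names_gene(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("MYGENE\tchr1\t+\t100,200\t1.5\t10\n")
    with pytest.raises(TableFormatError, match="MYGENE"):
        read_tapas(p)


def test_tapas_roundtrip_byte_identical(fig7_fixture, tmp_path):
    files, _ = fig7_fixture
    records = read_tapas(files["tapas"])
    out = tmp_path / "again.tsv"
    write_tapas(records, out)
    assert out.read_bytes() == files["tapas"].read_bytes()
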