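"""Positional classification, aggregation, and the per-gene inventory."""

import random

import pytest

from aluterm.gene_model import build_model
from aluterm.locator import (Orientation, PositionalCategory, classify_pair,
                             gene_inventory, locate_all, read_calls,
                             summarize_positions, write_calls)
from aluterm.synthetic_data import (FixtureSpec, PlantedRepeat,
                                    generate_fixture, random_instance)
from aluterm.ucsc_io import read_genepred, read_rmsk
from helpers import make_model, make_rmsk

C = PositionalCategory

# a roomy "+" host: 3'UTR [1000, 2000), txEnd 2000
HOST = dict(strand="+", tx=(0, 2000), cds=(200, 1000))


def test_element_spanning_tx_end_in_utr3_is_utr3_end_sense():
    m = make_model(**HOST)
    rep = make_rmsk(span=(1900, 2190), strand="+")
    call = classify_pair(rep, m)
    assert call.category is C.UTR3_END
    assert call.orientation is Orientation.SENSE
    assert call.overlap_bp == 100


def test_element_in_middle_of_utr3_is_internal():
    m = make_model(**HOST)
    call = classify_pair(make_rmsk(span=(1200, 1500)), m)
    assert call.category is C.UTR3_INTERNAL
    assert C.INSIDE_EXON in call.all_categories


def test_element_stopping_short_of_terminus_is_internal_not_end():
    """A repeat ending 30 bp upstream of txEnd with a strict window is in
    the UTR interior; an opt-in proximity window flips it to the end."""
    m = make_model(**HOST)
    rep = make_rmsk(span=(1700, 1970))
    assert classify_pair(rep, m, proximity_bp=0).category is C.UTR3_INTERNAL
    assert classify_pair(rep, m, proximity_bp=30).category is C.UTR3_END
    assert classify_pair(rep, m).distance_to_terminal == 30


def test_element_abutting_exclusive_tx_end_counts_as_end():
    m = make_model(**HOST)
    ending_at = classify_pair(make_rmsk(span=(1710, 2000)), m)
    assert ending_at.category is C.UTR3_END
    starting_at = classify_pair(make_rmsk(span=(2000, 2290)), m)
    assert starting_at.category is C.UTR3_END
    assert starting_at.overlap_bp == 0


@pytest.mark.parametrize("span,expect", [
    ((150, 400), C.ORF_START),       # covers cdsStart base
    ((900, 1100), C.ORF_END),        # covers cdsEnd-1 base
    ((50, 120), C.UTR5_INTERNAL),
    ((2500, 2700), C.NO_EXONIC_OVERLAP),
])
def test_boundary_and_containment_categories(span, expect):
    m = make_model(**HOST)
    assert classify_pair(make_rmsk(span=span), m).category is expect


def test_exon_splicing_on_internal_junction():
    m = make_model(strand="+", tx=(0, 2000), cds=(200, 1500),
                   exons=[(0, 800), (1200, 2000)])
    call = classify_pair(make_rmsk(span=(700, 900)), m)
    assert call.category is C.EXON_SPLICING


def test_whole_gene_spanning_element_resolves_by_precedence():
    m = make_model(**HOST)
    call = classify_pair(make_rmsk(span=(0, 2000)), m)
    assert call.category is C.UTR3_END
    assert {C.UTR3_END, C.UTR5_START, C.ORF_START, C.ORF_END} <= \
        call.all_categories


def test_orientation_involution():
    rng = random.Random(3)
    for _ in range(50):
        rep, m = random_instance(rng)
        base = classify_pair(rep, m).orientation
        flip_rep = make_rmsk(chrom=rep.genoName, span=rep.span,
                             strand="-" if rep.strand == "+" else "+")
        assert classify_pair(flip_rep, m).orientation is not base


def test_primary_category_always_in_all_categories():
    rng = random.Random(4)
    for _ in range(300):
        rep, m = random_instance(rng)
        call = classify_pair(rep, m)
        assert call.category in call.all_categories


def test_chromosome_mismatch_raises():
    m = make_model(**HOST)
    with pytest.raises(ValueError, match="chromosome mismatch"):
        classify_pair(make_rmsk(chrom="chr9", span=(0, 100)), m)


# -- locate_all -------------------------------------------------------------

def test_locate_all_empty_inputs():
    assert locate_all([], []) == []
    assert locate_all([make_rmsk(span=(0, 100))], []) == []


def test_repeat_overlapping_two_isoforms_yields_two_calls():
    iso1 = make_model(name="NM_1", name2="G", **HOST)
    iso2 = make_model(name="NM_2", name2="G", strand="+", tx=(0, 2100),
                      cds=(200, 1000))
    calls = locate_all([make_rmsk(span=(1200, 1500))], [iso1, iso2])
    assert len(calls) == 2
    assert {c.transcript_id for c in calls} == {"NM_1", "NM_2"}


def test_intronic_repeat_dropped_unless_requested():
    m = make_model(strand="+", tx=(0, 2000), cds=(200, 1500),
                   exons=[(0, 800), (1200, 2000)])
    rep = make_rmsk(span=(900, 1100))
    assert locate_all([rep], [m]) == []
    (call,) = locate_all([rep], [m], emit_nonoverlapping=True)
    assert call.category is C.NO_EXONIC_OVERLAP


# -- summaries --------------------------------------------------------------

def _utr3_end_calls(n_sense, n_antisense):
    m = make_model(**HOST)
    calls = []
    for i in range(n_sense + n_antisense):
        strand = "+" if i < n_sense else "-"
        calls.append(classify_pair(
            make_rmsk(span=(1900, 2190), strand=strand, rep_id=i), m))
    return calls


def test_summary_recovers_sense_antisense_ratio():
    calls = _utr3_end_calls(30, 10)
    table = summarize_positions(calls, group_by="repName")
    get = lambda o: int(table[(table.category == "UTR3_END")
                              & (table.orientation == o)]["count"].iloc[0])
    assert get("SENSE") == 30 and get("ANTISENSE") == 10
    assert get("SENSE") / get("ANTISENSE") == 3.0


def test_summary_is_dense_and_conserves_counts():
    calls = _utr3_end_calls(2, 1)
    table = summarize_positions(calls, group_by="repClass")
    # all 9 categories x 2 orientations present for the observed group
    assert len(table) == 18
    assert table["count"].sum() == len(calls)
    assert summarize_positions([], group_by="repName").empty


def test_summary_unknown_grouping_rejected():
    with pytest.raises(ValueError, match="group_by"):
        summarize_positions([], group_by="bogus")


# -- per-gene inventory -----------------------------------------------------

def test_inventory_collapses_isoforms_to_one_gene():
    iso1 = make_model(name="NM_1", name2="G", **HOST)
    iso2 = make_model(name="NM_2", name2="G", strand="+", tx=(0, 2100),
                      cds=(200, 1000))
    rep = make_rmsk(span=(1950, 2240))
    calls = locate_all([rep], [iso1, iso2])
    inv = gene_inventory(calls)
    assert list(inv.gene) == ["G"] and int(inv.n_transcripts.iloc[0]) == 2


def test_inventory_registered_predicted_split(tmp_path):
    """Plant 7 NM-supported and 3 XM-only 3'UTR-end elements; the inventory
    reports 10 genes and the accession filter recovers the 7."""
    spec = FixtureSpec(
        seed=5, n_genes=10,
        planted_repeats=(
            PlantedRepeat("AluYRa1", C.UTR3_END, Orientation.SENSE, 7,
                          accession_class="NM"),
            PlantedRepeat("AluYRa1", C.UTR3_END, Orientation.SENSE, 3,
                          accession_class="XM")))
    files, _ = generate_fixture(spec, tmp_path)
    models = [build_model(r) for r in read_genepred(files["refgene"])]
    calls = locate_all(read_rmsk(files["rmsk"]), models)
    inv = gene_inventory(calls)
    assert len(inv) == 10
    assert (inv.support == "NM").sum() == 7 and (inv.support == "XM").sum() == 3
    assert len(gene_inventory(calls, accession_classes={"NM"})) == 7


def test_calls_tsv_roundtrip(tmp_path):
    calls = _utr3_end_calls(2, 2)
    p = tmp_path / "calls.tsv"
    write_calls(calls, p)
    assert read_calls(p) == calls
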