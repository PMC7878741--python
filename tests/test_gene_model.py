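"""UTR/CDS decomposition, 3'UTR lengths, and cross-species comparison."""

import random

import pytest

from aluterm.gene_model import (build_model, compare_utr3, select_isoform,
                                utr3_length)
from aluterm.synthetic_data import random_instance
from helpers import make_genepred, make_model, reflect_genepred


def test_plus_strand_single_exon_decomposition():
    m = make_model(strand="+", tx=(0, 150), cds=(50, 100))
    assert m.utr5_blocks == ((0, 50),)
    assert m.cds_blocks == ((50, 100),)
    assert m.utr3_blocks == ((100, 150),)
    assert m.tx_end_point == 150 and m.terminal3_base == 149


def test_minus_strand_mirrors_utr_assignment():
    m = make_model(strand="-", tx=(0, 150), cds=(50, 100))
    assert m.utr5_blocks == ((100, 150),)
    assert m.utr3_blocks == ((0, 50),)
    assert m.tx_end_point == 0 and m.terminal3_base == 0


@pytest.mark.parametrize("strand", ["+", "-"])
def test_multi_exon_blocks_match_per_base_labelling(strand):
    """CDS spanning an intron: block decomposition equals labelling every
    exonic base independently."""
    rec = make_genepred(strand=strand, tx=(0, 300), cds=(40, 260),
                        exons=[(0, 100), (120, 200), (220, 300)])
    m = build_model(rec)

    labels = {}
    for s, e in rec.exon_blocks():
        for p in range(s, e):
            if rec.cdsStart <= p < rec.cdsEnd:
                labels[p] = "cds"
            elif p < rec.cdsStart:
                labels[p] = "utr5" if strand == "+" else "utr3"
            else:
                labels[p] = "utr3" if strand == "+" else "utr5"
    for blocks, want in [(m.utr5_blocks, "utr5"), (m.cds_blocks, "cds"),
                         (m.utr3_blocks, "utr3")]:
        got = {p for s, e in blocks for p in range(s, e)}
        assert got == {p for p, l in labels.items() if l == want}


def test_noncoding_flagged_with_empty_blocks():
    m = make_model(tx=(0, 150), cds=(150, 150))
    assert m.noncoding
    assert m.utr5_blocks == m.cds_blocks == m.utr3_blocks == ()
    with pytest.raises(ValueError, match="no 3'UTR"):
        utr3_length(m)


def test_utr3_length_single_and_spliced():
    assert utr3_length(make_model(tx=(0, 150), cds=(50, 100))) == 50
    # spliced: blocks [100,150) and [200,260) -> 110, not the genomic span
    m = make_model(tx=(0, 260), cds=(50, 100),
                   exons=[(0, 150), (200, 260)])
    assert m.utr3_blocks == ((100, 150), (200, 260))
    assert utr3_length(m) == 110


def test_internal_junctions_exclude_tx_bounds():
    m = make_model(tx=(0, 300), cds=(40, 260),
                   exons=[(0, 100), (120, 200), (220, 300)])
    assert m.internal_junctions == (100, 120, 200, 220)


def test_partition_sums_to_spliced_length_on_random_instances():
    rng = random.Random(7)
    for _ in range(200):
        _, m = random_instance(rng)
        if m.noncoding:
            continue
        total = sum(e - s for blocks in
                    (m.utr5_blocks, m.cds_blocks, m.utr3_blocks)
                    for s, e in blocks)
        assert total == m.spliced_length()


def test_strand_mirror_preserves_derived_lengths():
    rng = random.Random(8)
    for _ in range(100):
        _, m = random_instance(rng)
        if m.noncoding:
            continue
        mirrored = build_model(reflect_genepred(m.record))
        assert utr3_length(mirrored) == utr3_length(m)
        assert mirrored.spliced_length() == m.spliced_length()
        assert sum(e - s for s, e in mirrored.utr5_blocks) == \
            sum(e - s for s, e in m.utr5_blocks)


def test_cds_outside_tx_span_rejected():
    rec = make_genepred(tx=(0, 150), cds=(50, 100))
    bad = type(rec)(**{**rec.__dict__, "cdsEnd": 200, "txEnd": 150,
                       "exonEnds": rec.exonEnds})
    with pytest.raises(Exception):
        build_model(bad)


# -- cross-species comparison ----------------------------------------------

def _model_with_utr3(length, name="NM_1", name2="PDK4"):
    return make_model(name=name, name2=name2, tx=(0, 100 + length),
                      cds=(0, 100))


def test_compare_utr3_shorter_verdict():
    cmp = compare_utr3({"cyno": _model_with_utr3(1412),
                        "human": _model_with_utr3(2283)}, "PDK4")
    assert cmp.lengths == {"cyno": 1412, "human": 2283}
    assert cmp.verdict == "cyno-shorter"


def test_compare_utr3_similar_within_tolerance():
    assert compare_utr3({"a": _model_with_utr3(1000),
                         "b": _model_with_utr3(1000)}, "G").verdict == \
        "similar"
    assert compare_utr3({"a": _model_with_utr3(1000),
                         "b": _model_with_utr3(1050)}, "G").verdict == \
        "similar"
    assert compare_utr3({"a": _model_with_utr3(1000),
                         "b": _model_with_utr3(1200)}, "G").verdict == \
        "a-shorter"


def test_compare_utr3_missing_species_recorded_not_raised():
    cmp = compare_utr3({"a": _model_with_utr3(100),
                        "b": _model_with_utr3(120), "c": None}, "G")
    assert cmp.missing == ("c",)
    with pytest.raises(ValueError, match="two species"):
        compare_utr3({"a": _model_with_utr3(100), "c": None}, "G")


def test_select_isoform_prefers_registered_longest():
    models = [
        make_model(name="NM_1", name2="G", tx=(0, 200), cds=(0, 100)),
        make_model(name="NM_2", name2="G", tx=(0, 300), cds=(0, 100)),
        make_model(name="XM_9", name2="G", tx=(0, 900), cds=(0, 100)),
    ]
    assert select_isoform(models, "G").accession == "NM_2"
    only_xm = [m for m in models if m.accession.startswith("XM_")]
    assert select_isoform(only_xm, "G") is None
    assert select_isoform(only_xm, "G",
                          include_predicted=True).accession == "XM_9"
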