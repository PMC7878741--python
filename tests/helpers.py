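"""Builders shared across the test modules."""

from __future__ import annotations

from dataclasses import replace

from aluterm.gene_model import TranscriptModel, build_model
from aluterm.ucsc_io import GenePredRecord, RmskRecord


def make_genepred(name="NM_000001", chrom="chr1", strand="+",
                  tx=(0, 150), cds=(50, 100), exons=None,
                  name2="G1", **kwargs) -> GenePredRecord:
    if exons is None:
        exons = [tx]
    starts, ends = zip(*exons)
    return GenePredRecord(
        name=name, chrom=chrom, strand=strand,
        txStart=tx[0], txEnd=tx[1], cdsStart=cds[0], cdsEnd=cds[1],
        exonCount=len(exons), exonStarts=tuple(starts),
        exonEnds=tuple(ends), name2=name2, **kwargs)


def make_model(**kwargs) -> TranscriptModel:
    return build_model(make_genepred(**kwargs))


def make_rmsk(chrom="chr1", span=(0, 100), strand="+", name="AluYRa1",
              consensus_start=1, consensus_length=None, rep_id=1,
              rep_class="SINE", rep_family="Alu") -> RmskRecord:
    """An rmsk record whose consensus slice matches its genomic length,
    encoded with the strand-appropriate sign convention."""
    a, b = span
    ce = consensus_start + (b - a) - 1
    if consensus_length is None:
        consensus_length = ce
    left = -(consensus_length - ce)
    if strand == "+":
        rs, re_, rl = consensus_start, ce, left
    else:
        rs, re_, rl = left, ce, consensus_start
    return RmskRecord(
        bin=0, swScore=2000, milliDiv=10, milliDel=0, milliIns=0,
        genoName=chrom, genoStart=a, genoEnd=b, genoLeft=-1000,
        strand=strand, repName=name, repClass=rep_class,
        repFamily=rep_family, repStart=rs, repEnd=re_, repLeft=rl,
        id=rep_id)


def reflect_genepred(rec: GenePredRecord, pivot: int = 100_000
                     ) -> GenePredRecord:
    """Mirror a transcript about ``pivot`` and flip its strand; all
    strand-aware derived quantities must be invariant."""
    f = lambda x: pivot - x
    return replace(
        rec,
        strand="-" if rec.strand == "+" else "+",
        txStart=f(rec.txEnd), txEnd=f(rec.txStart),
        cdsStart=f(rec.cdsEnd), cdsEnd=f(rec.cdsStart),
        exonStarts=tuple(sorted(f(e) for e in rec.exonEnds)),
        exonEnds=tuple(sorted(f(s) for s in rec.exonStarts)))
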