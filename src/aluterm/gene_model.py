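"""Strand-aware transcript features derived from genePred records.

A :class:`TranscriptModel` decomposes the exon blocks of a transcript into
5'UTR, CDS and 3'UTR blocks and exposes the biological terminal and ORF
boundary positions the positional classifier tests against.  Genomic
coordinates stay 0-based half-open throughout; "biological" start/end means
the transcription start and end in the direction of transcription, so on the
"-" strand the biological 3' end is ``txStart``.

UCSC's half-open convention makes some coordinates *exclusive* (``txEnd``,
``cdsEnd``): the corresponding terminal/boundary *base* is the coordinate
minus one.  Both the raw coordinate (``tx_end_point`` etc.) and the inclusive
base (``terminal3_base`` etc.) are exposed, because boundary-overlap tests
need the two views.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .ucsc_io import GenePredRecord

__all__ = ["TranscriptModel", "build_model", "utr3_length", "compare_utr3",
           "select_isoform", "Utr3Comparison"]

Block = tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """A genePred record plus its UTR/CDS decomposition.

    ``utr5_blocks``/``cds_blocks``/``utr3_blocks`` partition the exonic
    bases; noncoding transcripts (cdsStart == cdsEnd) have all three empty
    and are flagged ``noncoding`` — their exon blocks remain available on
    the record.
    """

    record: GenePredRecord
    utr5_blocks: tuple[Block, ...]
    cds_blocks: tuple[Block, ...]
    utr3_blocks: tuple[Block, ...]
    noncoding: bool

    # -- identity conveniences -------------------------------------------
    @property
    def accession(self) -> str:
        return self.record.name

    @property
    def gene(self) -> str:
        return self.record.name2

    @property
    def chrom(self) -> str:
        return self.record.chrom

    @property
    def strand(self) -> str:
        return self.record.strand

    @property
    def coding(self) -> bool:
        return not self.noncoding

    def exon_blocks(self) -> tuple[Block, ...]:
        return self.record.exon_blocks()

    # -- biological terminal coordinates ---------------------------------
    @property
    def tx_start_point(self) -> int:
        """Transcription start, strand-aware (raw UCSC coordinate)."""
        return self.record.txStart if self.strand == "+" else self.record.txEnd

    @property
    def tx_end_point(self) -> int:
        """Transcription end, strand-aware (raw UCSC coordinate)."""
        return self.record.txEnd if self.strand == "+" else self.record.txStart

    @property
    def orf_start_point(self) -> int:
        return self.record.cdsStart if self.strand == "+" else self.record.cdsEnd

    @property
    def orf_end_point(self) -> int:
        return self.record.cdsEnd if self.strand == "+" else self.record.cdsStart

    # -- inclusive boundary bases ----------------------------------------
    @property
    def terminal5_base(self) -> int:
        """Genomic position of the first transcribed base."""
        return self.record.txStart if self.strand == "+" else self.record.txEnd - 1

    @property
    def terminal3_base(self) -> int:
        """Genomic position of the last transcribed base."""
        return self.record.txEnd - 1 if self.strand == "+" else self.record.txStart

    @property
    def orf_start_base(self) -> int:
        return self.record.cdsStart if self.strand == "+" else self.record.cdsEnd - 1

    @property
    def orf_end_base(self) -> int:
        return self.record.cdsEnd - 1 if self.strand == "+" else self.record.cdsStart

    @property
    def internal_junctions(self) -> tuple[int, ...]:
        """Exon start/end coordinates excluding txStart and txEnd."""
        starts = self.record.exonStarts[1:]
        ends = self.record.exonEnds[:-1]
        return tuple(sorted(starts + ends))

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks())


def build_model(rec: GenePredRecord) -> TranscriptModel:
    """Split a transcript's exons into 5'UTR / CDS / 3'UTR blocks.

    Exonic bases genomically left of cdsStart are 5'UTR on "+" and 3'UTR on
    "-"; symmetric on the right of cdsEnd.  Raises for CDS bounds outside
    the transcript span.
    """
    rec.validate()
    if rec.cdsStart < rec.txStart or rec.cdsEnd > rec.txEnd:
        raise ValueError(
            f"{rec.name}: CDS [{rec.cdsStart},{rec.cdsEnd}) outside "
            f"transcript span [{rec.txStart},{rec.txEnd})")
    if not rec.coding:
        return TranscriptModel(rec, (), (), (), noncoding=True)

    left: list[Block] = []   # genomically left of the CDS
    cds: list[Block] = []
    right: list[Block] = []
    for s, e in rec.exon_blocks():
        if s < rec.cdsStart:
            left.append((s, min(e, rec.cdsStart)))
        cs, ce = max(s, rec.cdsStart), min(e, rec.cdsEnd)
        if cs < ce:
            cds.append((cs, ce))
        if e > rec.cdsEnd:
            right.append((max(s, rec.cdsEnd), e))
    if rec.strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right, left
    return TranscriptModel(rec, tuple(utr5), tuple(cds), tuple(utr3),
                           noncoding=False)


def utr3_length(model: TranscriptModel) -> int:
    """Spliced 3'UTR length in bases (sum of exonic 3'UTR block lengths,
    not the genomic span)."""
    if model.noncoding:
        raise ValueError(f"{model.accession}: no 3'UTR defined "
                         "(noncoding transcript)")
    return sum(e - s for s, e in model.utr3_blocks)


@dataclass(frozen=True)
class Utr3Comparison:
    """Cross-species 3'UTR length comparison for one gene symbol."""

    gene: str
    lengths: dict[str, int]          # species -> spliced 3'UTR bp
    accessions: dict[str, str]
    missing: tuple[str, ...]
    verdict: str                     # e.g. "A-shorter" or "similar"

    def as_rows(self) -> list[dict]:
        return [{"gene": self.gene, "species": sp,
                 "accession": self.accessions[sp],
                 "utr3_len_bp": self.lengths[sp], "verdict": self.verdict}
                for sp in self.lengths]


def compare_utr3(models_by_species: Mapping[str, TranscriptModel | None],
                 gene: str, tolerance: float = 0.1) -> Utr3Comparison:
    """Compare spliced 3'UTR lengths across species for one gene.

    Species mapped to ``None`` (gene absent) are recorded as missing, not an
    error.  The verdict is "similar" when the relative spread
    ``(max-min)/max`` is within ``tolerance``, otherwise
    ``"<species-with-min>-shorter"``.
    """
    lengths: dict[str, int] = {}
    accessions: dict[str, str] = {}
    missing: list[str] = []
    for sp, model in models_by_species.items():
        if model is None:
            missing.append(sp)
            continue
        lengths[sp] = utr3_length(model)
        accessions[sp] = model.accession
    if len(lengths) < 2:
        raise ValueError(
            f"{gene}: need at least two species with a model, "
            f"got {len(lengths)}")
    lo_sp = min(lengths, key=lambda s: (lengths[s], s))
    hi = max(lengths.values())
    lo = lengths[lo_sp]
    if hi == 0 or (hi - lo) / hi <= tolerance:
        verdict = "similar"
    else:
        verdict = f"{lo_sp}-shorter"
    return Utr3Comparison(gene=gene, lengths=lengths, accessions=accessions,
                          missing=tuple(missing), verdict=verdict)


def select_isoform(models: Sequence[TranscriptModel], gene: str,
                   include_predicted: bool = False) -> TranscriptModel | None:
    """Pick the representative coding isoform for a gene symbol.

    Registered (NM_) isoforms are preferred; predicted (XM_) ones are
    considered only with ``include_predicted`` or when no NM_ exists under
    that flag.  Among candidates the longest spliced 3'UTR wins, accession
    string as deterministic tie-break.
    """
    candidates = [m for m in models if m.gene == gene and m.coding]
    if not candidates:
        return None
    nm = [m for m in candidates if m.record.accession_class == "NM"]
    if nm:
        pool = nm
    elif include_predicted:
        pool = [m for m in candidates if m.record.accession_class == "XM"] \
            or candidates
    else:
        return None
    return max(pool, key=lambda m: (utr3_length(m), m.accession))
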