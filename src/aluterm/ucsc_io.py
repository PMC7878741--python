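"""Readers and writers for UCSC annotation tables and TAPAS output.

Three tab-separated dialects are handled:

* **genePred** — gene models as distributed by UCSC (``refGene.txt``,
  ``refFlat.txt``).  Accepted layouts: 10-column basic genePred, 11-column
  ``bin`` + basic, 11-column refFlat (gene symbol + basic), 15-column
  extended genePred and 16-column ``bin`` + extended.  All genomic
  coordinates are 0-based half-open, exon lists are comma-separated with a
  trailing comma.
* **rmsk** — the 17-column RepeatMasker annotation table.  The
  strand-dependent sign convention of ``repStart``/``repEnd``/``repLeft``
  is normalised at parse time into a single
  ``(consensus_start, consensus_end, consensus_left)`` view so downstream
  code never branches on the raw sign trick.
* **TAPAS** — six columns: gene, chromosome, strand, polyadenylation
  sites, per-site abundances, read count.  Multi-site fields are
  comma-separated (whitespace also accepted on input).

Plain and gzip-compressed files are both accepted; compression is sniffed
from the magic bytes, not the file name.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "TableFormatError",
    "GenePredRecord",
    "RmskRecord",
    "ApaRecord",
    "read_genepred",
    "write_genepred",
    "read_rmsk",
    "write_rmsk",
    "read_tapas",
    "write_tapas",
    "write_bed6",
    "open_text",
]


class TableFormatError(ValueError):
    """A malformed table row, located by file, line number and field."""

    def __init__(self, message: str, path=None, line: int | None = None,
                 field_name: str | None = None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if field_name is not None:
            loc.append(f"field '{field_name}'")
        prefix = " ".join(loc)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.path = path
        self.line = line
        self.field_name = field_name


def open_text(path):
    """Open a possibly gzip-compressed text file, sniffing magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# genePred
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePredRecord:
    """One genePred row: a transcript's genomic structure.

    Coordinates are 0-based half-open (UCSC table native).  ``bin`` and the
    extended-genePred columns (``score``, ``cdsStartStat``, ``cdsEndStat``,
    ``exonFrames``) are kept when present so a parsed file can be re-emitted
    unchanged.
    """

    name: str
    chrom: str
    strand: str
    txStart: int
    txEnd: int
    cdsStart: int
    cdsEnd: int
    exonCount: int
    exonStarts: tuple[int, ...]
    exonEnds: tuple[int, ...]
    name2: str = ""
    bin: int | None = None
    score: int = 0
    cdsStartStat: str = "unk"
    cdsEndStat: str = "unk"
    exonFrames: tuple[int, ...] | None = None

    @property
    def coding(self) -> bool:
        return self.cdsStart < self.cdsEnd

    @property
    def accession_class(self) -> str:
        """'NM' for registered, 'XM' for predicted, 'other' otherwise."""
        if self.name.startswith("NM_"):
            return "NM"
        if self.name.startswith("XM_"):
            return "XM"
        return "other"

    def exon_blocks(self) -> tuple[tuple[int, int], ...]:
        return tuple(zip(self.exonStarts, self.exonEnds))

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise TableFormatError(f"bad strand {self.strand!r}",
                                   field_name="strand")
        if not (self.txStart <= self.cdsStart <= self.cdsEnd <= self.txEnd):
            raise TableFormatError(
                "coordinate order violated: need "
                "txStart <= cdsStart <= cdsEnd <= txEnd, got "
                f"{self.txStart},{self.cdsStart},{self.cdsEnd},{self.txEnd}",
                field_name="cdsStart/cdsEnd")
        if len(self.exonStarts) != self.exonCount or \
                len(self.exonEnds) != self.exonCount:
            raise TableFormatError(
                f"exonCount {self.exonCount} does not match exon lists "
                f"({len(self.exonStarts)}/{len(self.exonEnds)})",
                field_name="exonCount")
        prev_end = None
        for s, e in zip(self.exonStarts, self.exonEnds):
            if s >= e:
                raise TableFormatError(f"empty/inverted exon [{s},{e})",
                                       field_name="exonStarts")
            if prev_end is not None and s < prev_end:
                raise TableFormatError(
                    "exons unsorted or overlapping", field_name="exonStarts")
            prev_end = e
        if self.exonStarts[0] != self.txStart or self.exonEnds[-1] != self.txEnd:
            raise TableFormatError(
                "first exon must start at txStart and last end at txEnd",
                field_name="exonStarts")


_INT_RE = re.compile(r"-?\d+$")


def _parse_int_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.strip().rstrip(",").split(",") if x != "")


def _fmt_int_list(values: Sequence[int]) -> str:
    return "".join(f"{v}," for v in values)


def read_genepred(path, has_bin: str = "auto") -> list[GenePredRecord]:
    """Parse a genePred/refGene/refFlat table into records.

    ``has_bin`` is tri-state: "auto" dispatches on column count and whether
    the first column is an integer; "yes"/"no" force the interpretation.
    refFlat rows (gene symbol first, then a 10-column basic genePred) are
    recognised automatically: their first column is not an integer.
    """
    if has_bin not in ("auto", "yes", "no"):
        raise ValueError("has_bin must be 'auto', 'yes' or 'no'")
    records: list[GenePredRecord] = []
    with open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                records.append(_parse_genepred_row(cols, has_bin))
            except TableFormatError as err:
                raise TableFormatError(str(err), path=path, line=lineno) from None
            except ValueError as err:
                raise TableFormatError(str(err), path=path, line=lineno) from None
    return records


def _parse_genepred_row(cols: list[str], has_bin: str) -> GenePredRecord:
    n = len(cols)
    first_is_int = bool(_INT_RE.match(cols[0]))
    if has_bin == "yes":
        binned = True
    elif has_bin == "no":
        binned = False
    else:
        # refGene is 16 (bin+ext) and refFlat 11 (symbol+basic); an 11-column
        # bin+basic table is told apart from refFlat by the integer bin.
        binned = n in (11, 16) and first_is_int

    bin_val: int | None = None
    name2 = ""
    if binned:
        bin_val = int(cols[0])
        cols = cols[1:]
        n -= 1
    elif n == 11 and not first_is_int:
        # refFlat: geneName precedes the basic genePred columns
        name2 = cols[0]
        cols = cols[1:]
        n -= 1

    if n not in (10, 15):
        raise TableFormatError(
            f"unrecognised genePred layout with {n} payload columns")

    rec = GenePredRecord(
        name=cols[0],
        chrom=cols[1],
        strand=cols[2],
        txStart=int(cols[3]),
        txEnd=int(cols[4]),
        cdsStart=int(cols[5]),
        cdsEnd=int(cols[6]),
        exonCount=int(cols[7]),
        exonStarts=_parse_int_list(cols[8]),
        exonEnds=_parse_int_list(cols[9]),
        name2=cols[11] if n == 15 else name2,
        bin=bin_val,
        score=int(cols[10]) if n == 15 else 0,
        cdsStartStat=cols[12] if n == 15 else "unk",
        cdsEndStat=cols[13] if n == 15 else "unk",
        exonFrames=_parse_int_list(cols[14]) if n == 15 else None,
    )
    rec.validate()
    return rec


def write_genepred(records: Iterable[GenePredRecord], path,
                   layout: str = "auto") -> None:
    """Write records as a genePred table.

    ``layout``: "refgene" (bin + 15 extended columns), "refflat"
    (geneName + 10 basic columns), "basic" (10 columns), or "auto", which
    picks refgene when every record carries a bin and exonFrames, else basic.
    """
    records = list(records)
    if layout == "auto":
        if records and all(r.bin is not None and r.exonFrames is not None
                           for r in records):
            layout = "refgene"
        else:
            layout = "basic"
    with open(path, "w") as fh:
        for r in records:
            basic = [r.name, r.chrom, r.strand, str(r.txStart), str(r.txEnd),
                     str(r.cdsStart), str(r.cdsEnd), str(r.exonCount),
                     _fmt_int_list(r.exonStarts), _fmt_int_list(r.exonEnds)]
            if layout == "refgene":
                frames = r.exonFrames if r.exonFrames is not None \
                    else (-1,) * r.exonCount
                cols = [str(r.bin if r.bin is not None else 0), *basic,
                        str(r.score), r.name2, r.cdsStartStat, r.cdsEndStat,
                        _fmt_int_list(frames)]
            elif layout == "refflat":
                cols = [r.name2, *basic]
            elif layout == "basic":
                cols = basic
            else:
                raise ValueError(f"unknown layout {layout!r}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmskRecord:
    """One row of the UCSC RepeatMasker table.

    ``repStart``/``repEnd``/``repLeft`` carry RepeatMasker's strand-dependent
    sign convention: on "+" the consensus interval is [repStart, repEnd] with
    repLeft = -(bases of consensus past repEnd); on "-" the start/left roles
    swap, so the interval is [repLeft, repEnd] and repStart holds the
    negative remainder.  The ``consensus_*`` properties expose the
    normalised view (1-based inclusive).
    """

    bin: int
    swScore: int
    milliDiv: int
    milliDel: int
    milliIns: int
    genoName: str
    genoStart: int
    genoEnd: int
    genoLeft: int
    strand: str
    repName: str
    repClass: str
    repFamily: str
    repStart: int
    repEnd: int
    repLeft: int
    id: int
    flagged: bool = field(default=False, compare=False)

    @property
    def consensus_start(self) -> int:
        return self.repStart if self.strand == "+" else self.repLeft

    @property
    def consensus_end(self) -> int:
        return self.repEnd

    @property
    def consensus_left(self) -> int:
        """Bases of the consensus remaining past consensus_end (>= 0)."""
        raw = self.repLeft if self.strand == "+" else self.repStart
        return -raw

    @property
    def span(self) -> tuple[int, int]:
        return (self.genoStart, self.genoEnd)

    def sign_convention_ok(self) -> bool:
        if self.strand == "+":
            return (self.repStart >= 1 and self.repEnd >= self.repStart
                    and self.repLeft <= 0)
        return (self.repLeft >= 1 and self.repEnd >= self.repLeft
                and self.repStart <= 0)


_RMSK_FIELDS = ("bin", "swScore", "milliDiv", "milliDel", "milliIns",
                "genoName", "genoStart", "genoEnd", "genoLeft", "strand",
                "repName", "repClass", "repFamily", "repStart", "repEnd",
                "repLeft", "id")
_RMSK_INT = {f for f in _RMSK_FIELDS
             if f not in ("genoName", "strand", "repName", "repClass",
                          "repFamily")}


def read_rmsk(path) -> list[RmskRecord]:
    """Parse a 17-column UCSC rmsk table.

    Rows violating the consensus sign convention are kept but flagged and
    reported with a warning — real tables contain such edge cases.
    """
    records: list[RmskRecord] = []
    with open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 17:
                raise TableFormatError(
                    f"expected 17 columns, found {len(cols)}",
                    path=path, line=lineno)
            kwargs = {}
            for name, value in zip(_RMSK_FIELDS, cols):
                try:
                    kwargs[name] = int(value) if name in _RMSK_INT else value
                except ValueError:
                    raise TableFormatError(
                        f"non-integer value {value!r}", path=path,
                        line=lineno, field_name=name) from None
            rec = RmskRecord(**kwargs)
            if rec.genoStart >= rec.genoEnd:
                raise TableFormatError(
                    f"genoStart {rec.genoStart} >= genoEnd {rec.genoEnd}",
                    path=path, line=lineno, field_name="genoStart")
            if not rec.sign_convention_ok():
                warnings.warn(
                    f"{path} line {lineno}: rmsk consensus sign convention "
                    f"violated for {rec.repName} ({rec.strand} strand); "
                    "record flagged, not dropped", stacklevel=2)
                rec = RmskRecord(**{**kwargs, "flagged": True})
            records.append(rec)
    return records


def write_rmsk(records: Iterable[RmskRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join(str(getattr(r, f)) for f in _RMSK_FIELDS) + "\n")


# ---------------------------------------------------------------------------
# TAPAS six-column output
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ApaRecord:
    """One gene's polyadenylation-site calls in TAPAS output format."""

    gene: str
    chrom: str
    strand: str
    apa_sites: tuple[int, ...]
    abundances: tuple[float, ...]
    read_count: int

    def validate(self) -> None:
        if len(self.apa_sites) != len(self.abundances):
            raise TableFormatError(
                f"gene {self.gene}: {len(self.apa_sites)} sites but "
                f"{len(self.abundances)} abundances", field_name="abundances")
        if self.read_count < 0:
            raise TableFormatError(f"gene {self.gene}: negative read count",
                                   field_name="read_count")
        if any(a < 0 for a in self.abundances):
            raise TableFormatError(f"gene {self.gene}: negative abundance",
                                   field_name="abundances")


_LIST_SPLIT = re.compile(r"[,\s]+")


def _split_list(text: str) -> list[str]:
    text = text.strip()
    if text in ("", ".", "NA"):
        return []
    return [t for t in _LIST_SPLIT.split(text) if t]


def read_tapas(path) -> list[ApaRecord]:
    """Parse TAPAS six-column output (gene, chrom, strand, sites,
    abundances, read count).  Empty site lists are permitted."""
    records: list[ApaRecord] = []
    with open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise TableFormatError(
                    f"expected 6 columns, found {len(cols)}",
                    path=path, line=lineno)
            try:
                rec = ApaRecord(
                    gene=cols[0], chrom=cols[1], strand=cols[2],
                    apa_sites=tuple(int(x) for x in _split_list(cols[3])),
                    abundances=tuple(float(x) for x in _split_list(cols[4])),
                    read_count=int(cols[5]))
                rec.validate()
            except (TableFormatError, ValueError) as err:
                raise TableFormatError(str(err), path=path,
                                       line=lineno) from None
            records.append(rec)
    return records


def _fmt_float(x: float) -> str:
    return format(x, "g")


def write_tapas(records: Iterable[ApaRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join([
                r.gene, r.chrom, r.strand,
                ",".join(str(p) for p in r.apa_sites),
                ",".join(_fmt_float(a) for a in r.abundances),
                str(r.read_count)]) + "\n")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed6(rows: Iterable[tuple[str, int, int, str, int, str]],
               path) -> None:
    """Write (chrom, start, end, name, score, strand) tuples as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
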