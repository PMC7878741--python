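"""Positional classification of repeat elements within gene models.

Every repeat x transcript pair with exonic overlap (or abutting a transcript
terminus) is assigned the positional categories it satisfies, and one
*primary* category by precedence.  The taxonomy distinguishes the transcript
termini (3'UTR end, 5'UTR start), the ORF boundaries, internal splice
junctions, and pure containment (inside an exon, internal to a UTR).
Orientation is SENSE when the repeat's annotated strand matches the
transcript's — the configuration in which an Alu's own poly-A machinery can
act on the transcript — and ANTISENSE otherwise, the classic exonization
configuration.

Boundary semantics (half-open genomic intervals throughout):

* A repeat ``[a, b)`` overlaps an *inclusive* coordinate ``p`` (a genomic
  base such as txStart, an ORF boundary base or a junction) iff
  ``a <= p < b``.
* Tests against an *exclusive* UCSC coordinate (txEnd — the biological 3'
  end of a "+" transcript and the biological 5' start of a "-" transcript)
  use the closed form ``a <= p <= b`` so that an element ending exactly at,
  or starting exactly at, the terminus counts as touching it.
* ``proximity_bp`` widens the terminal tests symmetrically; the default 0
  is a strict overlap requirement, so an element stopping short of the
  terminus is UTR3_INTERNAL, not UTR3_END.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .gene_model import TranscriptModel
from .ucsc_io import RmskRecord

__all__ = ["PositionalCategory", "Orientation", "PositionalCall",
           "classify_pair", "locate_all", "summarize_positions",
           "gene_inventory", "write_calls", "read_calls", "PRECEDENCE"]


class PositionalCategory(enum.Enum):
    UTR5_START = "UTR5_START"
    ORF_START = "ORF_START"
    INSIDE_EXON = "INSIDE_EXON"
    EXON_SPLICING = "EXON_SPLICING"
    ORF_END = "ORF_END"
    UTR3_END = "UTR3_END"
    UTR3_INTERNAL = "UTR3_INTERNAL"
    UTR5_INTERNAL = "UTR5_INTERNAL"
    NO_EXONIC_OVERLAP = "NO_EXONIC_OVERLAP"


class Orientation(enum.Enum):
    SENSE = "SENSE"
    ANTISENSE = "ANTISENSE"


#: Primary-category precedence, terminal events first.  Boundary events
#: outrank containment; NO_EXONIC_OVERLAP is the fallback.
PRECEDENCE: tuple[PositionalCategory, ...] = (
    PositionalCategory.UTR3_END,
    PositionalCategory.UTR5_START,
    PositionalCategory.ORF_END,
    PositionalCategory.ORF_START,
    PositionalCategory.EXON_SPLICING,
    PositionalCategory.UTR3_INTERNAL,
    PositionalCategory.UTR5_INTERNAL,
    PositionalCategory.INSIDE_EXON,
)
_RANK = {c: i for i, c in enumerate(PRECEDENCE)}


@dataclass(frozen=True)
class PositionalCall:
    """The locator's verdict for one repeat x transcript pair."""

    repeat_id: int
    rep_name: str
    rep_class: str
    rep_family: str
    rep_strand: str
    chrom: str
    geno_start: int
    geno_end: int
    transcript_id: str
    gene: str
    category: PositionalCategory
    all_categories: frozenset[PositionalCategory]
    orientation: Orientation
    overlap_bp: int
    distance_to_terminal: int


def _touches(a: int, b: int, p: int, proximity: int, closed: bool) -> bool:
    if closed:
        return a - proximity <= p <= b + proximity
    return a - proximity <= p < b + proximity


def _contained(a: int, b: int, blocks: Iterable[tuple[int, int]]) -> bool:
    return any(s <= a and b <= e for s, e in blocks)


def _overlap_bp(a: int, b: int, blocks: Iterable[tuple[int, int]]) -> int:
    return sum(max(0, min(b, e) - max(a, s)) for s, e in blocks)


def classify_pair(rep: RmskRecord, model: TranscriptModel,
                  proximity_bp: int = 0) -> PositionalCall:
    """Classify one repeat against one transcript model.

    Returns a call whose ``category`` is the highest-precedence satisfied
    category and whose ``all_categories`` retains every satisfied one.
    Raises on a chromosome mismatch.
    """
    if rep.genoName != model.chrom:
        raise ValueError(
            f"chromosome mismatch: repeat on {rep.genoName}, "
            f"transcript {model.accession} on {model.chrom}")
    a, b = rep.genoStart, rep.genoEnd
    strand = model.strand
    cats: set[PositionalCategory] = set()

    overlap = _overlap_bp(a, b, model.exon_blocks())

    # terminal tests: txEnd is an exclusive coordinate -> closed test
    if model.utr3_blocks:
        end = model.tx_end_point
        if _touches(a, b, end, proximity_bp, closed=(strand == "+")) and \
                _in_blocks(model.terminal3_base, model.utr3_blocks):
            cats.add(PositionalCategory.UTR3_END)
    if model.utr5_blocks:
        start = model.tx_start_point
        if _touches(a, b, start, proximity_bp, closed=(strand == "-")) and \
                _in_blocks(model.terminal5_base, model.utr5_blocks):
            cats.add(PositionalCategory.UTR5_START)

    if model.coding:
        if a <= model.orf_start_base < b:
            cats.add(PositionalCategory.ORF_START)
        if a <= model.orf_end_base < b:
            cats.add(PositionalCategory.ORF_END)

    if any(a <= j < b for j in model.internal_junctions):
        cats.add(PositionalCategory.EXON_SPLICING)

    boundary = cats & {PositionalCategory.UTR3_END,
                       PositionalCategory.UTR5_START,
                       PositionalCategory.ORF_START,
                       PositionalCategory.ORF_END,
                       PositionalCategory.EXON_SPLICING}
    if overlap > 0 and not boundary:
        if _contained(a, b, model.utr3_blocks):
            cats.add(PositionalCategory.UTR3_INTERNAL)
        elif _contained(a, b, model.utr5_blocks):
            cats.add(PositionalCategory.UTR5_INTERNAL)
        if _contained(a, b, model.exon_blocks()):
            cats.add(PositionalCategory.INSIDE_EXON)

    if not cats:
        primary = PositionalCategory.NO_EXONIC_OVERLAP
        all_cats = frozenset({primary})
    else:
        primary = min(cats, key=_RANK.__getitem__)
        all_cats = frozenset(cats)

    return PositionalCall(
        repeat_id=rep.id, rep_name=rep.repName, rep_class=rep.repClass,
        rep_family=rep.repFamily, rep_strand=rep.strand, chrom=rep.genoName,
        geno_start=a, geno_end=b,
        transcript_id=model.accession, gene=model.gene,
        category=primary, all_categories=all_cats,
        orientation=(Orientation.SENSE if rep.strand == strand
                     else Orientation.ANTISENSE),
        overlap_bp=overlap,
        distance_to_terminal=_terminal_distance(a, b, model),
    )


def _in_blocks(p: int, blocks: Iterable[tuple[int, int]]) -> bool:
    return any(s <= p < e for s, e in blocks)


def _terminal_distance(a: int, b: int, model: TranscriptModel) -> int:
    """Signed bp from the repeat to the biological 3' end: 0 when touching,
    positive when the repeat lies upstream (5' side) of the terminus,
    negative when it lies past it."""
    e = model.tx_end_point
    if model.strand == "+":
        if a <= e <= b:
            return 0
        return e - b if b < e else -(a - e)
    if a <= e < b:
        return 0
    return a - e if a > e else -(e - b)


def locate_all(reps: Sequence[RmskRecord], models: Sequence[TranscriptModel],
               proximity_bp: int = 0, rep_name: str | None = None,
               emit_nonoverlapping: bool = False) -> list[PositionalCall]:
    """Classify every candidate repeat x transcript pair.

    Candidates are found with an interval index over transcript spans
    (padded by one base plus ``proximity_bp`` so terminus-abutting elements
    pair up).  Output is one call per pair; calls whose primary category is
    NO_EXONIC_OVERLAP are dropped unless ``emit_nonoverlapping``.  Order is
    deterministic: (chrom, genoStart, genoEnd, accession).
    """
    trees: dict[str, IntervalTree] = {}
    by_iv: dict[tuple[str, int, int], list[TranscriptModel]] = {}
    for m in models:
        iv = (m.chrom, m.record.txStart, m.record.txEnd + 1)
        by_iv.setdefault(iv, []).append(m)
    for (chrom, s, e), ms in by_iv.items():
        trees.setdefault(chrom, IntervalTree()).addi(s, e, ms)

    calls: list[PositionalCall] = []
    pad = proximity_bp + 1
    for rep in reps:
        if rep_name is not None and rep.repName != rep_name:
            continue
        tree = trees.get(rep.genoName)
        if tree is None:
            continue
        hits = tree.overlap(rep.genoStart - pad + 1, rep.genoEnd + pad)
        for hit in hits:
            for model in hit.data:
                call = classify_pair(rep, model, proximity_bp)
                if call.category is PositionalCategory.NO_EXONIC_OVERLAP \
                        and not emit_nonoverlapping:
                    continue
                calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.geno_start, c.geno_end,
                              c.transcript_id))
    return calls


_GROUP_KEYS = {"repClass": "rep_class", "repFamily": "rep_family",
               "repName": "rep_name"}


def summarize_positions(calls: Sequence[PositionalCall],
                        group_by: str = "repName") -> pd.DataFrame:
    """Count calls by (group, category, orientation).

    Returns a dense table: every observed group value crossed with all nine
    categories and both orientations, zero-filled, so figure-style bar
    heights can be read off directly.  Counts sum to ``len(calls)``.
    """
    if group_by not in _GROUP_KEYS:
        raise ValueError(f"unknown group_by {group_by!r}; expected one of "
                         f"{sorted(_GROUP_KEYS)}")
    attr = _GROUP_KEYS[group_by]
    groups = sorted({getattr(c, attr) for c in calls})
    index = pd.MultiIndex.from_product(
        [groups, [c.value for c in PositionalCategory],
         [o.value for o in Orientation]],
        names=[group_by, "category", "orientation"])
    counts = pd.Series(0, index=index, dtype=int)
    for c in calls:
        counts.loc[(getattr(c, attr), c.category.value,
                    c.orientation.value)] += 1
    out = counts.rename("count").reset_index()
    return out


def gene_inventory(calls: Sequence[PositionalCall],
                   category: PositionalCategory = PositionalCategory.UTR3_END,
                   rep_name: str | None = "AluYRa1",
                   accession_classes: set[str] | None = None) -> pd.DataFrame:
    """Collapse transcript-level calls to a per-gene table.

    Keeps calls matching ``category`` (and ``rep_name`` when given), groups
    by gene symbol, and reports whether support comes from registered (NM_)
    or predicted (XM_) accessions.  ``accession_classes`` filters genes to
    those supported by at least one accession of a requested class
    ({"NM"}, {"NM","XM"}, ...).
    """
    if accession_classes is None:
        accession_classes = {"NM", "XM", "other"}
    rows: dict[str, dict] = {}
    for c in calls:
        if c.category is not category:
            continue
        if rep_name is not None and c.rep_name != rep_name:
            continue
        acc_class = ("NM" if c.transcript_id.startswith("NM_") else
                     "XM" if c.transcript_id.startswith("XM_") else "other")
        row = rows.setdefault(c.gene, {"gene": c.gene, "accessions": set(),
                                       "classes": set(), "n_transcripts": 0})
        if c.transcript_id not in row["accessions"]:
            row["n_transcripts"] += 1
        row["accessions"].add(c.transcript_id)
        row["classes"].add(acc_class)
    out = []
    for gene in sorted(rows):
        row = rows[gene]
        if not (row["classes"] & accession_classes):
            continue
        support = ("NM" if "NM" in row["classes"] else
                   "XM" if "XM" in row["classes"] else "other")
        out.append({"gene": gene,
                    "n_transcripts": row["n_transcripts"],
                    "accessions": ",".join(sorted(row["accessions"])),
                    "support": support})
    return pd.DataFrame(out, columns=["gene", "n_transcripts", "accessions",
                                      "support"])


# ---------------------------------------------------------------------------
# calls TSV round-trip (CLI plumbing)
# ---------------------------------------------------------------------------

_CALL_COLS = ["chrom", "geno_start", "geno_end", "repeat_id", "rep_name",
              "rep_class", "rep_family", "rep_strand", "transcript_id",
              "gene", "category", "all_categories", "orientation",
              "overlap_bp", "distance_to_terminal"]


def write_calls(calls: Sequence[PositionalCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLS) + "\n")
        for c in calls:
            all_cats = ",".join(sorted(x.value for x in c.all_categories))
            fh.write("\t".join(str(x) for x in (
                c.chrom, c.geno_start, c.geno_end, c.repeat_id, c.rep_name,
                c.rep_class, c.rep_family, c.rep_strand, c.transcript_id,
                c.gene, c.category.value, all_cats, c.orientation.value,
                c.overlap_bp, c.distance_to_terminal)) + "\n")


def read_calls(path) -> list[PositionalCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CALL_COLS:
            raise ValueError(f"{path}: unexpected calls header")
        for line in fh:
            v = dict(zip(_CALL_COLS, line.rstrip("\n").split("\t")))
            calls.append(PositionalCall(
                repeat_id=int(v["repeat_id"]), rep_name=v["rep_name"],
                rep_class=v["rep_class"], rep_family=v["rep_family"],
                rep_strand=v["rep_strand"], chrom=v["chrom"],
                geno_start=int(v["geno_start"]), geno_end=int(v["geno_end"]),
                transcript_id=v["transcript_id"], gene=v["gene"],
                category=PositionalCategory(v["category"]),
                all_categories=frozenset(
                    PositionalCategory(x)
                    for x in v["all_categories"].split(",") if x),
                orientation=Orientation(v["orientation"]),
                overlap_bp=int(v["overlap_bp"]),
                distance_to_terminal=int(v["distance_to_terminal"])))
    return calls
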