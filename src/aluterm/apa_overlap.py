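"""Join polyadenylation sites against located repeat elements.

TAPAS reports, per gene, every detected polyadenylation site (constitutive
and alternative) with an abundance estimate.  This module asks, for each
site, whether it falls on a target repeat element inserted in the gene —
by default only counting elements in the *sense* orientation, since an
antisense element cannot contribute its own poly-A machinery — and, when it
does, which anatomical region of the element it hits.  The headline
statistics are the fraction of sites on-element and the split across the
poly-A tail and A-rich linker, the two regions expected to seed cleavage.

Genes are excluded from the join (and logged) when the TAPAS strand
contradicts the annotation strand or the representative isoform has no
3'UTR — the "inappropriate gene structure" situations in which a site
cannot be interpreted against the transcript's 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import pandas as pd

from .alu_anatomy import (AnatomyConfig, AnatomyRegion, DEFAULT_ANATOMY,
                          classify_anatomy, occupancy)
from .gene_model import TranscriptModel, select_isoform
from .locator import Orientation
from .ucsc_io import ApaRecord, RmskRecord

__all__ = ["ApaOverlapRow", "ApaSummary", "JoinResult",
           "join_apa_to_elements", "summarize_apa"]


@dataclass(frozen=True)
class ApaOverlapRow:
    """One polyadenylation site tested against the gene's target elements."""

    gene: str
    chrom: str
    apa_pos: int
    abundance: float
    on_element: bool
    element_orientation: Orientation | None
    anatomy: AnatomyRegion | None
    repeat_id: int | None


@dataclass(frozen=True)
class JoinResult:
    rows: tuple[ApaOverlapRow, ...]
    excluded: tuple[tuple[str, str], ...]   # (gene, reason)
    unjoined: tuple[str, ...]               # genes absent from the models


def join_apa_to_elements(apa: Sequence[ApaRecord],
                         reps: Sequence[RmskRecord],
                         models: Sequence[TranscriptModel],
                         cfg: AnatomyConfig = DEFAULT_ANATOMY,
                         target_rep_name: str = "AluYRa1",
                         sense_only: bool = True,
                         include_predicted: bool = True) -> JoinResult:
    """Test every APA site of every gene against target-name elements.

    A site is on-element when it falls within an element's genomic span
    extended by the poly-A tail window on the element's 3' side; with
    ``sense_only`` only elements whose strand matches the transcript
    qualify.  Anatomy is computed per site via consensus mapping.  Genes
    missing from the models are reported as unjoined; strand conflicts and
    missing 3'UTRs are excluded with a reason.
    """
    rows: list[ApaOverlapRow] = []
    excluded: list[tuple[str, str]] = []
    unjoined: list[str] = []
    targets = [r for r in reps if r.repName == target_rep_name]

    for rec in apa:
        model = select_isoform(models, rec.gene,
                               include_predicted=include_predicted)
        if model is None:
            unjoined.append(rec.gene)
            continue
        if model.strand != rec.strand:
            excluded.append((rec.gene, "strand conflict with annotation"))
            continue
        if not model.utr3_blocks:
            excluded.append((rec.gene, "no 3'UTR block"))
            continue
        span = (model.record.txStart, model.record.txEnd)
        candidates = [
            r for r in targets
            if r.genoName == model.chrom
            and r.genoStart < span[1] and r.genoEnd > span[0]
            and (not sense_only or r.strand == model.strand)]
        for pos, abundance in zip(rec.apa_sites, rec.abundances):
            hit = None
            for r in candidates:
                occ = occupancy(r, cfg.polyA_max_extension)
                if occ[0] <= pos < occ[1]:
                    hit = r
                    break
            if hit is None:
                rows.append(ApaOverlapRow(rec.gene, rec.chrom, pos, abundance,
                                          False, None, None, None))
            else:
                call = classify_anatomy(hit, pos, cfg)
                orient = (Orientation.SENSE if hit.strand == model.strand
                          else Orientation.ANTISENSE)
                rows.append(ApaOverlapRow(rec.gene, rec.chrom, pos, abundance,
                                          True, orient, call.region, hit.id))
    return JoinResult(tuple(rows), tuple(excluded), tuple(unjoined))


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ApaSummary:
    """Site (or abundance) weighted overlap percentages.

    ``pct_*`` fields carry one decimal; the ``headline`` tuple is the same
    three on-element/tail/A-rich numbers rounded half-up to integers.
    ``pct_on_element == pct_polyA_tail + pct_a_rich + pct_other_regions``
    up to rounding.
    """

    n_sites: int
    weight: str
    pct_on_element: float
    pct_polyA_tail: float
    pct_a_rich: float
    pct_other_regions: float
    per_gene: pd.DataFrame

    @property
    def headline(self) -> tuple[int, int, int]:
        return (int(_round_half_up(self.pct_on_element)),
                int(_round_half_up(self.pct_polyA_tail)),
                int(_round_half_up(self.pct_a_rich)))


def summarize_apa(rows: Sequence[ApaOverlapRow],
                  weight: str = "sites") -> ApaSummary:
    """Aggregate joined APA rows into overlap percentages.

    ``weight="sites"`` counts sites (the default); ``weight="abundance"``
    weights each site by its abundance.  Percentages are of *all* joined
    sites, so the tail and A-rich percentages are sub-fractions of the
    on-element percentage.  Raises on an empty row set.
    """
    if not rows:
        raise ValueError("no joined APA sites")
    if weight not in ("sites", "abundance"):
        raise ValueError(f"unknown weight {weight!r}")

    def w(row: ApaOverlapRow) -> float:
        return row.abundance if weight == "abundance" else 1.0

    total = sum(w(r) for r in rows)
    if total <= 0:
        raise ValueError("total weight is zero")
    on = sum(w(r) for r in rows if r.on_element)
    tail = sum(w(r) for r in rows if r.anatomy is AnatomyRegion.POLY_A_TAIL)
    arich = sum(w(r) for r in rows if r.anatomy is AnatomyRegion.A_RICH_LINKER)
    other = on - tail - arich

    per_gene_rows = []
    for gene in sorted({r.gene for r in rows}):
        sub = [r for r in rows if r.gene == gene]
        g_total = sum(w(r) for r in sub)
        g_on = sum(w(r) for r in sub if r.on_element)
        per_gene_rows.append({
            "gene": gene, "n_sites": len(sub),
            "weight_total": g_total, "weight_on_element": g_on,
            "pct_on_element": _round_half_up(100.0 * g_on / g_total, 1)})
    per_gene = pd.DataFrame(per_gene_rows,
                            columns=["gene", "n_sites", "weight_total",
                                     "weight_on_element", "pct_on_element"])

    return ApaSummary(
        n_sites=len(rows), weight=weight,
        pct_on_element=_round_half_up(100.0 * on / total, 1),
        pct_polyA_tail=_round_half_up(100.0 * tail / total, 1),
        pct_a_rich=_round_half_up(100.0 * arich / total, 1),
        pct_other_regions=_round_half_up(100.0 * other / total, 1),
        per_gene=per_gene)
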