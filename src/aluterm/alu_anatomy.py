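"""Repeat-consensus coordinate mapping and Alu anatomical classification.

An Alu element is a dimer: a left 7SL-derived monomer, a short A-rich
linker, a right monomer, and a 3' poly-A tail that is not part of the
numbered consensus.  The RepeatMasker table records, for every genomic
repeat copy, which slice of the subfamily consensus it represents
(``consensus_start``..``consensus_end``, 1-based inclusive).  This module
maps genomic positions into that consensus space and classifies them into
anatomy regions, which is how a transcript's 3' terminus can be said to
fall "on the right arm" or "at the poly-A tail" of an inserted element.

The poly-A tail is defined *positionally*: any position past the element's
consensus end on its own 3' side, within a configurable extension window,
is tail.  RepeatMasker does not annotate tails, so a positional definition
is the only one available from the table alone; an optional base
composition check can flag discordant calls when sequence is at hand.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .ucsc_io import RmskRecord

__all__ = ["AnatomyRegion", "AnatomyConfig", "AnatomyCall", "BEYOND_END",
           "OFF_ELEMENT_POS", "genomic_to_consensus", "consensus_to_genomic",
           "classify_anatomy", "scan_cleavage_motifs", "MotifReport",
           "DEFAULT_ANATOMY", "occupancy", "polya_composition_ok",
           "DEFAULT_PAS_HEXAMERS"]


class AnatomyRegion(enum.Enum):
    LEFT_ARM = "LEFT_ARM"
    A_RICH_LINKER = "A_RICH_LINKER"
    RIGHT_ARM = "RIGHT_ARM"
    POLY_A_TAIL = "POLY_A_TAIL"
    OFF_ELEMENT = "OFF_ELEMENT"


class _Marker(enum.Enum):
    BEYOND_END = "beyond_end"
    OFF_ELEMENT = "off_element"


#: Returned by :func:`genomic_to_consensus` for positions past the element's
#: consensus end but within the poly-A extension window.
BEYOND_END = _Marker.BEYOND_END
#: Returned for positions outside the element and its extension window.
OFF_ELEMENT_POS = _Marker.OFF_ELEMENT


@dataclass(frozen=True)
class AnatomyConfig:
    """Consensus intervals (1-based inclusive) delimiting the Alu regions.

    Defaults follow the canonical AluY dimeric layout — left monomer,
    A-rich linker, right monomer over a ~311 bp consensus — and are
    implementation defaults, not measured subfamily coordinates; analyses
    that depend on exact boundaries should construct their own config.
    ``polyA_max_extension`` is how far past the element's genomic 3' end a
    position is still counted as poly-A tail.
    """

    left_arm: tuple[int, int] = (1, 131)
    a_linker: tuple[int, int] = (132, 158)
    right_arm: tuple[int, int] = (159, 311)
    consensus_length: int = 311
    polyA_max_extension: int = 30

    def __post_init__(self):
        la, al, ra = self.left_arm, self.a_linker, self.right_arm
        if not (la[0] == 1 and la[1] + 1 == al[0] and al[1] + 1 == ra[0]
                and ra[1] == self.consensus_length):
            raise ValueError(
                "anatomy intervals must be contiguous and cover "
                f"[1, {self.consensus_length}]: got {la}, {al}, {ra}")
        if not (la[0] <= la[1] and al[0] <= al[1] and ra[0] <= ra[1]):
            raise ValueError("anatomy intervals must be non-empty")
        if self.polyA_max_extension < 0:
            raise ValueError("polyA_max_extension must be >= 0")

    def region_of(self, consensus_pos: int) -> AnatomyRegion:
        if self.left_arm[0] <= consensus_pos <= self.left_arm[1]:
            return AnatomyRegion.LEFT_ARM
        if self.a_linker[0] <= consensus_pos <= self.a_linker[1]:
            return AnatomyRegion.A_RICH_LINKER
        if self.right_arm[0] <= consensus_pos <= self.right_arm[1]:
            return AnatomyRegion.RIGHT_ARM
        # past the numbered consensus: positionally tail
        return AnatomyRegion.POLY_A_TAIL


DEFAULT_ANATOMY = AnatomyConfig()


@dataclass(frozen=True)
class AnatomyCall:
    region: AnatomyRegion
    consensus_pos: int | None      # None for POLY_A_TAIL / OFF_ELEMENT
    genomic_pos: int
    repeat_id: int


def genomic_to_consensus(rep: RmskRecord, pos: int,
                         polyA_max_extension: int = 0):
    """Map a genomic position into the element's consensus coordinates.

    For "+" elements consensus runs left-to-right with the genome; for "-"
    elements it runs right-to-left, so ``consensus_end`` sits at
    ``genoStart``.  Positions past the element's 3' (element-sense) end but
    within ``polyA_max_extension`` return :data:`BEYOND_END`; anything else
    outside the element returns :data:`OFF_ELEMENT_POS`.
    """
    a, b = rep.genoStart, rep.genoEnd
    if a <= pos < b:
        if rep.strand == "+":
            return rep.consensus_start + (pos - a)
        return rep.consensus_end - (pos - a)
    if rep.strand == "+":
        if b <= pos < b + polyA_max_extension:
            return BEYOND_END
    else:
        if a - polyA_max_extension <= pos < a:
            return BEYOND_END
    return OFF_ELEMENT_POS


def consensus_to_genomic(rep: RmskRecord, consensus_pos: int) -> int:
    """Inverse of :func:`genomic_to_consensus` over the element's span."""
    if not (rep.consensus_start <= consensus_pos <= rep.consensus_end):
        raise ValueError(
            f"consensus position {consensus_pos} outside element span "
            f"[{rep.consensus_start},{rep.consensus_end}]")
    if rep.strand == "+":
        return rep.genoStart + (consensus_pos - rep.consensus_start)
    return rep.genoStart + (rep.consensus_end - consensus_pos)


def occupancy(rep: RmskRecord, polyA_max_extension: int = 0) -> tuple[int, int]:
    """Genomic half-open interval covered by the element plus its tail
    window (the window lies on the element's own 3' side)."""
    if rep.strand == "+":
        return (rep.genoStart, rep.genoEnd + polyA_max_extension)
    return (rep.genoStart - polyA_max_extension, rep.genoEnd)


def classify_anatomy(rep: RmskRecord, pos: int,
                     cfg: AnatomyConfig = DEFAULT_ANATOMY,
                     family_gate: str | None = None) -> AnatomyCall:
    """Classify a genomic position into an Alu anatomy region.

    ``family_gate`` optionally restricts calls to elements of a repFamily
    (e.g. "Alu"); a mismatch raises.  Off-element positions yield an
    OFF_ELEMENT call, not an error.
    """
    if family_gate is not None and rep.repFamily != family_gate:
        raise ValueError(
            f"element {rep.repName} is family {rep.repFamily}, "
            f"not {family_gate}")
    c = genomic_to_consensus(rep, pos, cfg.polyA_max_extension)
    if c is OFF_ELEMENT_POS:
        return AnatomyCall(AnatomyRegion.OFF_ELEMENT, None, pos, rep.id)
    if c is BEYOND_END:
        return AnatomyCall(AnatomyRegion.POLY_A_TAIL, None, pos, rep.id)
    region = cfg.region_of(c)
    cpos = None if region is AnatomyRegion.POLY_A_TAIL else c
    return AnatomyCall(region, cpos, pos, rep.id)


def polya_composition_ok(seq: str, pos: int, window: int = 10,
                         min_frac_a: float = 0.8) -> bool:
    """Optional check that a poly-A-tail call sits in A-rich sequence:
    fraction of A in the ``window`` bases starting at ``pos``."""
    chunk = seq[pos:pos + window].upper()
    if not chunk:
        return False
    return chunk.count("A") / len(chunk) >= min_frac_a


# ---------------------------------------------------------------------------
# cleavage / PAS motif scanning
# ---------------------------------------------------------------------------

DEFAULT_PAS_HEXAMERS = ("AATAAA", "ATTAAA")


@dataclass(frozen=True)
class MotifReport:
    """Cleavage-site motif scan: is the dinucleotide immediately 5' of the
    cleavage point CA, and where do PAS hexamers sit upstream of it?

    ``pas_hits`` holds (hexamer, distance) pairs where distance is from the
    hexamer start to the cleavage offset (bp, > 0 means upstream).
    """

    ca_at_cleavage: bool
    cleavage_dinucleotide: str
    pas_hits: tuple[tuple[str, int], ...]


def scan_cleavage_motifs(seq: str, cleavage_offset: int,
                         pas_window: int = 40,
                         hexamers: Sequence[str] = DEFAULT_PAS_HEXAMERS
                         ) -> MotifReport:
    """Scan a sense-strand sequence around a cleavage position.

    ``cleavage_offset`` indexes the first base 3' of the cut (0-based into
    ``seq``); the CA test looks at ``seq[offset-2:offset]``.  PAS hexamers
    are searched in the ``pas_window`` bases upstream of the cut and must
    lie entirely upstream of it; overlapping occurrences are all reported,
    ordered by distance.
    """
    if not (0 <= cleavage_offset <= len(seq)):
        raise ValueError(
            f"cleavage offset {cleavage_offset} outside sequence of length "
            f"{len(seq)}")
    s = seq.upper()
    dinuc = s[max(0, cleavage_offset - 2):cleavage_offset]
    hits: list[tuple[str, int]] = []
    win_start = max(0, cleavage_offset - pas_window)
    window = s[win_start:cleavage_offset]
    for hexamer in hexamers:
        hx = hexamer.upper()
        for m in re.finditer(f"(?={re.escape(hx)})", window):
            hits.append((hx, cleavage_offset - (win_start + m.start())))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return MotifReport(ca_at_cleavage=(dinuc == "CA"),
                       cleavage_dinucleotide=dinuc,
                       pas_hits=tuple(hits))
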