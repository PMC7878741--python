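"""Seeded generator of toy annotation sets with planted ground truth.

The study conditions this package targets — UCSC gene/repeat tables for a
macaque genome plus TAPAS output from a 30-animal RNA-seq cohort — cannot
be redistributed or regenerated at desk scale, so every downstream stage is
exercised against *synthetic* fixtures: a complete refGene / rmsk / TAPAS /
FASTA file set in which every repeat and every polyadenylation site is
planted at coordinates that guarantee its positional category, orientation
and anatomy region.  The planted labels are returned (and serialised) as
:class:`GroundTruth`, so end-to-end runs can be scored for exact recovery.

Genes follow a fixed template — 5'UTR and 3'UTR each confined to a terminal
exon, a CDS spread over ``k >= 3`` exons — with sizes drawn from one seeded
``random.Random`` stream; identical seeds give byte-identical files.  The
template's compartments (UTRs ~700-1500 bp, middle exons ~700 bp, introns
~1 kb) are sized so that a 280-310 bp element, the canonical Alu length,
fits strictly inside any single compartment.

This module also hosts :func:`brute_force_classify`, a per-base re-derivation
of the positional taxonomy kept deliberately free of the interval logic in
:mod:`aluterm.locator`, used as the independent oracle in equivalence tests.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alu_anatomy import (AnatomyConfig, AnatomyRegion, DEFAULT_ANATOMY,
                          consensus_to_genomic)
from .gene_model import TranscriptModel, build_model
from .locator import Orientation, PositionalCategory, PRECEDENCE
from .ucsc_io import (ApaRecord, GenePredRecord, RmskRecord, write_genepred,
                      write_rmsk, write_tapas)

__all__ = ["PlantedRepeat", "PlantedApa", "FixtureSpec", "GroundTruth",
           "TruthRepeat", "TruthApa", "TruthGene", "generate_fixture",
           "fig7_preset", "brute_force_classify", "random_instance"]

REPEAT_LEN_RANGE = (280, 310)

_RANK = {c: i for i, c in enumerate(PRECEDENCE)}

# repName -> (repClass, repFamily) for the names the fixtures use
_REP_TAXONOMY = {
    "MIR": ("SINE", "MIR"), "MIRb": ("SINE", "MIR"),
    "L1MA4": ("LINE", "L1"), "L2": ("LINE", "L2"),
    "MLT1A": ("LTR", "ERVL-MaLR"),
}


def _rep_taxonomy(rep_name: str) -> tuple[str, str]:
    if rep_name.startswith("Alu") or rep_name.startswith(("FLAM", "FRAM")):
        return ("SINE", "Alu")
    return _REP_TAXONOMY.get(rep_name, ("SINE", "Alu"))


@dataclass(frozen=True)
class PlantedRepeat:
    """Request for ``count`` repeats of one (name, category, orientation)."""

    rep_name: str
    category: PositionalCategory
    orientation: Orientation
    count: int
    accession_class: str | None = None   # force host gene NM/XM; None = mix


@dataclass(frozen=True)
class PlantedApa:
    """Request for ``count`` APA sites planted in one anatomy region
    (OFF_ELEMENT plants them in the host 3'UTR away from any element)."""

    region: AnatomyRegion
    count: int


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (3, 5)
    utr3_length_range: tuple[int, int] = (900, 1500)
    planted_repeats: tuple[PlantedRepeat, ...] = ()
    planted_apa: tuple[PlantedApa, ...] = ()
    anatomy_cfg: AnatomyConfig = DEFAULT_ANATOMY
    accession_mix: float = 0.7           # fraction of genes given NM_ names
    gene_symbols: tuple[str, ...] | None = None

    def total_planted_repeats(self) -> int:
        return sum(p.count for p in self.planted_repeats)

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 50_000:
            raise ValueError("infeasible spec: need >=1 chromosome of "
                             ">=50 kb")
        if self.exon_count_range[0] < 3:
            raise ValueError("infeasible spec: gene template needs >= 3 "
                             "exons")
        if self.utr3_length_range[0] < 400:
            raise ValueError("infeasible spec: 3'UTR must be >= 400 bp to "
                             "host a planted element")
        if self.total_planted_repeats() > self.n_genes:
            raise ValueError(
                f"infeasible spec: {self.total_planted_repeats()} planted "
                f"repeats but only {self.n_genes} genes (one host gene per "
                "repeat)")
        if not (0.0 <= self.accession_mix <= 1.0):
            raise ValueError("accession_mix must be in [0,1]")
        on_element = [p for p in self.planted_apa
                      if p.region is not AnatomyRegion.OFF_ELEMENT]
        if self.planted_apa:
            targets = [p for p in self.planted_repeats
                       if p.category is PositionalCategory.UTR3_END
                       and p.orientation is Orientation.SENSE]
            if not targets:
                raise ValueError(
                    "infeasible spec: planted APA sites need at least one "
                    "sense-oriented UTR3_END repeat to host them")
        if any(p.region is AnatomyRegion.POLY_A_TAIL for p in on_element) \
                and self.anatomy_cfg.polyA_max_extension < 5:
            raise ValueError("infeasible spec: poly-A tail sites need "
                             "polyA_max_extension >= 5")


@dataclass(frozen=True)
class TruthRepeat:
    repeat_id: int
    rep_name: str
    gene: str
    transcript_id: str
    category: PositionalCategory
    orientation: Orientation


@dataclass(frozen=True)
class TruthApa:
    gene: str
    chrom: str
    pos: int
    region: AnatomyRegion


@dataclass(frozen=True)
class TruthGene:
    gene: str
    transcript_id: str
    utr3_len: int


@dataclass(frozen=True)
class GroundTruth:
    repeats: tuple[TruthRepeat, ...]
    apa: tuple[TruthApa, ...]
    genes: tuple[TruthGene, ...]


# ---------------------------------------------------------------------------
# gene template
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    symbol: str
    accession: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    u5: int
    u3: int

    def to_record(self) -> GenePredRecord:
        n = len(self.exon_starts)
        return GenePredRecord(
            name=self.accession, chrom=self.chrom, strand=self.strand,
            txStart=self.tx_start, txEnd=self.tx_end,
            cdsStart=self.cds_start, cdsEnd=self.cds_end,
            exonCount=n, exonStarts=self.exon_starts,
            exonEnds=self.exon_ends, name2=self.symbol, bin=585,
            score=0, cdsStartStat="cmpl", cdsEndStat="cmpl",
            exonFrames=(-1,) * n)


def _build_gene(rng: random.Random, spec: FixtureSpec, index: int,
                chrom: str, cursor: int, accession_class: str | None) -> _Gene:
    strand = rng.choice("+-")
    k = rng.randint(*spec.exon_count_range)
    u5 = rng.randint(700, 900)
    u3 = rng.randint(*spec.utr3_length_range)
    mids = [rng.randint(650, 750) for _ in range(k - 2)]
    introns = [rng.randint(800, 1500) for _ in range(k - 1)]
    if strand == "+":
        exon_lens = [u5 + 300, *mids, 300 + u3]
    else:
        exon_lens = [u3 + 300, *mids, 300 + u5]

    starts, ends = [], []
    pos = cursor
    for i, length in enumerate(exon_lens):
        starts.append(pos)
        pos += length
        ends.append(pos)
        if i < len(introns):
            pos += introns[i]
    tx_start, tx_end = starts[0], ends[-1]
    if strand == "+":
        cds_start, cds_end = tx_start + u5, tx_end - u3
    else:
        cds_start, cds_end = tx_start + u3, tx_end - u5

    if accession_class is None:
        accession_class = "NM" if rng.random() < spec.accession_mix else "XM"
    accession = f"{accession_class}_{index + 1:06d}"
    if spec.gene_symbols is not None:
        symbol = spec.gene_symbols[index % len(spec.gene_symbols)]
    else:
        symbol = f"GENE{index:03d}"
    return _Gene(symbol, accession, chrom, strand, tx_start, tx_end,
                 cds_start, cds_end, tuple(starts), tuple(ends), u5, u3)


# ---------------------------------------------------------------------------
# repeat placement
# ---------------------------------------------------------------------------

def _place_repeat(rng: random.Random, g: _Gene, category: PositionalCategory,
                  length: int) -> tuple[int, int]:
    """Genomic interval [a, b) guaranteeing ``category`` for a repeat of
    ``length`` bp against gene ``g``, by construction within the template's
    compartments."""
    L = length
    plus = g.strand == "+"
    C = PositionalCategory
    if category is C.UTR3_END:
        o = rng.randint(20, L - 20)
        return (g.tx_end - o, g.tx_end - o + L) if plus \
            else (g.tx_start + o - L, g.tx_start + o)
    if category is C.UTR3_INTERNAL:
        if plus:
            a = rng.randint(g.cds_end + 5, g.tx_end - 5 - L)
        else:
            a = rng.randint(g.tx_start + 5, g.cds_start - 5 - L)
        return (a, a + L)
    if category is C.UTR5_START:
        o = rng.randint(20, L - 20)
        return (g.tx_start + o - L, g.tx_start + o) if plus \
            else (g.tx_end - o, g.tx_end - o + L)
    if category is C.UTR5_INTERNAL:
        if plus:
            a = rng.randint(g.tx_start + 5, g.cds_start - 5 - L)
        else:
            a = rng.randint(g.cds_end + 5, g.tx_end - 5 - L)
        return (a, a + L)
    if category is C.ORF_START:
        o = rng.randint(20, min(L - 20, 290))
        return (g.cds_start + o - L, g.cds_start + o) if plus \
            else (g.cds_end - o, g.cds_end - o + L)
    if category is C.ORF_END:
        o = rng.randint(20, min(L - 20, 290))
        return (g.cds_end - o, g.cds_end - o + L) if plus \
            else (g.cds_start + o - L, g.cds_start + o)
    if category is C.EXON_SPLICING:
        j = g.exon_ends[0]            # first internal junction
        o = rng.randint(20, min(290, L - 10))
        return (j - o, j - o + L)
    if category is C.INSIDE_EXON:
        es, ee = g.exon_starts[1], g.exon_ends[1]   # pure-CDS middle exon
        a = rng.randint(es + 5, ee - 5 - L)
        return (a, a + L)
    if category is C.NO_EXONIC_OVERLAP:
        i_s, i_e = g.exon_ends[0], g.exon_starts[1]  # first intron
        a = rng.randint(i_s + 5, i_e - 5 - L)
        return (a, a + L)
    raise ValueError(f"cannot plant category {category}")


def _make_rmsk(rng: random.Random, rep_id: int, g: _Gene, a: int, b: int,
               rep_name: str, orientation: Orientation,
               consensus_length: int, chrom_length: int) -> RmskRecord:
    strand = g.strand if orientation is Orientation.SENSE else \
        ("-" if g.strand == "+" else "+")
    rep_class, rep_family = _rep_taxonomy(rep_name)
    L = b - a
    cs, ce = 1, L                      # element covers consensus [1, L]
    left = -(consensus_length - ce)
    if strand == "+":
        rep_start, rep_end, rep_left = cs, ce, left
    else:
        rep_start, rep_end, rep_left = left, ce, cs
    return RmskRecord(
        bin=585, swScore=rng.randint(1500, 2600),
        milliDiv=rng.randint(0, 150), milliDel=rng.randint(0, 50),
        milliIns=rng.randint(0, 50), genoName=g.chrom, genoStart=a,
        genoEnd=b, genoLeft=-(chrom_length - b), strand=strand,
        repName=rep_name, repClass=rep_class, repFamily=rep_family,
        repStart=rep_start, repEnd=rep_end, repLeft=rep_left, id=rep_id)


# ---------------------------------------------------------------------------
# APA planting
# ---------------------------------------------------------------------------

def _plant_apa_site(rng: random.Random, g: _Gene, rep: RmskRecord,
                    region: AnatomyRegion, cfg: AnatomyConfig,
                    used: set[int]) -> int:
    plus = g.strand == "+"
    for _ in range(200):
        if region is AnatomyRegion.OFF_ELEMENT:
            if plus:
                pos = rng.randint(g.cds_end + 5, rep.genoStart - 6)
            else:
                pos = rng.randint(rep.genoEnd + 5, g.cds_start - 6)
        elif region is AnatomyRegion.POLY_A_TAIL:
            ext = cfg.polyA_max_extension
            if rep.strand == "+":
                pos = rng.randint(rep.genoEnd, rep.genoEnd + ext - 1)
            else:
                pos = rng.randint(rep.genoStart - ext, rep.genoStart - 1)
        else:
            iv = {AnatomyRegion.LEFT_ARM: cfg.left_arm,
                  AnatomyRegion.A_RICH_LINKER: cfg.a_linker,
                  AnatomyRegion.RIGHT_ARM: cfg.right_arm}[region]
            lo = max(iv[0], rep.consensus_start)
            hi = min(iv[1], rep.consensus_end)
            if lo > hi:
                raise ValueError(
                    f"infeasible spec: element covers consensus "
                    f"[{rep.consensus_start},{rep.consensus_end}], cannot "
                    f"host a {region.value} site")
            pos = consensus_to_genomic(rep, rng.randint(lo, hi))
        if pos not in used:
            used.add(pos)
            return pos
    raise ValueError(f"infeasible spec: cannot place distinct {region.value} "
                     f"APA sites in gene {g.symbol}")


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

_GAP = 3000
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def generate_fixture(spec: FixtureSpec, outdir) -> tuple[dict, GroundTruth]:
    """Write a complete fixture (refGene.txt, rmsk.txt, tapas.tsv,
    genome.fa, truth*.tsv) under ``outdir``.

    All placement decisions come from one ``random.Random(seed)`` stream
    (integer arithmetic only), so identical specs give byte-identical
    files.  Infeasible specs fail before anything is written.  Returns the
    file paths and the planted :class:`GroundTruth`.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    outdir = Path(outdir)

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    cursors = {c: _GAP for c in chrom_names}

    # expand plants; each planted repeat gets its own host gene
    plants: list[PlantedRepeat] = []
    for p in spec.planted_repeats:
        plants.extend(replace(p, count=1) for _ in range(p.count))

    genes: list[_Gene] = []
    repeats: list[RmskRecord] = []
    truth_repeats: list[TruthRepeat] = []
    truth_genes: list[TruthGene] = []
    target_genes: list[tuple[_Gene, RmskRecord]] = []

    for i in range(spec.n_genes):
        chrom = chrom_names[i % spec.n_chromosomes]
        plant = plants[i] if i < len(plants) else None
        g = _build_gene(rng, spec, i, chrom, cursors[chrom],
                        plant.accession_class if plant else None)
        # leave room for terminus-spanning elements and their tail windows
        margin = REPEAT_LEN_RANGE[1] + spec.anatomy_cfg.polyA_max_extension
        if g.tx_end + margin + _GAP > spec.chrom_length:
            raise ValueError(
                f"infeasible spec: gene {i} overflows {chrom} "
                f"({spec.chrom_length} bp)")
        cursors[chrom] = g.tx_end + _GAP
        genes.append(g)
        truth_genes.append(TruthGene(g.symbol, g.accession, g.u3))

        if plant is not None:
            L = rng.randint(*REPEAT_LEN_RANGE)
            a, b = _place_repeat(rng, g, plant.category, L)
            rep = _make_rmsk(rng, len(repeats) + 1, g, a, b, plant.rep_name,
                             plant.orientation,
                             spec.anatomy_cfg.consensus_length,
                             spec.chrom_length)
            repeats.append(rep)
            truth_repeats.append(TruthRepeat(
                rep.id, rep.repName, g.symbol, g.accession,
                plant.category, plant.orientation))
            if plant.category is PositionalCategory.UTR3_END and \
                    plant.orientation is Orientation.SENSE:
                target_genes.append((g, rep))

    # APA sites round-robin across the sense UTR3_END host genes
    truth_apa: list[TruthApa] = []
    sites_by_gene: dict[str, list[tuple[int, AnatomyRegion]]] = {}
    used_by_gene: dict[str, set[int]] = {}
    turn = 0
    for p in spec.planted_apa:
        for _ in range(p.count):
            g, rep = target_genes[turn % len(target_genes)]
            turn += 1
            used = used_by_gene.setdefault(g.symbol, set())
            pos = _plant_apa_site(rng, g, rep, p.region, spec.anatomy_cfg,
                                  used)
            sites_by_gene.setdefault(g.symbol, []).append((pos, p.region))
            truth_apa.append(TruthApa(g.symbol, g.chrom, pos, p.region))

    apa_records: list[ApaRecord] = []
    for g in genes:
        if g.symbol not in sites_by_gene:
            continue
        planted = sorted(sites_by_gene[g.symbol])
        abundances = tuple(round(rng.uniform(0.5, 50.0), 2) for _ in planted)
        apa_records.append(ApaRecord(
            gene=g.symbol, chrom=g.chrom, strand=g.strand,
            apa_sites=tuple(pos for pos, _ in planted),
            abundances=abundances, read_count=rng.randint(100, 10_000)))

    # genome sequence with PAS/CA motifs planted at each cleavage site
    np_rng = np.random.default_rng(spec.seed)
    chrom_seqs: dict[str, bytearray] = {}
    for c in chrom_names:
        idx = np_rng.integers(0, 4, size=spec.chrom_length, dtype=np.uint8)
        chrom_seqs[c] = bytearray(_BASES[idx].tobytes())
    for t in truth_apa:
        g = next(gg for gg in genes if gg.symbol == t.gene)
        _plant_cleavage_motifs(chrom_seqs[t.chrom], t.pos, g.strand)

    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "refgene": outdir / "refGene.txt",
        "refflat": outdir / "refFlat.txt",
        "rmsk": outdir / "rmsk.txt",
        "tapas": outdir / "tapas.tsv",
        "fasta": outdir / "genome.fa",
        "truth_repeats": outdir / "truth.tsv",
        "truth_apa": outdir / "truth_apa.tsv",
        "truth_genes": outdir / "truth_utr3.tsv",
    }
    gp_records = [g.to_record() for g in genes]
    write_genepred(gp_records, files["refgene"], layout="refgene")
    write_genepred(gp_records, files["refflat"], layout="refflat")
    write_rmsk(repeats, files["rmsk"])
    write_tapas(apa_records, files["tapas"])
    seq_records = [SeqRecord(Seq(bytes(chrom_seqs[c]).decode()), id=c,
                             description="") for c in chrom_names]
    SeqIO.write(seq_records, files["fasta"], "fasta")

    with open(files["truth_repeats"], "w") as fh:
        fh.write("repeat_id\trep_name\tgene\ttranscript_id\tcategory\t"
                 "orientation\n")
        for t in truth_repeats:
            fh.write(f"{t.repeat_id}\t{t.rep_name}\t{t.gene}\t"
                     f"{t.transcript_id}\t{t.category.value}\t"
                     f"{t.orientation.value}\n")
    with open(files["truth_apa"], "w") as fh:
        fh.write("gene\tchrom\tpos\tregion\n")
        for t in truth_apa:
            fh.write(f"{t.gene}\t{t.chrom}\t{t.pos}\t{t.region.value}\n")
    with open(files["truth_genes"], "w") as fh:
        fh.write("gene\ttranscript_id\tutr3_len\n")
        for t in truth_genes:
            fh.write(f"{t.gene}\t{t.transcript_id}\t{t.utr3_len}\n")

    truth = GroundTruth(tuple(truth_repeats), tuple(truth_apa),
                        tuple(truth_genes))
    return files, truth


def _plant_cleavage_motifs(seq: bytearray, pos: int, strand: str,
                           pas_offset: int = 21) -> None:
    """Write AATAAA ``pas_offset`` bp upstream and CA immediately 5' of the
    cleavage point at genomic ``pos``, in the transcript's sense.

    Plants are applied in site order; when two sites fall within the same
    60 bp window the later plant overwrites part of the earlier one, so
    motif recovery is only guaranteed for sites with no neighbour closer
    than the window (dense poly-A-tail clusters trade this off on purpose).
    """
    win = 60
    lo = pos - win
    sense = bytes(seq[lo:pos + win]).decode()
    if strand == "-":
        sense = "".join(_COMP[b] for b in reversed(sense))
    cut = win  # cleavage falls between sense[cut-1] and sense[cut]
    sense = (sense[:cut - pas_offset] + "AATAAA"
             + sense[cut - pas_offset + 6:cut - 2] + "CA" + sense[cut:])
    if strand == "-":
        sense = "".join(_COMP[b] for b in reversed(sense))
    seq[lo:pos + win] = sense.encode()


def fig7_preset(seed: int) -> FixtureSpec:
    """Fixture emulating the planted APA composition used in acceptance:
    four genes carrying one sense-oriented UTR3_END AluYRa1 each, with 100
    polyadenylation sites planted 40/34/26 across the poly-A tail, the
    A-rich linker, and off-element 3'UTR positions."""
    return FixtureSpec(
        seed=seed,
        n_chromosomes=2,
        chrom_length=150_000,
        n_genes=4,
        planted_repeats=(
            PlantedRepeat("AluYRa1", PositionalCategory.UTR3_END,
                          Orientation.SENSE, 4, accession_class="NM"),),
        planted_apa=(
            PlantedApa(AnatomyRegion.POLY_A_TAIL, 40),
            PlantedApa(AnatomyRegion.A_RICH_LINKER, 34),
            PlantedApa(AnatomyRegion.OFF_ELEMENT, 26)),
        gene_symbols=("TK2", "GTPBP4", "PEX26", "IRF9"),
    )


# ---------------------------------------------------------------------------
# per-base brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_classify(rep: RmskRecord, model: TranscriptModel,
                         proximity_bp: int = 0) -> PositionalCategory:
    """Independent per-base re-derivation of the primary positional
    category.

    Labels every transcribed base explicitly, enumerates the coordinates the
    repeat covers as sets, and derives the category from set membership with
    the same precedence table as the locator — but without sharing any of
    its interval logic.  Terminal tests against the exclusive ``txEnd``
    coordinate use the closed coordinate range, mirroring the documented
    boundary semantics.
    """
    rec = model.record
    s = rec.strand
    label: dict[int, str] = {}
    for es, ee in rec.exon_blocks():
        for p in range(es, ee):
            if not rec.coding:
                label[p] = "exon"
            elif rec.cdsStart <= p < rec.cdsEnd:
                label[p] = "cds"
            elif p < rec.cdsStart:
                label[p] = "utr5" if s == "+" else "utr3"
            else:
                label[p] = "utr3" if s == "+" else "utr5"

    a, b = rep.genoStart, rep.genoEnd
    P = proximity_bp
    covered = set(range(a, b))
    exonic = covered & set(label)
    C = PositionalCategory
    cats: set[C] = set()

    end_coord = rec.txEnd if s == "+" else rec.txStart
    end_base = rec.txEnd - 1 if s == "+" else rec.txStart
    end_reach = set(range(a - P, b + P + (1 if s == "+" else 0)))
    if end_coord in end_reach and label.get(end_base) == "utr3":
        cats.add(C.UTR3_END)

    start_coord = rec.txStart if s == "+" else rec.txEnd
    start_base = rec.txStart if s == "+" else rec.txEnd - 1
    start_reach = set(range(a - P, b + P + (1 if s == "-" else 0)))
    if start_coord in start_reach and label.get(start_base) == "utr5":
        cats.add(C.UTR5_START)

    if rec.coding:
        orf_start_base = rec.cdsStart if s == "+" else rec.cdsEnd - 1
        orf_end_base = rec.cdsEnd - 1 if s == "+" else rec.cdsStart
        if orf_start_base in covered:
            cats.add(C.ORF_START)
        if orf_end_base in covered:
            cats.add(C.ORF_END)

    junctions = set(rec.exonStarts[1:]) | set(rec.exonEnds[:-1])
    if covered & junctions:
        cats.add(C.EXON_SPLICING)

    if exonic and not cats:
        utr3 = {p for p, l in label.items() if l == "utr3"}
        utr5 = {p for p, l in label.items() if l == "utr5"}
        if covered <= utr3:
            cats.add(C.UTR3_INTERNAL)
        elif covered <= utr5:
            cats.add(C.UTR5_INTERNAL)
        if covered <= set(label):
            cats.add(C.INSIDE_EXON)

    if not cats:
        return C.NO_EXONIC_OVERLAP
    return min(cats, key=_RANK.__getitem__)


# ---------------------------------------------------------------------------
# randomized small instances for equivalence testing
# ---------------------------------------------------------------------------

def random_instance(rng: random.Random
                    ) -> tuple[RmskRecord, TranscriptModel]:
    """One random small repeat x transcript configuration: 1-5 exons,
    either strand, coding or noncoding, repeat placed anywhere around the
    transcript (including purely intronic and fully outside)."""
    k = rng.randint(1, 5)
    pos = rng.randint(100, 300)
    starts, ends = [], []
    for _ in range(k):
        starts.append(pos)
        pos += rng.randint(5, 60)
        ends.append(pos)
        pos += rng.randint(5, 40)
    tx_start, tx_end = starts[0], ends[-1]

    exonic = [p for s, e in zip(starts, ends) for p in range(s, e)]
    if rng.random() < 0.8 and len(exonic) >= 2:
        i, j = sorted(rng.sample(range(len(exonic)), 2))
        cds_start, cds_end = exonic[i], exonic[j] + 1
    else:
        cds_start = cds_end = tx_end
    strand = rng.choice("+-")
    rec = GenePredRecord(
        name=f"NM_{rng.randint(1, 999):06d}", chrom="chrT", strand=strand,
        txStart=tx_start, txEnd=tx_end, cdsStart=cds_start, cdsEnd=cds_end,
        exonCount=k, exonStarts=tuple(starts), exonEnds=tuple(ends),
        name2="TOY")
    model = build_model(rec)

    length = rng.randint(5, 150)
    a = rng.randint(tx_start - 170, tx_end + 20)
    b = a + length
    conslen = length + rng.randint(0, 30)
    if rng.random() < 0.5:
        rep_strand = "+"
        rs, re_, rl = 1, length, -(conslen - length)
    else:
        rep_strand = "-"
        rs, re_, rl = -(conslen - length), length, 1
    rep = RmskRecord(
        bin=0, swScore=1000, milliDiv=10, milliDel=0, milliIns=0,
        genoName="chrT", genoStart=a, genoEnd=b, genoLeft=-1000,
        strand=rep_strand, repName="AluYRa1", repClass="SINE",
        repFamily="Alu", repStart=rs, repEnd=re_, repLeft=rl,
        id=rng.randint(1, 10_000))
    return rep, model
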