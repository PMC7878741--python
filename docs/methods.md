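# Methods

## Problem and model

Alu elements are ~300 bp primate SINE retrotransposons: two 7SL-derived
monomers (left arm, right arm) joined by an A-rich linker and ending in a
poly-A tail. Inserted in the *sense* orientation inside a gene's 3′UTR, an
Alu carries its own polyadenylation-competent sequence — an A-rich tract
and potential PAS hexamers — and can therefore terminate the host
transcript early, shortening the 3′UTR and creating alternative
polyadenylation (APA) isoforms. Inserted antisense, the same element
instead supplies cryptic splice sites (the classic exonization signature).
The package quantifies this asymmetry for annotated genomes: where every
repeat copy sits relative to transcript structure, in which orientation,
which part of the element's consensus anatomy coincides with the
transcript's 3′ terminus, and what fraction of detected polyadenylation
sites fall on target elements.

All computation runs off three standard inputs: a UCSC genePred gene table
(refGene/refFlat dialects), the UCSC RepeatMasker (rmsk) table, and the
six-column per-gene polyadenylation output of the TAPAS tool (gene, chrom,
strand, site list, abundance list, read count). Coordinates are kept
0-based half-open internally, matching the tables.

## Positional taxonomy and boundary semantics

Every repeat × transcript pair with exonic overlap (or abutting a
transcript terminus) receives the set of categories it satisfies and one
primary category by precedence:

    UTR3_END > UTR5_START > ORF_END > ORF_START > EXON_SPLICING
    > UTR3_INTERNAL > UTR5_INTERNAL > INSIDE_EXON

with `NO_EXONIC_OVERLAP` as the fallback. Terminal events outrank boundary
events, which outrank containment, because transcript termination is the
phenomenon under study.

Boundary semantics needed one genuine design decision. UCSC interval ends
are exclusive, so "the transcript 3′ end" of a `+` transcript is the
coordinate `txEnd`, which no half-open repeat interval `[a, b)` with
`b == txEnd` contains. We test any terminal that is an *exclusive*
coordinate (`txEnd`: the 3′ end of a `+` transcript and the 5′ start of a
`-` transcript) with the closed form `a <= p <= b`, so an element ending
exactly at — or beginning exactly at — the terminus counts as touching it.
Terminals that are inclusive coordinates (`txStart`) keep the half-open
test. ORF boundaries and splice junctions are tested as inclusive boundary
*bases* (first/last coding base, junction coordinate) against `[a, b)`.
A consequence we accept: an element abutting the `+` terminus from outside
has zero exonic overlap yet is called `UTR3_END`; and a repeat crossing the
terminus of a *noncoding* transcript (which has no UTR blocks by
definition) falls through to `NO_EXONIC_OVERLAP` despite overlapping
exonic sequence. Both corners are exercised by tests and reproduced
identically by the independent per-base oracle.

`proximity_bp` (default 0) widens the terminal tests symmetrically. The
strict default means an element stopping tens of bases short of the
terminus is `UTR3_INTERNAL`, not `UTR3_END`; a nonzero window is opt-in.

Orientation is `SENSE` iff the repeat's annotated strand equals the
transcript's. Calls are per transcript; the gene inventory deduplicates by
gene symbol and records whether support comes from registered (NM_) or
predicted (XM_) accessions.

## Consensus mapping and Alu anatomy

The rmsk columns `repStart/repEnd/repLeft` encode the element's slice of
its subfamily consensus with a strand-dependent sign convention (on `-`
the start/left roles swap). The reader normalises this into
`(consensus_start, consensus_end, consensus_left)` at parse time; no
downstream code branches on the sign trick. Genomic→consensus mapping is
linear within the element (`+`: `cs + (pos − genoStart)`; `-`:
`ce − (pos − genoStart)`) and is a bijection over the element span — an
exact property for synthetic elements, an approximation for real copies
with indels relative to consensus (a known limitation).

Anatomy regions are pure configuration: left arm `[1, 131]`, A-rich linker
`[132, 158]`, right arm `[159, 311]` over a 311 bp consensus, with a 30 bp
poly-A tail extension window past the element's 3′ end. These defaults
follow the canonical AluY dimeric layout and are implementation defaults,
not measured subfamily coordinates; every analysis that depends on exact
boundaries should pass its own `AnatomyConfig`, and the test suite
constructs its own. The poly-A tail is defined positionally (beyond the
consensus end, within the extension window) because RepeatMasker does not
annotate tails; `polya_composition_ok` offers an optional ≥80%-A check
when sequence is available.

The motif scanner reports whether the dinucleotide immediately 5′ of a
cleavage offset is CA and all occurrences of configured PAS hexamers
(default `AATAAA`, `ATTAAA`) lying entirely within an upstream window
(default 40 bp).

## APA joining and summary statistics

Each gene's TAPAS sites are tested against target-name elements
overlapping the gene's representative isoform (registered accessions
preferred, longest spliced 3′UTR, accession string as tie-break). A site
is on-element when it falls in the element's genomic span plus the tail
window on the element's 3′ side; with `sense_only` (default) only elements
matching the transcript strand qualify. Genes whose TAPAS strand
contradicts the annotation, or whose isoform has no 3′UTR, are excluded
and logged; genes absent from the annotation are reported unjoined —
mirroring how real cohort runs silently lose genes to annotation gaps.

Percentages are site-weighted by default (abundance weighting is an
option) and are fractions of *all* joined sites, so the poly-A-tail and
A-rich percentages are sub-fractions of the on-element percentage.
Headline figures are rounded half-up to integers; TSV output keeps one
decimal.

## Synthetic fixtures and what they do (not) show

The generator writes complete refGene/refFlat/rmsk/TAPAS/FASTA file sets
from a single seeded `random.Random` stream (integer coordinate arithmetic
only), so identical seeds give byte-identical files. Genes follow a fixed
template — UTRs confined to the terminal exons (5′UTR 700–900 bp, 3′UTR
900–1500 bp by default), 300 bp CDS flanks, ~700 bp middle exons, 0.8–1.5 kb
introns, 3 kb intergenic gaps, defaults of 20 genes on 2 × 1 Mb
chromosomes — sized so a 280–310 bp element fits strictly inside any one
compartment. Each planted repeat gets its own host gene and is placed by
construction to satisfy exactly its requested category and orientation;
infeasible requests fail before any file is written. Planted APA sites are
placed at chosen consensus offsets of the sense 3′UTR-end elements (or
off-element in the host 3′UTR), and the FASTA gets an `AATAAA` 21 bp
upstream plus `CA` immediately 5′ of each cleavage point, in transcript
sense; when two sites fall within the same 60 bp window the later plant
partially overwrites the earlier one, so motif recovery is guaranteed only
for isolated sites.

The `fig7` preset plants 100 sites across four NM-registered genes, each
carrying one sense-oriented `UTR3_END` AluYRa1: 40 in the tail window, 34
in the A-rich linker, 26 off-element, yielding 74% / 40% / 34% by
construction. This validates the *bookkeeping* — joining, orientation
gating, anatomy mapping, weighting, rounding — not the biology: passing
says nothing about real genomes, where category frequencies depend on
annotation versions, elements diverge from consensus, isoforms overlap,
and repeat boundaries are fuzzy. The generator also omits repeat copies
outside genes, nested/fragmented elements, and multi-gene loci.

The per-base brute-force classifier labels every transcribed base
explicitly and re-derives the category from coordinate-set membership,
sharing no interval code with the locator; classifier↔oracle agreement is
checked on ≥1000 randomized instances per run (1–5 exons, both strands,
coding and noncoding, arbitrary repeat placement) and the randomized
generator is itself tested to reach all nine categories.

## Numerical and degenerate-input choices

* "Similar" cross-species 3′UTR length: relative spread ≤ 10%
  (configurable); 3′UTR length is the *spliced* length (sum of exonic
  3′UTR bases), not the genomic span — the alternative convention is noted
  here because published per-gene lengths rarely state which they use.
* Ties in isoform selection break on accession string; output ordering is
  always an explicit sort (chrom, start, end, accession), making runs
  byte-reproducible.
* rmsk rows violating the consensus sign convention are flagged and kept
  (real tables contain such rows); malformed genePred/TAPAS rows raise
  errors naming file, line and field.
* Empty inputs: zero repeats → zero calls; a gene with zero TAPAS sites is
  a valid record; summarising zero joined sites is an error rather than a
  0/0.
* Count tables are dense (zero rows for empty cells of the requested
  grouping) so bar-chart-style comparisons can be read off directly.

## Known limitations

* Consensus mapping ignores alignment indels; real elements map
  approximately.
* One repeat overlapping both a junction and a terminus is counted once
  under its primary category; `all_categories` is exposed for the
  alternative tally.
* Cross-species comparison joins on user-supplied shared gene symbols; no
  orthology inference.
* TAPAS is consumed as a format only; its detection algorithm, read
  alignment, and any wet-lab validation are out of scope.
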