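# Methods

This note records the model behind `ntmap`, the parameter choices, the
numerical details of the aligner and composer, what the synthetic fixtures
do and do not emulate, and the design decisions taken where more than one
reasonable implementation existed.

## Mapping model

An insertion of a natural transposon (NT) into a genome duplicates a short
target site motif (TSD): if the pre-insertion locus reads `L·M·R` with motif
`M` (8 bp for P-element and hobo), the post-insertion locus reads
`L·M·NT·M·R`. A junction query (JQ) — a terminal segment of the NT plus
genomic flank taken from the strain under study — therefore aligns against
the canonical reference as a split alignment: a genome-origin ("blue") part
ending at the insertion site and a transposon-origin ("red") part covering
the NT terminus. The first genome-derived nucleotide adjacent to the NT on
the query is the TGN, reported 1-based; the 5′-side junction of a plus
(orientation 1) insertion lands on the high-coordinate end of `M` and the
3′-side junction on its low end, so the two sides of one insertion bracket
the TSD and must recover the same motif. Orientation is defined by the
strand of the genomic part of the alignment (1 = plus, 2 = minus), which
also means reverse-complementing a junction query flips the reported
orientation while leaving the TGN unchanged.

Internally all coordinates are 0-based half-open; every reported coordinate
is 1-based. The one deliberate exception is the transposon-annotation TSV,
whose coordinates are 0-based by convention (the line describing the first
nucleotide starts at zero); GFF3 input is converted from its native 1-based
inclusive form.

## Aligner

Queries are seeded with exact k-mers (k = "nucleus size"). The index stores
plus-strand postings only; minus-strand hits come from looking up the
reverse-complemented query, which halves the memory with an identical
contract. Seeds whose diagonals differ by ≤ 16 (and that are within 500
positions of each other) merge into one chain; each chain is extended with a
banded local affine-gap DP (Gotoh) over the chain's diagonal range plus a
pad. The pad is 64 diagonals for the "short" extension mode and 512 for
"long" (capped at half the query length), so the explored reference span is
the query length plus the band width — roughly twice the query length for
"short", which is the intended budget of that mode. The band is also a
semantic choice, not only a performance one: a deletion wider than the band
cannot be bridged inside one subalignment, so distant fragments surface as
separate partial results and their reconciliation is owned entirely by the
composition rules below.

Scoring is match +1, mismatch −1, gap open −2, gap extend −1 (a gap of
length L costs −2 − (L−1)); a perfect 60-nt query scores 60, the scale on
which the recommended reporting threshold of 40 is expressed. N matches
nothing, including another N. The row recurrence computes the
reference-consuming gap state with a prefix-max scan, which is exact because
gap open ≤ gap extend makes re-opening inside a gap never profitable.
Traceback uses stored per-cell choice pointers plus the open/extend
equalities on the stored score matrix; ties prefer the diagonal, then the
vertical gap, for determinism. Every subalignment carries a cigar
(M/X/I/D run-lengths) from which its score is exactly recomputable — a
property the test suite asserts. Equal-scoring extensions are ordered by
(reference id, reference start) and near-duplicate extensions of the same
locus (≥ 80% overlap on both query and reference) are collapsed to the best
one.

The full-matrix Smith–Waterman–Gotoh used to validate the aligner lives in
the test suite, shares no code with the production path, and is run on
random ≤ 2 kb instances with substitutions and small indels (net diagonal
drift well inside the band, so the banded optimum equals the global one).

## Composer

All rule-respecting chains of subalignments are enumerated (the subalignment
count per query is small; above 16 parts only the 16 best-scoring are
considered). Genome–genome neighbours require same reference, same strand,
query order consistent with reference order, and a reference gap in
[0, `max_genomic_gap`] (default 200 nt) — so a query spanning a deletion of
201+ nt produces two separate finals. Pairs involving a transposon part
compose without restrictions, including overlapping transposon coordinates
(self-insertions, internally deleted remnants). Output is ranked by total
score with deterministic tie-breaks (fewer parts, reference id, leftmost
start) and truncated to `number_of_results`.

Two practical complications are handled explicitly:

* **Breakpoint overlaps.** The first transposon base can equal the next
  genomic base by chance, letting the blue extension creep a few bases (or,
  via a gap plus stray matches, a few columns) past the true junction — the
  locally optimal alignment is then slightly *wrong* at the breakpoint.
  When two parts overlap on the query (up to 60 bases), the composer trims
  the genome part back to the transposon edge (TIR ends are the anchored
  coordinates; for same-origin pairs the lower-scoring part yields), then
  re-anchors the trimmed end: the boundary-side stub is optionally shaved
  back to a ≥ 8-column match anchor and re-extended toward the boundary with
  exact matches only, keeping whichever candidate scores higher. This is
  what makes TGN recovery exact on clean data while degrading gracefully on
  noisy data.
* **Covered-span suppression.** If an all-genomic composite covers a mixed
  composite's query span at equal or better (pre-bonus) score, the mixed one
  is dropped. An insertion shared between the strain and the reference
  genome therefore reports as a completely blue result with no TGN, and only
  strain-private insertions yield junction calls.

The +500 insertion-candidate bonus applies once per junction composite when
the transposon part abuts the genomic part on the query (gap ≤ 5) and covers
an annotated TIR at the junction end with ≥ 90% of its length at ≥ 90%
identity ("almost intact"; both thresholds are module constants). The bonus
is restricted to mixed composites; it exists to rank candidates, so it is
applied after suppression and cannot resurrect a suppressed junction.

Placement picking: within one reference sequence, at most `picking_depth`
(default 1) equal-scoring placements of the same query span are reported,
even if identical subsequences occur elsewhere in that reference. The limit
is deliberately per reference — equal hits on *different* contigs are all
reported, which is what makes contig scanning with depth 1 useful, while a
tandem duplication inside one contig needs a higher depth to surface both
copies.

## Workflows

WF1 (scan) aligns the NT's terminal 60-nt crops against the contig set,
keeps hits with score ≥ `min_report_score` (default 40) whose TIR region is
≥ 90% covered at ≥ 90% identity (the automated version of visually checking
for a complete TIR), and extracts JQs: upstream flank + Q5′ region, and Q3′
region + downstream flank, 3000 nt of flank by default (≈ 3060-nt JQs).
Minus-strand windows are reverse-complemented before flank collection so
every JQ reads flank→TIR5 or TIR3→flank regardless of insertion orientation.
A 5′-only remnant additionally gets a joined 3′ query of crop + one NT
length + 2000 nt (mirrored for 3′-only remnants); a flank truncated by a
contig end is emitted with an ALERT flag in the header rather than dropped.
WF2 (map) runs each JQ through align → compose → suppress → bonus → pick →
truncate and converts the best composite into a result row; junction rows
carry TGN, orientation, TSD and gene context. Preset parameters: WF1 short
extension, depth 1, nucleus 20, 1000 results, bonus off; WF2 short
extension, depth 1, nucleus 30, 2 results, bonus on.

## Consensus

The IUPAC consensus takes ≥ 2 equal-length sequences; per position, every
base whose frequency among informative (non-N) sequences is ≥ the threshold
(default 20%, inclusive comparison done on integers to avoid float-boundary
artifacts) enters the symbol set, which maps to the IUPAC code. At a 100%
threshold a non-invariant column is an error (only identical columns admit a
consensus); below that, a column where no base reaches the threshold prints
N with a warning. Monotonicity — raising the threshold never widens any
position's qualifying set — holds on the sets themselves and is exposed via
`ConsensusResult.position_sets`; it cannot be read off the printed string
because the fallback N is typographically identical to the genuine 4-fold
symbol.

## Synthetic fixtures

The simulator emulates the comparative design the workflows target: a random
genome (default GC 0.42, fly-like), a class II NT built as TIR + random body
+ inverted TIR, and insertions planted as `genome[:c] + NT + M + genome[c:]`
with `M` copied from the genomic site (so 5′/3′ TSD concordance is a real
signal, not an artifact), in both orientations, optionally truncated to a
single-TIR remnant (60% of the element retained) or nested inside a
previously planted element. "Shared" insertions are planted into the CRG as
well. Fixture scale for the recovery suite: one 50–200 kb chromosome per
fixture, 2 kb elements, TSDs of 4–10 bp; the multi-contig case study uses a
60 kb backbone with private, shared, single-TIR and nested events. These
sizes keep the full suite at desk scale while leaving every algorithmic
branch exercised. Everything is byte-reproducible from (parameters, seed).

What the fixtures do **not** emulate: sequencing error inside the JQ (the
tool maps contigs, not raw reads), genome-wide repeat families beyond the
planted elements, assembly artifacts, and heterozygosity. Passing tests
therefore demonstrate the correctness of the mapping machinery on clean
junctions, not robustness to noisy assemblies — on real data the
"approximate" TSD agreement check and the ALERT/manual-curation paths carry
that weight.

## Known limitations

* The aligner is exact only within its band; a true optimum drifting more
  than the pad (64 diagonals in short mode) off the seed chain is missed by
  construction. This is intended behaviour (see composer), but it means the
  tool is not a general-purpose aligner for arbitrarily divergent sequences.
* Chain enumeration in the composer is exponential in the number of parts
  and is capped at the 16 best subalignments; pathological queries hitting
  hundreds of loci are resolved per locus instead.
* One transposon species is processed per workflow run; ranking across
  multiple species in one TD uses plain score only.
* Whether the bonus should ever fire on red–red (self-insertion) composites
  is undocumented in the original tool; here it is restricted to junctions.
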