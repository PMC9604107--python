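# ntmap

Mapping and annotation of natural transposon (NT) insertions in contigs,
long reads and assembled genomes.

## The problem

Transposable elements reshape genomes, disrupt genes and create strain-level
polymorphism. When a new genome assembly (an *alternative reference genome*,
ARG) is compared against the canonical reference of the species (*CRG*), the
question is: where exactly does each copy of a transposon of interest sit,
which insertions are private to the new strain, and which are shared with the
reference? `ntmap` answers this at single-nucleotide resolution for
individually chosen elements — class II DNA transposons with terminal
inverted repeats (TIRs) as well as LTR retrotransposons — and reports each
insertion with its gene context and target site duplication. It is aimed at
genome annotators and transposon biologists working with one or a few
elements of interest, not at genome-wide repeat quantification.

## How it works

The central object is the **junction query (JQ)**: a transposon terminal
segment plus genomic flank, read out of an ARG contig around a detected
remnant. Mapping JQs against the CRG plus the transposon reference produces
split ("blue–red") alignments whose breakpoint is the insertion site.

1. **Seed and extend.** Queries are aligned against two reference
   collections — the genome database (GD) and the transposon database (TD) —
   by exact *k*-mer seeding (*k* = the *nucleus size*, default 20–30,
   minimum effective value 10) followed by banded local affine-gap extension
   (match +1, mismatch −1, gap open −2, gap extend −1; a perfect 60-nt query
   scores 60).
2. **Compose.** Partial alignments are assembled into final results. Two
   genome-origin parts merge only on the same reference and strand, in
   consistent order, with reference gap ≥ 0 and ≤ 200 nt (configurable); a
   deletion larger than that yields two separate results. Pairs involving a
   transposon-origin part compose without restriction, which is what detects
   insertions, self-insertions and internally deleted remnants.
3. **Call.** For the best junction result, the **TGN** (terminal genomic
   nucleotide — the first genome-derived base adjacent to the transposon at
   the junction) is the reported 1-based insertion coordinate; orientation 1
   or 2 follows the strand of the genomic part; the **TSD** (target site
   duplication, default 8 bp) is read off the genomic side of the junction.
   With the *bonus* option on, a junction whose transposon part carries an
   almost intact annotated TIR at the border gains +500 score, lifting
   insertion candidates above concurrent purely genomic alignments. An
   insertion present in the CRG as well maps as a completely "blue"
   alignment instead, and no junction is reported for it.
4. **Annotate.** Calls are associated with the hit gene (joined labels for
   overlapping genes), the nearest up/downstream genes, and any annotated
   transposons containing the TGN (nested-insertion landscape).

Two workflow presets mirror recommended practice: **WF1** scans ARG contigs
with the 60-nt terminal crops of the element (Q5′/Q3′, containing the TIRs)
and extracts JQs of crop + 3000 nt flank; a remnant that lost one TIR gets a
joined query of crop + one element length + 2000 nt so the missing junction
can still be crossed. **WF2** maps those JQs against CRG + TD with the bonus
enabled and two results per query.

The package also ships the surrounding utilities: flank extraction at
arbitrary coordinates, TSD list export, IUPAC ambiguity-code consensus of
TSD/flank sets (a base enters a position's symbol when it occurs in ≥ 20% of
the sequences, configurable), FASTA→RAW conversion, a transposon annotator
(zero-based coordinate convention), and a synthetic-fixture simulator that
plants insertions with known TGN/TSD truth for testing.

## Worked example

```python
from ntmap import ReferenceDB, Parameters, make_fixture, wf1_scan, wf2_map

fx = make_fixture(seed=3, genome_length=60_000, orientation=1)
nt = fx.transposons[0]                        # 2 kb element, 31-nt TIRs
arg = ReferenceDB(fx.contigs, role="genome")  # assembly contigs
scan = wf1_scan(nt, arg, tir5_len=31, tir3_len=31, params=Parameters.wf1())
print(f"{len(scan.hits)} terminal hits, {len(scan.junction_queries)} junction queries")

gd = ReferenceDB(fx.crg, role="genome")       # canonical reference
td = ReferenceDB(fx.transposons, role="transposon")
result = wf2_map([j.to_record() for j in scan.junction_queries], gd, td,
                 Parameters.wf2(), {nt.id: fx.tir_features})
for row in result.rows:
    print(row.query_id, row.classification, row.tgn_coordinate,
          row.orientation, row.tsd, row.score)
print("planted:", fx.truth[0].insertion_coordinate, fx.truth[0].tsd)
```

prints

```
2 terminal hits, 2 junction queries
contig_3_JQ5 junction 13972 1 AAAATCAA 3560
contig_3_JQ3 junction 13965 1 AAAATCAA 3560
planted: 13972 AAAATCAA
```

Both junction queries map as blue–red results: the 5′ junction reports the
TGN at 13972 (the last genomic base before the element, i.e. the high end of
the duplicated motif) and the 3′ junction at 13965 (the motif's low end —
the two coordinates straddle the 8-bp TSD `AAAATCAA`, which both sides
recover identically). The score 3560 is the 3060-nt junction query aligned
end-to-end (3060) plus the +500 insertion-candidate bonus for the intact
31-nt TIR at the border.

The same pipeline is available from the shell via the `ntmap` console
command (`simulate`, `scan`, `map`, `flank`, `tsd`, `consensus`, `convert`,
`annotate-te`).

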