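"""Reference databases and the exact k-mer seed index.

Two reference collections are used throughout: the genome database (GD) and
the transposon database (TD).  Any query is aligned against both; the same
sequence may legitimately live in either or both of them.  The seed index is
a plus-strand exact k-mer table; minus-strand matches are found by looking up
the reverse complement of the query, which keeps the index half the size with
an identical contract.

The seed length k is the "nucleus size" of the alignment heuristic: larger
values make scanning faster and drop marginal partial alignments; 10 is the
minimal effective value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional

from .dna import revcomp
from .errors import DuplicateIdError, KmerError, QueryTooShortError
from .io import SequenceRecord

log = logging.getLogger(__name__)

MIN_EFFECTIVE_NUCLEUS = 10


@dataclass
class Parameters:
    """Runtime parameters of the mapping pipeline.

    nucleus_size        seed (k-mer) length of the alignment heuristic
    picking_depth       number of equal-scoring placements reported per
                        reference sequence (1 = first placement only)
    number_of_results   length of the final ranked result list
    interval_extension  "short" or "long" seed-extension window
    bonus               add +500 to a junction alignment whose transposon part
                        carries an almost intact TIR at the border
    max_genomic_gap     largest reference gap (nt) bridged when merging two
                        genome-origin subalignments into one final alignment
    tsd_flank_length    length of the TSD / flanking sequence exports
    consensus_threshold per-position inclusion threshold (%) for IUPAC consensus
    min_report_score    minimum subalignment score kept when scanning contigs
    """

    nucleus_size: int = 20
    picking_depth: int = 1
    number_of_results: int = 1000
    interval_extension: str = "short"
    bonus: bool = False
    max_genomic_gap: int = 200
    tsd_flank_length: int = 8
    consensus_threshold: float = 20.0
    min_report_score: int = 40

    def __post_init__(self):
        if self.nucleus_size < 4:
            raise ValueError("nucleus_size must be >= 4")
        if self.picking_depth < 1:
            raise ValueError("picking_depth must be >= 1")
        for name in ("number_of_results", "max_genomic_gap", "tsd_flank_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.interval_extension not in ("short", "long"):
            raise ValueError("interval_extension must be 'short' or 'long'")
        if not 0 < self.consensus_threshold <= 100:
            raise ValueError("consensus_threshold is a percentage in (0, 100]")
        if self.nucleus_size < MIN_EFFECTIVE_NUCLEUS:
            log.warning(
                "nucleus_size %d below the minimal effective value %d",
                self.nucleus_size, MIN_EFFECTIVE_NUCLEUS,
            )

    @classmethod
    def wf1(cls, **overrides) -> "Parameters":
        """Contig-scanning preset: short extension, depth 1, nucleus 20,
        1000 results, no bonus."""
        base = dict(interval_extension="short", picking_depth=1, nucleus_size=20,
                    number_of_results=1000, bonus=False)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def wf2(cls, **overrides) -> "Parameters":
        """Insertion-mapping preset: short extension, depth 1, nucleus 30,
        2 results, bonus on."""
        base = dict(interval_extension="short", picking_depth=1, nucleus_size=30,
                    number_of_results=2, bonus=True)
        base.update(overrides)
        return cls(**base)

    def with_overrides(self, **kw) -> "Parameters":
        return replace(self, **kw)


class SeedHit(NamedTuple):
    """One exact k-mer match between an oriented query and a reference.

    ``query_offset`` is an offset into the query as looked up: for minus-strand
    hits that is the reverse complement of the original query.
    """

    reference_id: str
    query_offset: int
    reference_offset: int
    strand: str  # '+' or '-'


class SeedIndex:
    """Exact k-mer postings over the plus strand of a reference collection."""

    def __init__(self, k: int, postings: dict[str, list[tuple[str, int]]]):
        self.k = k
        self.postings = postings

    def n_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())


class ReferenceDB:
    """An ordered collection of named reference sequences with a role.

    role is "genome" (GD) or "transposon" (TD); subalignments inherit it as
    their origin (the blue/red colour of the original tool).
    """

    def __init__(self, records: Iterable[SequenceRecord] = (), role: str = "genome"):
        if role not in ("genome", "transposon"):
            raise ValueError("role must be 'genome' or 'transposon'")
        self.role = role
        self.entries: dict[str, SequenceRecord] = {}
        self._indexes: dict[int, SeedIndex] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.id in self.entries:
            raise DuplicateIdError(f"duplicate reference id {rec.id!r} in {self.role} database")
        self.entries[rec.id] = rec
        self._indexes.clear()

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, rid: str) -> bool:
        return rid in self.entries

    def get(self, rid: str) -> SequenceRecord:
        return self.entries[rid]

    def ids(self) -> list[str]:
        return list(self.entries)

    def seed_index(self, k: int) -> SeedIndex:
        """Build (and memoize) the k-mer index for this database."""
        if k not in self._indexes:
            self._indexes[k] = build_index(self, k)
        return self._indexes[k]


def build_index(db: ReferenceDB, k: int) -> SeedIndex:
    """Index every plus-strand k-mer occurrence of every entry.

    Errors if k exceeds the shortest reference; warns below the minimal
    effective nucleus size.
    """
    if k < 4:
        raise KmerError("seed length must be >= 4")
    if k < MIN_EFFECTIVE_NUCLEUS:
        log.warning("seed length %d below the minimal effective value %d",
                    k, MIN_EFFECTIVE_NUCLEUS)
    if db.entries:
        shortest = min(len(r) for r in db.entries.values())
        if k > shortest:
            raise KmerError(
                f"seed length {k} longer than the shortest reference ({shortest} nt)"
            )
    postings: dict[str, list[tuple[str, int]]] = {}
    for rid, rec in db.entries.items():
        seq = rec.seq
        for off in range(len(seq) - k + 1):
            kmer = seq[off:off + k]
            if "N" in kmer:
                continue
            postings.setdefault(kmer, []).append((rid, off))
    return SeedIndex(k, postings)


def lookup(index: SeedIndex, query: str) -> list[SeedHit]:
    """All exact k-mer matches of *query* against the index, both strands.

    Minus-strand hits report offsets into the reverse-complemented query.
    """
    k = index.k
    if len(query) < k:
        raise QueryTooShortError(f"query length {len(query)} < seed length {k}")
    hits: list[SeedHit] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        for qoff in range(len(q) - k + 1):
            for rid, roff in index.postings.get(q[qoff:qoff + k], ()):
                hits.append(SeedHit(rid, qoff, roff, strand))
    return hits
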