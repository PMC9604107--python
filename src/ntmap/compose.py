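"""Assembly of subalignments into final composite alignments.

Composition rules
-----------------
Two genome-origin ("blue") parts may coalesce into the same final alignment
only when they sit on the same reference and strand, their query order agrees
with their reference order, and the reference-coordinate gap between them is
non-negative (no genomic overlap) and at most ``max_genomic_gap`` (200 by
default).  A query spanning a genomic deletion larger than that is therefore
reported as two separate final results.  Neither restriction applies to pairs
involving a transposon-origin ("red") part: blue-red composition is what
detects insertions, and red-red composition detects self-insertions and large
internal deletions, regardless of overlapping transposon coordinates.

A junction alignment whose transposon part carries an almost intact TIR right
at the border nucleotide can receive a +500 score bonus, which lets insertion
candidates outrank concurrent purely genomic alignments.

Chance identity at a breakpoint can make two parts overlap by a few query
bases (the first transposon base may equal the next genomic base).  Overlaps
up to ``MAX_QUERY_OVERLAP`` are resolved by trimming: at a genome-transposon
junction the genome part is cut back to the transposon edge, because the TIR
end is the anchored coordinate; otherwise the lower-scoring part yields.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .align import (
    DEFAULT_SCHEME,
    ScoringScheme,
    Subalignment,
    cigar_identity_over_reference,
    extend_exact,
    shave_end,
    trim_query_interval,
)
from .annotate import Feature
from .errors import NtmapError
from .index import Parameters, ReferenceDB

log = logging.getLogger(__name__)

BONUS = 500
MAX_QUERY_OVERLAP = 60
JUNCTION_ABUT_TOLERANCE = 5
TIR_MIN_IDENTITY = 0.9
TIR_MIN_COVERAGE = 0.9
_MAX_PARTS_ENUMERATED = 16


@dataclass
class CompositeAlignment:
    """An ordered set of subalignments forming one final result."""

    parts: tuple[Subalignment, ...]
    total_score: int
    bonus_applied: bool = False
    placement_rank: int = 0

    @property
    def classification(self) -> str:
        origins = {p.origin for p in self.parts}
        if origins == {"genome"}:
            return "genomic"
        if origins == {"transposon"}:
            return "transposon_internal"
        return "junction"

    @property
    def query_span(self) -> tuple[int, int]:
        return (min(p.q_start for p in self.parts), max(p.q_end for p in self.parts))

    @property
    def base_score(self) -> int:
        return self.total_score - (BONUS if self.bonus_applied else 0)

    def placement_key(self) -> tuple:
        return tuple((p.reference_id, p.reference_interval, p.strand) for p in self.parts)


def _genomic_gap(a: Subalignment, b: Subalignment) -> Optional[int]:
    """Reference gap between consecutive genome parts (a before b on the query),
    oriented by strand; None when the order is inconsistent."""
    if a.strand == "+":
        return b.r_start - a.r_end
    return a.r_start - b.r_end


def pair_allowed(a: Subalignment, b: Subalignment, params: Parameters,
                 slack: int = 0) -> bool:
    """May *b* follow *a* (query order) inside one composite?

    ``slack`` loosens the genomic-gap window to admit pairs that become valid
    once an overlap is trimmed; materialization re-checks strictly.
    """
    overlap = a.q_end - b.q_start
    if overlap > MAX_QUERY_OVERLAP:
        return False
    if a.origin == "genome" and b.origin == "genome":
        if a.reference_id != b.reference_id or a.strand != b.strand:
            return False
        gap = _genomic_gap(a, b)
        return -slack <= gap <= params.max_genomic_gap + slack
    return True  # blue-red / red-red: no restriction


def _repair(sub, scheme, query_seq, ref_seqs, q_end=None, q_start=None):
    """Re-anchor a trimmed part at the junction boundary.

    The optimal untrimmed alignment may have crossed the breakpoint via a gap
    plus a few chance matches; trimming then leaves a weakly anchored stub
    that misplaces the junction coordinate.  Two candidates are compared: the
    plain trim, and the trim with the boundary-side stub shaved back to a
    solid match anchor -- each re-extended toward the boundary with exact
    matches only.  The higher-scoring candidate wins (the shaved one on a
    tie)."""
    if query_seq is None or ref_seqs is None:
        return sub
    ref = ref_seqs.get((sub.origin, sub.reference_id))
    if ref is None:
        return sub

    def grown(s):
        return extend_exact(s, query_seq, ref, target_q_end=q_end,
                            target_q_start=q_start, scheme=scheme)

    candidates = []
    shaved = shave_end(sub, "end" if q_end is not None else "start", scheme=scheme)
    if shaved is not None:
        candidates.append(grown(shaved))
    candidates.append(grown(sub))
    return max(candidates, key=lambda s: s.score)


def _resolve_overlaps(
    chain: Sequence[Subalignment],
    scheme: ScoringScheme,
    query_seq: Optional[str] = None,
    ref_seqs: Optional[dict] = None,
) -> Optional[list[Subalignment]]:
    """Trim query overlaps between consecutive parts; None if a part vanishes."""
    parts: list[Subalignment] = []
    for cur in chain:
        if parts:
            prev = parts[-1]
            overlap = prev.q_end - cur.q_start
            if overlap > 0:
                trim_prev = (prev.origin == "genome") if prev.origin != cur.origin \
                    else (prev.score < cur.score)
                if trim_prev:
                    boundary = cur.q_start
                    prev = trim_query_interval(prev, new_q_end=boundary, scheme=scheme)
                    if prev is not None:
                        prev = _repair(prev, scheme, query_seq, ref_seqs, q_end=boundary)
                else:
                    boundary = prev.q_end
                    cur = trim_query_interval(cur, new_q_start=boundary, scheme=scheme)
                    if cur is not None:
                        cur = _repair(cur, scheme, query_seq, ref_seqs, q_start=boundary)
                if prev is None or cur is None:
                    return None
                parts[-1] = prev
        parts.append(cur)
    return parts


def _chain_valid(parts: Sequence[Subalignment], params: Parameters) -> bool:
    for a, b in zip(parts, parts[1:]):
        if b.q_start < a.q_end:
            return False
        if a.origin == "genome" and b.origin == "genome":
            if a.reference_id != b.reference_id or a.strand != b.strand:
                return False
            gap = _genomic_gap(a, b)
            if gap is None or gap < 0 or gap > params.max_genomic_gap:
                return False
    return True


def ranking_key(c: CompositeAlignment) -> tuple:
    first = c.parts[0]
    return (-c.total_score, len(c.parts), first.reference_id,
            min(p.r_start for p in c.parts), first.strand)


def compose(
    subs: Sequence[Subalignment],
    params: Parameters = Parameters(),
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_seq: Optional[str] = None,
    ref_seqs: Optional[dict] = None,
) -> list[CompositeAlignment]:
    """Enumerate every rule-respecting chain of subalignments of one query.

    Output is ranked by total score (ties: fewer parts, then reference id,
    then leftmost reference start) and truncated to ``number_of_results``.
    ``query_seq``/``ref_seqs`` (keyed by (origin, reference_id)) enable
    exact-match repair of trimmed junction boundaries.
    """
    subs = sorted(subs, key=lambda s: (s.q_start, s.q_end, -s.score,
                                       s.reference_id, s.r_start))
    if len(subs) > _MAX_PARTS_ENUMERATED:
        top = sorted(subs, key=lambda s: -s.score)[:_MAX_PARTS_ENUMERATED]
        keep = set(id(s) for s in top)
        subs = [s for s in subs if id(s) in keep]
    n = len(subs)
    chains: list[tuple[Subalignment, ...]] = []

    def grow(chain: list[Subalignment], start: int) -> None:
        chains.append(tuple(chain))
        for j in range(start, n):
            if pair_allowed(chain[-1], subs[j], params, slack=MAX_QUERY_OVERLAP):
                chain.append(subs[j])
                grow(chain, j + 1)
                chain.pop()

    for i in range(n):
        grow([subs[i]], i + 1)

    out: list[CompositeAlignment] = []
    seen: set[tuple] = set()
    for chain in chains:
        parts = (_resolve_overlaps(chain, scheme, query_seq, ref_seqs)
                 if len(chain) > 1 else list(chain))
        if parts is None or not _chain_valid(parts, params):
            continue
        key = tuple((p.reference_id, p.query_interval, p.reference_interval, p.strand,
                     p.origin) for p in parts)
        if key in seen:
            continue
        seen.add(key)
        out.append(CompositeAlignment(
            parts=tuple(parts),
            total_score=sum(p.score for p in parts),
        ))
    out.sort(key=ranking_key)
    return out[: params.number_of_results]


def _junction_pairs(c: CompositeAlignment):
    for a, b in zip(c.parts, c.parts[1:]):
        if {a.origin, b.origin} == {"genome", "transposon"}:
            yield a, b


def apply_bonus(
    c: CompositeAlignment,
    td: ReferenceDB,
    tir_annotations: dict[str, list[Feature]],
    params: Parameters,
) -> CompositeAlignment:
    """Add +500 once when an almost intact annotated TIR abuts the junction.

    "Almost intact" means the transposon part covers >= 90% of the TIR length
    with >= 90% identity, and the TIR lies at the junction end of the
    transposon part.  No-op when the bonus option is off, the composite is not
    a junction, or no TIR qualifies.
    """
    if not params.bonus or c.classification != "junction" or c.bonus_applied:
        return c
    for a, b in _junction_pairs(c):
        if b.q_start - a.q_end > JUNCTION_ABUT_TOLERANCE:
            continue
        tp = a if a.origin == "transposon" else b
        genome_first = a.origin == "genome"
        tirs = tir_annotations.get(tp.reference_id, [])
        # reference coordinate of the transposon part at the junction side
        if genome_first:
            junction_ref = tp.r_start if tp.strand == "+" else tp.r_end - 1
        else:
            junction_ref = tp.r_end - 1 if tp.strand == "+" else tp.r_start
        for tir in tirs:
            if tir.category not in ("TIR5", "TIR3"):
                continue
            lo, hi = tir.interval
            if not (lo - JUNCTION_ABUT_TOLERANCE <= junction_ref < hi + JUNCTION_ABUT_TOLERANCE):
                continue
            matches, cols, covered = cigar_identity_over_reference(tp, tir.interval)
            tir_len = hi - lo
            if covered >= TIR_MIN_COVERAGE * tir_len and cols > 0 \
                    and matches >= TIR_MIN_IDENTITY * cols:
                return replace(c, total_score=c.total_score + BONUS, bonus_applied=True)
    return c


def suppress_covered_junctions(
    composites: Sequence[CompositeAlignment],
) -> list[CompositeAlignment]:
    """Drop mixed composites whose query span is covered by an all-genomic
    composite of at least the same (pre-bonus) score.

    Once a best blue alignment covers a query interval, no alternative
    blue-red alignment with the same score is reported for it -- this is what
    classifies insertions shared with the reference genome as genomic-only.
    """
    genomic = [c for c in composites if c.classification == "genomic"]
    out = []
    for c in composites:
        if c.classification != "genomic":
            span = c.query_span
            if any(
                g.query_span[0] <= span[0] and g.query_span[1] >= span[1]
                and g.base_score >= c.base_score
                for g in genomic
            ):
                continue
        out.append(c)
    return out


def pick_placements(
    composites: Sequence[CompositeAlignment],
    params: Parameters,
) -> list[CompositeAlignment]:
    """Limit equal-scoring, same-span placements within one reference.

    Once a query interval is covered by an alignment against a subsequence of
    a particular reference, at most ``picking_depth`` distinct placements of
    that alignment are reported for that reference, even if identical
    subsequences occur at other coordinates.  Ranks are assigned 1-based.
    """
    counts: dict[tuple, int] = {}
    seen_placements: set[tuple] = set()
    out: list[CompositeAlignment] = []
    for c in sorted(composites, key=ranking_key):
        placement = c.placement_key()
        if placement in seen_placements:
            continue
        seen_placements.add(placement)
        group = (c.total_score, c.query_span,
                 tuple(sorted({p.reference_id for p in c.parts})))
        counts[group] = counts.get(group, 0) + 1
        if counts[group] > params.picking_depth:
            continue
        out.append(replace(c, placement_rank=len(out) + 1))
    return out
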