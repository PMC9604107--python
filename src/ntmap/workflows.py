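"""The two mapping workflows, as library functions.

WF1 (scan): the genome database holds only the ARG contigs; the contigs are
scanned with the transposon's terminal queries (Q5'/Q3'), hits are filtered
on score and TIR integrity, and junction queries are extracted around each
retained remnant.

WF2 (map): the genome database holds the canonical reference genome and the
transposon database the transposon reference; the junction queries from WF1
are aligned, composed, optionally bonus-boosted, and the best result per
query becomes a row of the exported table -- a junction row carries the TGN
coordinate, orientation and TSD, a completely genomic row marks an insertion
shared with the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .align import DEFAULT_SCHEME, ScoringScheme, Subalignment, align_query, \
    cigar_identity_over_query
from .annotate import Feature, annotate_call
from .call import InsertionCall, call_insertion, extract_tsd
from .compose import (
    CompositeAlignment,
    apply_bonus,
    compose,
    pick_placements,
    ranking_key,
    suppress_covered_junctions,
)
from .errors import QueryTooShortError, TsdAlertError
from .index import Parameters, ReferenceDB
from .io import ResultRow, SequenceRecord
from .junctions import (
    DEFAULT_CROP,
    DEFAULT_FLANK,
    DEFAULT_TAIL,
    JunctionQuery,
    RemnantHit,
    crop_terminal_queries,
    extract_junction_queries,
)

log = logging.getLogger(__name__)

TIR_MIN_IDENTITY = 0.9


def _tir_query_interval(side: str, tir_len: int, crop_len: int) -> tuple[int, int]:
    # Q5' carries the TIR at its start, Q3' at its end
    return (0, tir_len) if side == "5'" else (crop_len - tir_len, crop_len)


def filter_remnant_hits(
    subs: Sequence[Subalignment],
    side: str,
    tir_len: int,
    crop_len: int,
    params: Parameters,
) -> list[Subalignment]:
    """Keep subalignments scoring at least ``min_report_score`` whose TIR
    region is completely covered at high identity (the automated version of
    visually checking that the hit has the complete TIR)."""
    lo, hi = _tir_query_interval(side, tir_len, crop_len)
    out = []
    for s in subs:
        if s.score < params.min_report_score:
            continue
        matches, cols, covered = cigar_identity_over_query(s, (lo, hi))
        if covered >= TIR_MIN_IDENTITY * (hi - lo) and cols > 0 \
                and matches >= TIR_MIN_IDENTITY * cols:
            out.append(s)
    return out


def _limit_placements(hits: Sequence[Subalignment], params: Parameters) -> list[Subalignment]:
    """Picking-depth rule at the subalignment level: within one reference,
    at most picking_depth equal-scoring placements of the same query span."""
    counts: dict[tuple, int] = {}
    out = []
    for s in sorted(hits, key=lambda s: (-s.score, s.reference_id, s.r_start)):
        key = (s.score, s.query_interval, s.reference_id)
        counts[key] = counts.get(key, 0) + 1
        if counts[key] <= params.picking_depth:
            out.append(s)
    return out


@dataclass
class ScanResult:
    query_records: tuple[SequenceRecord, SequenceRecord]  # Q5', Q3'
    hits: list[RemnantHit]
    junction_queries: list[JunctionQuery]


def wf1_scan(
    nt: SequenceRecord,
    arg: ReferenceDB,
    tir5_len: int,
    tir3_len: int,
    params: Optional[Parameters] = None,
    crop_len: int = DEFAULT_CROP,
    flank: int = DEFAULT_FLANK,
    tail: int = DEFAULT_TAIL,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> ScanResult:
    """Scan ARG contigs with the transposon terminal queries and extract JQs."""
    params = params or Parameters.wf1()
    q5, q3 = crop_terminal_queries(nt, crop_len)
    empty_td = ReferenceDB(role="transposon")
    hits: list[RemnantHit] = []
    for rec, side, tir_len in ((q5, "5'", tir5_len), (q3, "3'", tir3_len)):
        subs = align_query(rec, arg, empty_td, params, scheme)
        subs = filter_remnant_hits(subs, side, tir_len, crop_len, params)
        subs = _limit_placements(subs, params)
        for s in subs:
            hits.append(RemnantHit(
                contig_id=s.reference_id, side=side,
                start=s.r_start, end=s.r_end, strand=s.strand, score=s.score,
            ))
    if not hits:
        log.warning("no %s remnants found in the contig set", nt.id)
    jqs = extract_junction_queries(
        list(arg.entries.values()), hits,
        flank=flank, nt_len=len(nt), tail=tail, crop_len=crop_len,
    )
    return ScanResult(query_records=(q5, q3), hits=hits, junction_queries=jqs)


def map_query(
    query: SequenceRecord,
    gd: ReferenceDB,
    td: ReferenceDB,
    params: Parameters,
    tir_annotations: Optional[dict[str, list[Feature]]] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[CompositeAlignment]:
    """Full alignment pipeline for one query: seed/extend, compose, suppress
    covered junctions, bonus, rank, placement picking, truncation."""
    subs = align_query(query, gd, td, params, scheme)
    ref_seqs = {("genome", rid): rec.seq for rid, rec in gd.entries.items()}
    ref_seqs.update({("transposon", rid): rec.seq for rid, rec in td.entries.items()})
    # compose with an uncapped list so suppression/bonus act before truncation
    composites = compose(subs, params.with_overrides(number_of_results=10_000), scheme,
                         query_seq=query.seq, ref_seqs=ref_seqs)
    composites = suppress_covered_junctions(composites)
    if params.bonus:
        composites = [
            apply_bonus(c, td, tir_annotations or {}, params) for c in composites
        ]
        composites.sort(key=ranking_key)
    composites = pick_placements(composites, params)
    return composites[: params.number_of_results]


@dataclass
class MapResult:
    rows: list[ResultRow]
    calls: list[InsertionCall]
    composites: dict[str, list[CompositeAlignment]]


def wf2_map(
    queries: Sequence[SequenceRecord],
    gd: ReferenceDB,
    td: ReferenceDB,
    params: Optional[Parameters] = None,
    tir_annotations: Optional[dict[str, list[Feature]]] = None,
    features: Sequence[Feature] = (),
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> MapResult:
    """Map junction queries against CRG + TD and build the result table."""
    params = params or Parameters.wf2()
    rows: list[ResultRow] = []
    calls: list[InsertionCall] = []
    all_composites: dict[str, list[CompositeAlignment]] = {}
    for q in queries:
        try:
            composites = map_query(q, gd, td, params, tir_annotations, scheme)
        except QueryTooShortError:
            log.warning("query %s shorter than the nucleus size; skipped", q.id)
            continue
        all_composites[q.id] = composites
        if not composites:
            rows.append(ResultRow(query_id=q.id, classification="genomic", score=0))
            continue
        best = composites[0]
        if best.classification == "junction":
            call = call_insertion(best, gd, params, td)
            try:
                call.tsd = extract_tsd(call, gd, params.tsd_flank_length, params)
            except TsdAlertError as exc:
                log.warning("%s: %s", q.id, exc)
                call.tsd = ""
            ctx = annotate_call(call, features)
            calls.append(call)
            rows.append(ResultRow(
                query_id=q.id,
                transposon=call.transposon,
                reference_id=call.reference_id,
                tgn_coordinate=call.tgn,
                orientation=call.orientation,
                score=best.total_score,
                hit_gene=ctx.hit_gene,
                upstream_gene=ctx.upstream_gene,
                downstream_gene=ctx.downstream_gene,
                tsd=call.tsd,
                classification="junction",
            ))
        else:
            first = best.parts[0]
            rows.append(ResultRow(
                query_id=q.id,
                reference_id=first.reference_id,
                score=best.total_score,
                classification=best.classification,
            ))
    return MapResult(rows=rows, calls=calls, composites=all_composites)
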