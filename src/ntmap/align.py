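"""Seed-and-extend local alignment of a query against the reference databases.

A query is aligned by (1) looking up exact nucleus-size seeds on both strands,
(2) merging seeds that fall on nearby diagonals into chains, and (3) extending
each chain with a banded local affine-gap (Smith-Waterman/Gotoh) DP around the
chain diagonals.  The band is what bounds the explored reference window: the
DP visits reference span = query length + band width, so the "short" extension
stays within roughly twice the query length.  A gap larger than the band can
never be bridged inside one subalignment -- reconciling distant pieces is the
composer's job, which is exactly the division of labour the composition rules
assume.

Scoring defaults: match +1, mismatch -1, gap open -2, gap extend -1 (a gap of
length L costs open + (L-1)*extend).  A perfect 60-nt query therefore scores
60, which is the scale on which the recommended reporting threshold of 40 is
expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .dna import N_CODE, encode, revcomp
from .errors import QueryTooShortError
from .index import Parameters, ReferenceDB, SeedHit, lookup
from .io import SequenceRecord

log = logging.getLogger(__name__)

NEG = -(1 << 20)
MAX_RECOMMENDED_QUERY = 15_000

# band half-width added around the chain diagonals, per extension mode
_BAND_PAD = {"short": 64, "long": 512}
# seeds whose diagonals differ by at most this much are merged into one chain
CHAIN_DIAG_BAND = 16
# split a chain when consecutive seeds are further apart than this on the
# query or the reference
CHAIN_MAX_SEED_GAP = 500


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open > self.mismatch or self.gap_extend > self.mismatch:
            raise ValueError("gap penalties must be <= mismatch")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be <= gap_extend")


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class Subalignment:
    """One locally aligned query<->reference segment.

    Query interval is 0-based half-open in the *original* query coordinates.
    The cigar runs along the oriented query (the reverse complement for
    minus-strand hits) with the reference always read forward, using M (match),
    X (mismatch), I (query insertion) and D (reference deletion) run-lengths.
    """

    query_id: str
    query_interval: tuple[int, int]
    reference_id: str
    reference_interval: tuple[int, int]
    origin: str  # genome | transposon
    strand: str  # + | -
    score: int
    cigar: str
    query_length: int

    @property
    def q_start(self) -> int:
        return self.query_interval[0]

    @property
    def q_end(self) -> int:
        return self.query_interval[1]

    @property
    def r_start(self) -> int:
        return self.reference_interval[0]

    @property
    def r_end(self) -> int:
        return self.reference_interval[1]

    def oriented_query_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.query_interval
        n = self.query_length
        return (n - self.q_end, n - self.q_start)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    runs = []
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            runs.append((int(num), c))
            num = ""
    if num:
        raise ValueError(f"trailing run length in cigar {cigar!r}")
    return runs


def cigar_from_ops(ops: Iterable[str]) -> str:
    out = []
    prev = None
    count = 0
    for op in ops:
        if op == prev:
            count += 1
        else:
            if prev is not None:
                out.append(f"{count}{prev}")
            prev, count = op, 1
    if prev is not None:
        out.append(f"{count}{prev}")
    return "".join(out)


def score_from_cigar(cigar: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Recompute an alignment score from its cigar (affine gaps)."""
    total = 0
    for length, op in parse_cigar(cigar):
        if op == "M":
            total += length * scheme.match
        elif op == "X":
            total += length * scheme.mismatch
        elif op in "ID":
            total += scheme.gap_open + (length - 1) * scheme.gap_extend
        else:
            raise ValueError(f"unknown cigar op {op!r}")
    return total


def banded_local_align(
    q: np.ndarray,
    r: np.ndarray,
    dlo: int,
    dhi: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> Optional[tuple[int, tuple[int, int], tuple[int, int], str]]:
    """Local affine-gap DP restricted to diagonals d = j - i in [dlo, dhi].

    Returns (score, (q_start, q_end), (r_start, r_end), cigar) of the best
    local alignment inside the band, or None if no positive-scoring cell
    exists.  Rows are query positions, columns reference positions.
    """
    n, m = len(q), len(r)
    dlo = max(dlo, -n)
    dhi = min(dhi, m)
    if dhi < dlo:
        return None
    W = dhi - dlo + 1
    ma, mi, go, ge = scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend

    H = np.full((n + 1, W), NEG, dtype=np.int32)
    ptr = np.zeros((n + 1, W), dtype=np.uint8)  # 0 stop, 1 diag, 2 E(horiz), 3 F(vert)
    bidx = np.arange(W, dtype=np.int32)
    j0 = dlo + bidx
    H[0][(j0 >= 0) & (j0 <= m)] = 0
    Fprev = np.full(W, NEG, dtype=np.int32)
    zeros = np.zeros(W, dtype=np.int32)
    ge_ramp = bidx * ge

    for i in range(1, n + 1):
        j = i + dlo + bidx
        valid = (j >= 1) & (j <= m)
        hp = H[i - 1]
        # substitution scores against r[j-1]
        jc = np.clip(j - 1, 0, m - 1)
        qc = q[i - 1]
        s = np.where((r[jc] == qc) & (qc != N_CODE) & (r[jc] != N_CODE), ma, mi)
        diag = hp + s
        # vertical (query-consuming) gap: predecessor is (i-1, b+1)
        hp_up = np.empty(W, dtype=np.int32)
        hp_up[:-1] = hp[1:]
        hp_up[-1] = NEG
        f_up = np.empty(W, dtype=np.int32)
        f_up[:-1] = Fprev[1:]
        f_up[-1] = NEG
        F = np.maximum(hp_up + go, f_up + ge)
        H0 = np.maximum(np.maximum(zeros, diag), F)
        H0[~valid] = NEG
        # horizontal (reference-consuming) gap via prefix scan over the row;
        # exact because gap_open <= gap_extend makes re-opening inside a gap
        # never profitable
        E = np.full(W, NEG, dtype=np.int32)
        if W > 1:
            P = np.maximum.accumulate(H0 - ge_ramp)
            E[1:] = go + ge_ramp[1:] - ge + P[:-1]
            E[~valid] = NEG
        Hrow = np.maximum(H0, E)
        p = np.zeros(W, dtype=np.uint8)
        p[Hrow == E] = 2
        p[Hrow == F] = 3
        p[Hrow == diag] = 1
        boundary = j == 0
        Hrow[boundary] = 0
        Hrow[~valid & ~boundary] = NEG
        p[Hrow <= 0] = 0
        F[~valid] = NEG
        H[i] = Hrow
        ptr[i] = p
        Fprev = F

    flat = int(np.argmax(H))
    i, b = divmod(flat, W)
    score = int(H[i, b])
    if score <= 0:
        return None
    j = i + dlo + b
    qe, re_ = i, j
    ops: list[str] = []
    state = "H"
    v = score
    while True:
        if state == "H":
            pt = ptr[i, b]
            if pt == 0:
                break
            if pt == 1:
                ops.append("M" if (q[i - 1] == r[j - 1] and q[i - 1] != N_CODE) else "X")
                i -= 1
                j -= 1
            elif pt == 2:
                state = "E"
                v = int(H[i, b])
            else:
                state = "F"
                v = int(H[i, b])
        elif state == "E":
            # gap consuming r[j-1]; predecessor (i, b-1)
            ops.append("D")
            prev = int(H[i, b - 1])
            if v == prev + go:
                state = "H"
            else:
                v -= ge
            b -= 1
            j -= 1
        else:  # F state: gap consuming q[i-1]; predecessor (i-1, b+1)
            ops.append("I")
            prev = int(H[i - 1, b + 1])
            if v == prev + go:
                state = "H"
            else:
                v -= ge
            i -= 1
            b += 1
    qs, rs = i, j
    cigar = cigar_from_ops(reversed(ops))
    return score, (qs, qe), (rs, re_), cigar


@dataclass
class SeedChain:
    reference_id: str
    strand: str
    q_min: int
    q_max: int  # inclusive of the last seed start
    d_min: int
    d_max: int
    n_seeds: int


def chain_seeds(
    hits: Iterable[SeedHit],
    diag_band: int = CHAIN_DIAG_BAND,
    max_gap: int = CHAIN_MAX_SEED_GAP,
) -> list[SeedChain]:
    """Merge seeds on nearby diagonals of one (reference, strand) into chains."""
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        by_key.setdefault((h.reference_id, h.strand), []).append(
            (h.reference_offset - h.query_offset, h.query_offset)
        )
    chains: list[SeedChain] = []
    for (rid, strand), pairs in by_key.items():
        pairs.sort()
        cur: Optional[SeedChain] = None
        for d, qoff in pairs:
            if (
                cur is not None
                and d - cur.d_max <= diag_band
                and (d != cur.d_max or abs(qoff - cur.q_max) <= max_gap)
            ):
                cur.d_max = d
                cur.q_min = min(cur.q_min, qoff)
                cur.q_max = max(cur.q_max, qoff)
                cur.n_seeds += 1
            else:
                if cur is not None:
                    chains.append(cur)
                cur = SeedChain(rid, strand, qoff, qoff, d, d, 1)
        if cur is not None:
            chains.append(cur)
    return chains


def extend_chain(
    chain: SeedChain,
    query_oriented: str,
    reference: SequenceRecord,
    scheme: ScoringScheme,
    extension: str = "short",
) -> Optional[tuple[int, tuple[int, int], tuple[int, int], str]]:
    """Banded extension of one seed chain; returns the raw DP result in
    oriented-query coordinates."""
    pad = _BAND_PAD.get(extension, _BAND_PAD["short"])
    n = len(query_oriented)
    pad = max(CHAIN_DIAG_BAND, min(pad, max(n // 2, CHAIN_DIAG_BAND)))
    q = encode(query_oriented)
    r = encode(reference.seq)
    return banded_local_align(q, r, chain.d_min - pad, chain.d_max + pad, scheme)


def extend_seed(
    seed: SeedHit,
    query: str,
    reference: SequenceRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    extension: str = "short",
) -> Optional[tuple[int, tuple[int, int], tuple[int, int], str]]:
    """Extend a single seed hit (convenience wrapper around the banded DP).

    The query must already be oriented to the seed strand.
    """
    d = seed.reference_offset - seed.query_offset
    chain = SeedChain(seed.reference_id, seed.strand, seed.query_offset,
                      seed.query_offset, d, d, 1)
    return extend_chain(chain, query, reference, scheme, extension)


def _redundant(a: Subalignment, b: Subalignment, frac: float = 0.8) -> bool:
    """True when *a* is essentially the same locus as the kept *b*."""
    if a.reference_id != b.reference_id or a.strand != b.strand:
        return False
    qo = min(a.q_end, b.q_end) - max(a.q_start, b.q_start)
    ro = min(a.r_end, b.r_end) - max(a.r_start, b.r_start)
    qlen = min(a.q_end - a.q_start, b.q_end - b.q_start)
    rlen = min(a.r_end - a.r_start, b.r_end - b.r_start)
    return qo >= frac * qlen and ro >= frac * rlen


def align_query(
    query: SequenceRecord,
    gd: ReferenceDB,
    td: ReferenceDB,
    params: Parameters = Parameters(),
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[Subalignment]:
    """Seed, chain and extend *query* against both databases, both strands.

    Returns deduplicated subalignments sorted by score (ties by reference id
    and leftmost reference start, for determinism).
    """
    k = params.nucleus_size
    if len(query) < k:
        raise QueryTooShortError(
            f"query {query.id!r} ({len(query)} nt) shorter than nucleus size {k}"
        )
    if len(query) > MAX_RECOMMENDED_QUERY:
        log.warning("query %s is %d nt; queries longer than %d nt are not recommended",
                    query.id, len(query), MAX_RECOMMENDED_QUERY)
    oriented = {"+": query.seq, "-": revcomp(query.seq)}
    n = len(query)
    raw: list[Subalignment] = []
    for db in (gd, td):
        if len(db) == 0:
            continue
        index = db.seed_index(k)
        hits = lookup(index, query.seq)
        for chain in chain_seeds(hits):
            ref = db.get(chain.reference_id)
            res = extend_chain(chain, oriented[chain.strand], ref, scheme,
                               params.interval_extension)
            if res is None:
                continue
            score, (qs, qe), (rs, re_), cigar = res
            if chain.strand == "+":
                q_int = (qs, qe)
            else:
                q_int = (n - qe, n - qs)
            raw.append(Subalignment(
                query_id=query.id,
                query_interval=q_int,
                reference_id=chain.reference_id,
                reference_interval=(rs, re_),
                origin=db.role,
                strand=chain.strand,
                score=score,
                cigar=cigar,
                query_length=n,
            ))
    raw.sort(key=lambda s: (-s.score, s.reference_id, s.r_start, s.strand))
    kept: list[Subalignment] = []
    for sub in raw:
        if not any(_redundant(sub, k_) for k_ in kept):
            kept.append(sub)
    return kept


def trim_query_interval(
    sub: Subalignment,
    new_q_start: Optional[int] = None,
    new_q_end: Optional[int] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> Optional[Subalignment]:
    """Restrict a subalignment to original-query positions [new_q_start, new_q_end).

    Used by the composer to resolve small query overlaps between parts.  The
    cigar is cut at the boundary, dangling gap columns are stripped and the
    score recomputed.  Returns None when nothing is left.
    """
    qs, qe = sub.query_interval
    new_q_start = qs if new_q_start is None else max(qs, new_q_start)
    new_q_end = qe if new_q_end is None else min(qe, new_q_end)
    if new_q_start <= qs and new_q_end >= qe:
        return sub
    if new_q_end <= new_q_start:
        return None
    # map to oriented coordinates (cigar order)
    if sub.strand == "+":
        o_start, o_end = new_q_start, new_q_end
    else:
        o_start, o_end = sub.query_length - new_q_end, sub.query_length - new_q_start
    ostart_cur, _ = sub.oriented_query_interval()
    cols: list[tuple[str, bool, bool]] = []  # (op, consumes_q, consumes_r)
    for length, op in parse_cigar(sub.cigar):
        cq = op in "MXI"
        cr = op in "MXD"
        cols.extend([(op, cq, cr)] * length)
    oq = ostart_cur
    r = sub.r_start
    kept: list[tuple[str, int, int]] = []  # (op, oq before column, r before column)
    for op, cq, cr in cols:
        if oq >= o_end:
            break
        inside = (not cq) or (o_start <= oq < o_end)
        if inside:
            kept.append((op, oq, r))
        if cq:
            oq += 1
        if cr:
            r += 1
    # an alignment may not begin or end with a gap column
    while kept and kept[0][0] in "ID":
        kept.pop(0)
    while kept and kept[-1][0] in "ID":
        kept.pop()
    if not kept:
        return None
    new_or_start = kept[0][1]
    new_r_start = kept[0][2]
    new_or_end = kept[-1][1] + 1
    new_r_end = kept[-1][2] + 1
    cigar = cigar_from_ops(op for op, _, _ in kept)
    if sub.strand == "+":
        q_int = (new_or_start, new_or_end)
    else:
        q_int = (sub.query_length - new_or_end, sub.query_length - new_or_start)
    return replace(
        sub,
        query_interval=q_int,
        reference_interval=(new_r_start, new_r_end),
        cigar=cigar,
        score=score_from_cigar(cigar, scheme),
    )


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def shave_end(
    sub: Subalignment,
    side: str,
    min_anchor: int = 8,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> Optional[Subalignment]:
    """Drop weakly anchored runs from one end of a subalignment.

    ``side`` is "end" (high original-query coordinates) or "start".  Runs are
    removed from that end until the terminal run is a match run of at least
    ``min_anchor`` columns, so a gap-plus-stray-match tail left over from
    trimming cannot misplace a junction coordinate.  Returns None when
    nothing anchored remains.
    """
    if side not in ("start", "end"):
        raise ValueError("side must be 'start' or 'end'")
    runs = parse_cigar(sub.cigar)
    oqs, oqe = sub.oriented_query_interval()
    rs, re_ = sub.reference_interval
    tail = (side == "end") == (sub.strand == "+")
    changed = False
    while runs:
        n, op = runs[-1] if tail else runs[0]
        if op == "M" and n >= min_anchor:
            break
        changed = True
        if tail:
            runs.pop()
        else:
            runs.pop(0)
        if op in "MX":
            if tail:
                oqe -= n
                re_ -= n
            else:
                oqs += n
                rs += n
        elif op == "I":
            if tail:
                oqe -= n
            else:
                oqs += n
        else:  # D
            if tail:
                re_ -= n
            else:
                rs += n
    if not runs:
        return None
    if not changed:
        return sub
    cigar = "".join(f"{n}{op}" for n, op in runs)
    if sub.strand == "+":
        q_int = (oqs, oqe)
    else:
        q_int = (sub.query_length - oqe, sub.query_length - oqs)
    return replace(
        sub,
        query_interval=q_int,
        reference_interval=(rs, re_),
        cigar=cigar,
        score=score_from_cigar(cigar, scheme),
    )


def extend_exact(
    sub: Subalignment,
    query_seq: str,
    ref_seq: str,
    target_q_end: Optional[int] = None,
    target_q_start: Optional[int] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> Subalignment:
    """Grow a subalignment with exact single-base matches up to a query bound.

    Used after a junction trim: when the optimal local alignment consumed a
    breakpoint base inside a gap, the trimmed part can lose the base adjacent
    to the junction even though it matches the reference exactly.  This adds
    back match columns only (no gaps, no mismatches), so the score stays
    consistent with the cigar.
    """
    qs, qe = sub.query_interval
    rs, re_ = sub.reference_interval
    runs = parse_cigar(sub.cigar)
    added_head = added_tail = 0
    if target_q_end is not None:
        while qe < target_q_end:
            if sub.strand == "+":
                if re_ >= len(ref_seq) or query_seq[qe] != ref_seq[re_]:
                    break
                re_ += 1
            else:
                if rs <= 0 or _COMPLEMENT[query_seq[qe]] != ref_seq[rs - 1]:
                    break
                rs -= 1
            qe += 1
            added_tail += 1
    if target_q_start is not None:
        while qs > target_q_start:
            if sub.strand == "+":
                if rs <= 0 or query_seq[qs - 1] != ref_seq[rs - 1]:
                    break
                rs -= 1
            else:
                if re_ >= len(ref_seq) or _COMPLEMENT[query_seq[qs - 1]] != ref_seq[re_]:
                    break
                re_ += 1
            qs -= 1
            added_head += 1
    if not (added_head or added_tail):
        return sub
    # in oriented (cigar) order: original tail extensions sit at the head for
    # minus-strand parts and vice versa
    head_m = added_tail if sub.strand == "-" else added_head
    tail_m = added_head if sub.strand == "-" else added_tail
    if head_m:
        if runs and runs[0][1] == "M":
            runs[0] = (runs[0][0] + head_m, "M")
        else:
            runs.insert(0, (head_m, "M"))
    if tail_m:
        if runs and runs[-1][1] == "M":
            runs[-1] = (runs[-1][0] + tail_m, "M")
        else:
            runs.append((tail_m, "M"))
    cigar = "".join(f"{n}{op}" for n, op in runs)
    return replace(
        sub,
        query_interval=(qs, qe),
        reference_interval=(rs, re_),
        cigar=cigar,
        score=score_from_cigar(cigar, scheme),
    )


def cigar_identity_over_reference(
    sub: Subalignment, ref_interval: tuple[int, int]
) -> tuple[int, int, int]:
    """(matches, aligned_columns, covered_ref_positions) of the subalignment
    restricted to a reference interval (used for TIR integrity checks)."""
    lo, hi = ref_interval
    r = sub.r_start
    matches = cols = covered = 0
    for length, op in parse_cigar(sub.cigar):
        if op in "MX":
            for t in range(length):
                if lo <= r + t < hi:
                    cols += 1
                    covered += 1
                    if op == "M":
                        matches += 1
            r += length
        elif op == "D":
            for t in range(length):
                if lo <= r + t < hi:
                    cols += 1
            r += length
        # I consumes query only
    return matches, cols, covered


def cigar_identity_over_query(
    sub: Subalignment, query_interval: tuple[int, int]
) -> tuple[int, int, int]:
    """Same as above but restricted to *original* query positions."""
    lo, hi = query_interval
    ostart, _ = sub.oriented_query_interval()
    n = sub.query_length
    oq = ostart
    matches = cols = covered = 0
    for length, op in parse_cigar(sub.cigar):
        if op in "MXI":
            for t in range(length):
                pos = oq + t if sub.strand == "+" else n - 1 - (oq + t)
                if lo <= pos < hi:
                    cols += 1
                    if op != "I":
                        covered += 1
                        if op == "M":
                            matches += 1
            oq += length
    return matches, cols, covered
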