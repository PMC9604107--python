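"""Insertion calls (TGN, orientation, TSD) derived from junction composites.

The TGN (terminal genomic nucleotide) is the first genome-derived nucleotide
adjacent, on the query, to a transposon nucleotide at the genome-transposon
junction; it is the reported insertion coordinate (1-based).  The TSD (target
site duplication) is the short genomic motif duplicated on both sides of an
insertion; reading it from the genome side of the junction recovers one copy,
and the 5' and 3' junction queries of the same insertion must agree on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .compose import CompositeAlignment
from .errors import NotCallableError, TsdAlertError
from .index import Parameters, ReferenceDB

log = logging.getLogger(__name__)


@dataclass
class InsertionCall:
    """One mapped transposon insertion.

    ``genome_end`` records at which end of the genome part's reference
    interval the TGN sits ("right" = highest coordinate, "left" = lowest);
    it determines on which side of the TGN the duplicated motif is read.
    """

    transposon: str
    reference_id: str
    tgn: int  # 1-based genomic coordinate
    orientation: str  # "1" (genome part on plus strand) or "2"
    side: str  # "5'" or "3'": which transposon end forms the junction
    score: int
    source_query: str
    genome_end: str = "right"
    tsd: str = ""


def call_insertion(
    c: CompositeAlignment,
    gd: ReferenceDB,
    params: Parameters = Parameters(),
    td: Optional[ReferenceDB] = None,
) -> InsertionCall:
    """Derive the insertion call from a junction composite.

    The junction pair is the adjacent (genome, transposon) pair of parts with
    the highest combined score.  Orientation is 1 when the genome part aligns
    on the plus strand of the reference, 2 otherwise; the side is 5' or 3'
    according to which end region of the transposon reference the transposon
    part occupies.
    """
    if c.classification != "junction":
        raise NotCallableError(
            f"composite is {c.classification}, not a junction alignment"
        )
    pairs = [
        (a, b) for a, b in zip(c.parts, c.parts[1:])
        if {a.origin, b.origin} == {"genome", "transposon"}
    ]
    if not pairs:
        raise NotCallableError("no adjacent genome-transposon pair in composite")
    a, b = max(pairs, key=lambda ab: ab[0].score + ab[1].score)
    gp = a if a.origin == "genome" else b
    tp = b if gp is a else a
    genome_first = gp.q_start < tp.q_start
    if genome_first:
        # junction base is the last genome base before the transposon part
        if gp.strand == "+":
            tgn0, genome_end = gp.r_end - 1, "right"
        else:
            tgn0, genome_end = gp.r_start, "left"
    else:
        if gp.strand == "+":
            tgn0, genome_end = gp.r_start, "left"
        else:
            tgn0, genome_end = gp.r_end - 1, "right"
    # side: which end region of the transposon reference the part occupies
    if td is not None and tp.reference_id in td:
        ref_len = len(td.get(tp.reference_id))
    else:
        ref_len = tp.r_end  # without the TD, only the 5' distance is known
    side = "5'" if tp.r_start <= (ref_len - tp.r_end) else "3'"
    return InsertionCall(
        transposon=tp.reference_id,
        reference_id=gp.reference_id,
        tgn=tgn0 + 1,
        orientation="1" if gp.strand == "+" else "2",
        side=side,
        score=c.total_score,
        source_query=gp.query_id,
        genome_end=genome_end,
    )


def extract_tsd(call: InsertionCall, gd: ReferenceDB, length: Optional[int] = None,
                params: Parameters = Parameters()) -> str:
    """The duplicated motif copy adjacent to the transposon, read from the
    genome side of the junction.

    When the TGN sits at the high-coordinate end of the genome part, the motif
    is the ``length`` genomic nucleotides ending at the TGN; at the
    low-coordinate end it starts at the TGN.  Raises :class:`TsdAlertError`
    when the TGN is closer than ``length`` to the reference end.
    """
    if length is None:
        length = params.tsd_flank_length
    if length < 1:
        raise ValueError("TSD length must be >= 1")
    seq = gd.get(call.reference_id).seq
    tgn0 = call.tgn - 1
    if call.genome_end == "right":
        start, end = tgn0 - length + 1, tgn0 + 1
    else:
        start, end = tgn0, tgn0 + length
    if start < 0 or end > len(seq):
        raise TsdAlertError(
            f"ALERT: TSD window [{start}, {end}) outside reference "
            f"{call.reference_id!r} (length {len(seq)})"
        )
    return seq[start:end]


def verify_tsd_pair(call5: InsertionCall, call3: InsertionCall, gd: ReferenceDB,
                    length: Optional[int] = None,
                    params: Parameters = Parameters()) -> tuple[bool, str, str]:
    """Compare the TSD read from the 5' and 3' junction calls of one insertion.

    The two strings are expected to be identical for a clean target site
    duplication; disagreement (possible with sequencing noise) is reported
    with both strings rather than silently merged.
    """
    t5 = extract_tsd(call5, gd, length, params)
    t3 = extract_tsd(call3, gd, length, params)
    if t5 != t3:
        log.warning("TSD mismatch between 5' and 3' calls: %s vs %s", t5, t3)
    return t5 == t3, t5, t3
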