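"""Junction-query machinery and sequence utilities around insertion sites.

A junction query (JQ) is a transposon terminal segment plus genomic flank,
extracted from a contig around a detected transposon remnant; mapping JQs
against a canonical reference genome is what localizes insertions.  The
terminal segments are the first and last ``crop_len`` (default 60) nucleotides
of the transposon (Q5'/Q3'), chosen long enough to contain the TIR plus
enough internal sequence to tell the two ends apart.

This module also provides flank extraction at arbitrary coordinates, and the
IUPAC ambiguity-code consensus over equal-length sequence sets (TSD lists,
flank lists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .dna import revcomp
from .errors import ConsensusError, CoordinateError, FormatError
from .index import ReferenceDB
from .io import SequenceRecord

log = logging.getLogger(__name__)

DEFAULT_CROP = 60
DEFAULT_FLANK = 3000
DEFAULT_TAIL = 2000

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class JunctionQuery:
    """A transposon terminal segment plus contig flank, ready for mapping.

    ``alert`` marks remnants sitting so close to a contig end that the flank
    was truncated; the header carries a verbatim "ALERT" string as well.
    ``joined`` marks the three-part join emitted for single-TIR remnants.
    """

    id: str
    seq: str
    side: str  # "5'" or "3'"
    source_contig: str
    alert: bool = False
    joined: bool = False

    def to_record(self) -> SequenceRecord:
        desc = []
        if self.alert:
            desc.append("ALERT")
        if self.joined:
            desc.append("joined_single_TIR")
        return SequenceRecord(id=self.id, seq=self.seq, description=" ".join(desc))


@dataclass(frozen=True)
class RemnantHit:
    """One filtered terminal-query hit on a contig (a WF1 table row)."""

    contig_id: str
    side: str  # "5'" or "3'"
    start: int  # 0-based, on the contig
    end: int
    strand: str
    score: int


@dataclass
class ConsensusResult:
    consensus: str
    threshold: float
    n_sequences: int
    #: per-position sets of qualifying nucleotides; empty when no base reached
    #: the threshold (printed as N in the consensus string)
    position_sets: tuple[frozenset, ...] = ()


def crop_terminal_queries(
    nt: SequenceRecord, crop_len: int = DEFAULT_CROP
) -> tuple[SequenceRecord, SequenceRecord]:
    """First and last ``crop_len`` nucleotides of a transposon (Q5', Q3').

    Header ids end in TIR5/TIR3, the convention the extraction step keys on.
    """
    if len(nt) < 2 * crop_len:
        raise CoordinateError(
            f"transposon {nt.id!r} ({len(nt)} nt) shorter than twice the crop length {crop_len}"
        )
    q5 = SequenceRecord(id=f"{nt.id}_TIR5", seq=nt.seq[:crop_len])
    q3 = SequenceRecord(id=f"{nt.id}_TIR3", seq=nt.seq[-crop_len:])
    return q5, q3


def _window(contig: str, start: int, end: int) -> tuple[str, bool]:
    """Clamp [start, end) to the contig; the flag reports truncation."""
    lo, hi = max(0, start), min(len(contig), end)
    return contig[lo:hi], (lo != start or hi != end)


def extract_junction_queries(
    contigs: Sequence[SequenceRecord],
    hits: Iterable[RemnantHit],
    flank: int = DEFAULT_FLANK,
    nt_len: Optional[int] = None,
    tail: int = DEFAULT_TAIL,
    crop_len: int = DEFAULT_CROP,
    pair_slack: int = 1000,
) -> list[JunctionQuery]:
    """Build junction queries from terminal-query hits on contigs.

    For a remnant with both TIRs, the 5' JQ is the upstream contig flank plus
    the Q5' region and the 3' JQ is the Q3' region plus the downstream flank
    (upstream/downstream in transposon orientation: minus-strand windows are
    reverse-complemented so every JQ reads flank->TIR5 or TIR3->flank).  A
    remnant with a single TIR additionally gets the paired JQ built by joining
    the present terminal region, a window of one transposon length, and
    ``tail`` further nucleotides, so the lost junction can still be crossed.
    Truncation by a contig end sets the ALERT flag instead of failing.
    """
    by_id = {c.id: c for c in contigs}
    hits = list(hits)
    for h in hits:
        if h.contig_id not in by_id:
            raise FormatError(f"hit refers to unknown contig {h.contig_id!r}")
        contig = by_id[h.contig_id].seq
        if not (0 <= h.start < h.end <= len(contig)):
            raise CoordinateError(
                f"hit coordinates [{h.start}, {h.end}) outside contig {h.contig_id!r}"
            )

    paired: dict[int, bool] = {}
    if nt_len is not None:
        for i, a in enumerate(hits):
            for j, b in enumerate(hits):
                if i == j or a.contig_id != b.contig_id or a.strand != b.strand:
                    continue
                if {a.side, b.side} != {"5'", "3'"}:
                    continue
                five, three = (a, b) if a.side == "5'" else (b, a)
                # on the plus strand the 3' TIR lies downstream of the 5' one
                delta = (three.start - five.start) if a.strand == "+" else (five.start - three.start)
                if 0 < delta <= nt_len + pair_slack:
                    paired[i] = paired[j] = True

    out: list[JunctionQuery] = []
    counters: dict[tuple[str, str], int] = {}
    for i, h in enumerate(hits):
        contig = by_id[h.contig_id].seq
        key = (h.contig_id, h.side)
        counters[key] = counters.get(key, 0) + 1
        tag = f"_{counters[key]}" if counters[key] > 1 else ""
        label = "JQ5" if h.side == "5'" else "JQ3"

        if h.side == "5'":
            if h.strand == "+":
                seq, trunc = _window(contig, h.start - flank, h.end)
            else:
                seq, trunc = _window(contig, h.start, h.end + flank)
                seq = revcomp(seq)
        else:
            if h.strand == "+":
                seq, trunc = _window(contig, h.start, h.end + flank)
            else:
                seq, trunc = _window(contig, h.start - flank, h.end)
                seq = revcomp(seq)
        out.append(JunctionQuery(
            id=f"{h.contig_id}_{label}{tag}" + ("_ALERT" if trunc else ""),
            seq=seq, side=h.side, source_contig=h.contig_id, alert=trunc,
        ))

        if nt_len is not None and not paired.get(i, False):
            # single-TIR remnant: join terminal region + one NT length + tail
            span = h.end - h.start + nt_len + tail
            if h.side == "5'":
                mate_label = "JQ3"
                if h.strand == "+":
                    seq, trunc = _window(contig, h.start, h.start + span)
                else:
                    seq, trunc = _window(contig, h.end - span, h.end)
                    seq = revcomp(seq)
            else:
                mate_label = "JQ5"
                if h.strand == "+":
                    seq, trunc = _window(contig, h.end - span, h.end)
                else:
                    seq, trunc = _window(contig, h.start, h.start + span)
                    seq = revcomp(seq)
            out.append(JunctionQuery(
                id=f"{h.contig_id}_{mate_label}{tag}_joined" + ("_ALERT" if trunc else ""),
                seq=seq, side="3'" if mate_label == "JQ3" else "5'",
                source_contig=h.contig_id, alert=trunc, joined=True,
            ))
    return out


def hits_to_table(hits: Iterable[RemnantHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.contig_id, h.side, h.start, h.end, h.strand, h.score) for h in hits],
        columns=["contig_id", "side", "start", "end", "strand", "score"],
    )


def hits_from_table(df: pd.DataFrame) -> list[RemnantHit]:
    return [
        RemnantHit(str(r.contig_id), str(r.side), int(r.start), int(r.end),
                   str(r.strand), int(r.score))
        for r in df.itertuples(index=False)
    ]


def flanking_at_coordinate(
    gd: ReferenceDB, reference_id: str, coordinate: int, half_len: int = 8
) -> SequenceRecord:
    """Two local subsequences of ``half_len`` nt centered on a 1-based
    coordinate, returned as one contiguous record of 2*half_len nucleotides;
    the coordinate itself falls in the right-hand subsequence."""
    if half_len < 1:
        raise ValueError("half_len must be >= 1")
    seq = gd.get(reference_id).seq
    pos = coordinate - 1
    if not 0 <= pos < len(seq):
        raise CoordinateError(
            f"coordinate {coordinate} outside reference {reference_id!r}"
        )
    start, end = pos - half_len, pos + half_len
    if start < 0 or end > len(seq):
        raise CoordinateError(
            f"coordinate {coordinate} within {half_len} nt of an end of {reference_id!r}"
        )
    return SequenceRecord(
        id=f"{reference_id}_{coordinate}_flank{2 * half_len}",
        seq=seq[start:end],
    )


def compute_consensus(
    seqs: Sequence[str], threshold: float = 20.0
) -> ConsensusResult:
    """Per-position IUPAC consensus of equal-length sequences.

    A nucleotide enters the symbol set of a position when it occurs in at
    least ``threshold`` percent of the sequences informative at that position
    (inclusive comparison; N is excluded from the counts).  At a 100%
    threshold, non-identical columns admit no consensus at all and raise; at
    lower thresholds a position where every base stays below the threshold
    degrades to N with a warning.
    """
    if len(seqs) < 2:
        raise ConsensusError("need at least 2 sequences for a consensus")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ConsensusError("consensus requires equal-length sequences")
    seqs = [s.upper() for s in seqs]
    out = []
    sets: list[frozenset] = []
    for pos in range(length):
        counts = {b: 0 for b in "ACGT"}
        for s in seqs:
            c = s[pos]
            if c in counts:
                counts[c] += 1
            elif c != "N":
                raise ConsensusError(f"invalid character {c!r} at position {pos}")
        informative = sum(counts.values())
        if informative == 0:
            out.append("N")
            sets.append(frozenset())
            continue
        # inclusive threshold, compared exactly on rationals
        chosen = frozenset(
            b for b, n in counts.items() if n > 0 and n * 100 >= threshold * informative
        )
        if not chosen:
            if threshold >= 100:
                raise ConsensusError(
                    f"position {pos} not invariant: no consensus at a 100% threshold"
                )
            log.warning("position %d: every nucleotide below %s%%, emitting N",
                        pos, threshold)
            out.append("N")
            sets.append(frozenset())
            continue
        out.append(IUPAC[chosen])
        sets.append(chosen)
    return ConsensusResult("".join(out), threshold, len(seqs), tuple(sets))
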