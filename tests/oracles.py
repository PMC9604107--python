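"""Independent reference implementations used only to check the package.

These deliberately share no code with ntmap: the local aligner is a textbook
full-matrix Smith-Waterman/Gotoh (every cell, no seeding, no band), the
composer oracle enumerates every subset of parts and filters it against the
composition rules, and the consensus oracle works directly on per-position
frequency tables.
"""

from __future__ import annotations

import itertools

import numba
import numpy as np


@numba.njit(cache=False)
def _sw_gotoh(q, r, match, mismatch, gap_open, gap_extend):
    n = q.shape[0]
    m = r.shape[0]
    NEGI = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEGI, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEGI, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open
            if E[i, j - 1] + gap_extend > e:
                e = E[i, j - 1] + gap_extend
            E[i, j] = e
            f = H[i - 1, j] + gap_open
            if F[i - 1, j] + gap_extend > f:
                f = F[i - 1, j] + gap_extend
            F[i, j] = f
            s = match if q[i - 1] == r[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def sw_score(q: str, r: str, match=1, mismatch=-1, gap_open=-2, gap_extend=-1) -> int:
    """Best local alignment score by exhaustive DP."""
    qa = np.frombuffer(q.encode(), dtype=np.uint8).astype(np.int64)
    ra = np.frombuffer(r.encode(), dtype=np.uint8).astype(np.int64)
    return int(_sw_gotoh(qa, ra, match, mismatch, gap_open, gap_extend))


def enumerate_composites(subs, max_genomic_gap=200):
    """All rule-respecting ordered part subsets with their total scores.

    Parts must be non-overlapping on the query; consecutive genome-genome
    pairs need the same reference and strand, query order consistent with
    reference order, and a reference gap in [0, max_genomic_gap].  Returns a
    list of (score, parts-tuple).
    """
    out = []
    n = len(subs)
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            parts = sorted((subs[i] for i in combo), key=lambda s: s.q_start)
            ok = True
            for a, b in zip(parts, parts[1:]):
                if b.q_start < a.q_end:
                    ok = False
                    break
                if a.origin == "genome" and b.origin == "genome":
                    if a.reference_id != b.reference_id or a.strand != b.strand:
                        ok = False
                        break
                    if a.strand == "+":
                        gap = b.r_start - a.r_end
                    else:
                        gap = a.r_start - b.r_end
                    if gap < 0 or gap > max_genomic_gap:
                        ok = False
                        break
            if ok:
                out.append((sum(p.score for p in parts), tuple(parts)))
    return out


_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def consensus_by_frequency(seqs, threshold):
    """Per-position frequency-table consensus (N if nothing qualifies)."""
    length = len(seqs[0])
    cols = []
    for pos in range(length):
        column = [s[pos] for s in seqs if s[pos] != "N"]
        total = len(column)
        chosen = frozenset(
            b for b in "ACGT"
            if total and column.count(b) and 100.0 * column.count(b) / total >= threshold - 1e-12
        )
        cols.append(_IUPAC[chosen] if chosen else "N")
    return "".join(cols)
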