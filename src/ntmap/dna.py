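"""Small DNA-string helpers shared across the package.

Sequences are plain upper-case Python strings over the alphabet {A,C,G,T,N};
the aligner additionally works on uint8 views of the ASCII bytes.
"""

from __future__ import annotations

import numpy as np

ALPHABET = frozenset("ACGTN")
N_CODE = ord("N")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def normalize(seq: str) -> tuple[str, int]:
    """Upper-case *seq* and replace anything outside {A,C,G,T,N} with N.

    Returns the cleaned sequence and the number of replaced characters.
    """
    s = seq.upper()
    if set(s) <= ALPHABET:
        return s, 0
    out = []
    replaced = 0
    for c in s:
        if c in ALPHABET:
            out.append(c)
        else:
            out.append("N")
            replaced += 1
    return "".join(out), replaced


def encode(seq: str) -> np.ndarray:
    """ASCII byte view of a sequence, suitable for the alignment kernels."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
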