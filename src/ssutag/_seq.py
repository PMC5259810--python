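"""Nucleotide encoding helpers shared across the package.

Bases are encoded as small integers: A=0, C=1, G=2, T=3, N=4 (any
ambiguity code collapses to N), gap ('-' or '.') = 5.  The numeric
encoding lets the scanner and profile builder work on numpy arrays.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T, N, GAP = 0, 1, 2, 3, 4, 5

ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    ENCODE[ord(_b)] = _i
    ENCODE[ord(_b.lower())] = _i
ENCODE[ord("U")] = T
ENCODE[ord("u")] = T
ENCODE[ord("-")] = GAP
ENCODE[ord(".")] = GAP

_DECODE = np.frombuffer(b"ACGTN-", dtype=np.uint8)

# complement; N and gap map to themselves
COMP = np.array([T, G, C, A, N, GAP], dtype=np.uint8)

# IUPAC degenerate codes
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
IUPAC_BASES = {v: frozenset(k) for k, v in IUPAC.items()}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array."""
    return ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case string."""
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMP[codes][::-1]


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (keeps N)."""
    return decode(revcomp_codes(encode(seq)))
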