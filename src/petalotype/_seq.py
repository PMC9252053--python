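"""Small DNA-string helpers shared across modules.

Sequences are plain upper-case Python strings over the alphabet ACGTN.
Performance-critical code converts to ``numpy.uint8`` arrays of ASCII
codes; the helpers here centralise those conversions so every module
agrees on the encoding.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: ASCII codes for the four bases, index 0..3 = A, C, G, T.
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Lookup table ASCII -> base index (A=0 C=1 G=2 T=3, everything else 255).
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """ASCII byte view of a sequence (no copy of semantics, uint8)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def encode_bases(seq: str) -> np.ndarray:
    """Map a sequence to base indices 0..3; non-ACGT become 255."""
    return _CODE[seq_to_array(seq)]


def random_dna(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    """Random DNA with the requested expected GC content.

    Bases are drawn i.i.d. with P(G) = P(C) = gc/2 and
    P(A) = P(T) = (1 - gc)/2.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    draws = rng.choice(4, size=length, p=[at, gc, gc, at])
    return array_to_seq(BASES[draws])


def gc_content(seq: str) -> float:
    """Observed G+C fraction of a sequence (N excluded from denominator)."""
    arr = seq_to_array(seq)
    acgt = np.isin(arr, BASES)
    n = int(acgt.sum())
    if n == 0:
        raise ValueError("sequence contains no ACGT bases")
    gc = int(np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)).sum())
    return gc / n
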