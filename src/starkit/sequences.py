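"""RNA sequence primitives.

All starkit operations work on plain Python strings over the RNA alphabet
{A, C, G, U}, read 5'→3'.  :func:`normalize` is the single entry point that
turns user input (possibly lowercase, possibly DNA-style with T) into that
canonical form; everything downstream assumes normalized input.
"""

from __future__ import annotations

import numpy as np

from .errors import AlphabetError, InputError

RNA_ALPHABET = frozenset("ACGU")
PURINES = frozenset("AG")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Integer encoding used by the folding kernels: A=0, C=1, G=2, U=3.
_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def normalize(seq: str) -> str:
    """Return ``seq`` uppercased with T→U, validated against {A,C,G,U}.

    Raises
    ------
    AlphabetError
        If any symbol remains outside the RNA alphabet.
    """
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"illegal symbol(s) {sorted(bad)!r} in sequence (expected A/C/G/U)"
        )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a normalized RNA sequence (an involution)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C residues; 0.0 for the empty sequence."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length sequences."""
    if len(a) != len(b):
        raise InputError(f"hamming distance needs equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-nucleotide run (0 for empty)."""
    best = run = 0
    prev = None
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


def encode(seq: str) -> np.ndarray:
    """Encode a normalized sequence as an int8 array (A=0, C=1, G=2, U=3)."""
    if not seq:
        raise InputError("empty sequence")
    return np.fromiter((_ENCODE[c] for c in seq), dtype=np.int8, count=len(seq))
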