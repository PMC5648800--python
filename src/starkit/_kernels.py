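"""Numba-compiled dynamic-programming kernels for the folding engine.

The kernels operate on integer-encoded sequences (A=0, C=1, G=2, U=3) and a
4x4 pair-score table.  A strand break index ``brk`` >= 0 marks the first
position of the second strand in a two-strand complex; pairs spanning the
break (i < brk <= j) are exempt from the minimum-loop constraint.  ``mask``
is an n x n uint8 matrix of forbidden pairs (1 = forbidden).

If numba is unavailable the kernels run as plain Python — identical results,
just slower.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _pair_ok(enc, score4, min_loop, brk, mask, i, j):
    if score4[enc[i], enc[j]] <= 0:
        return False
    if mask[i, j]:
        return False
    if brk >= 0 and i < brk <= j:
        return True
    return j - i - 1 >= min_loop


@njit(cache=True)
def fill_mfe(enc, score4, min_loop, brk, mask):
    """Maximum-score pseudoknot-free pairing matrix.

    M[i, j] = best total pair score on the inclusive interval [i, j].
    Recursion: position i is unpaired, or pairs with some k in (i, j].
    """
    n = enc.shape[0]
    M = np.zeros((n, n), dtype=np.int64)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1, j]
            for k in range(i + 1, j + 1):
                if not _pair_ok(enc, score4, min_loop, brk, mask, i, k):
                    continue
                v = score4[enc[i], enc[k]]
                if k - i >= 2:
                    v += M[i + 1, k - 1]
                if k + 1 <= j:
                    v += M[k + 1, j]
                if v > best:
                    best = v
            M[i, j] = best
    return M


@njit(cache=True)
def traceback_mfe(M, enc, score4, min_loop, brk, mask):
    """Deterministic traceback of one optimal structure.

    Tie-break rule: at every interval, pairing the leftmost position is
    preferred over leaving it unpaired, and among co-optimal partners the
    smallest j wins.  This selects the co-optimal structure whose sorted
    pair list is lexicographically smallest.
    """
    n = enc.shape[0]
    pairs = np.empty((n // 2 + 1, 2), dtype=np.int64)
    npairs = 0
    stack = np.empty((2 * n + 4, 2), dtype=np.int64)
    sp = 0
    stack[sp, 0] = 0
    stack[sp, 1] = n - 1
    sp += 1
    while sp > 0:
        sp -= 1
        i = stack[sp, 0]
        j = stack[sp, 1]
        if i >= j:
            continue
        target = M[i, j]
        found = False
        for k in range(i + 1, j + 1):
            if not _pair_ok(enc, score4, min_loop, brk, mask, i, k):
                continue
            v = score4[enc[i], enc[k]]
            if k - i >= 2:
                v += M[i + 1, k - 1]
            if k + 1 <= j:
                v += M[k + 1, j]
            if v == target:
                pairs[npairs, 0] = i
                pairs[npairs, 1] = k
                npairs += 1
                if k - i >= 2:
                    stack[sp, 0] = i + 1
                    stack[sp, 1] = k - 1
                    sp += 1
                if k + 1 <= j:
                    stack[sp, 0] = k + 1
                    stack[sp, 1] = j
                    sp += 1
                found = True
                break
        if not found:
            stack[sp, 0] = i + 1
            stack[sp, 1] = j
            sp += 1
    return pairs[:npairs]
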