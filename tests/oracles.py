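"""Independent test oracles.

These deliberately avoid the code paths they check: Boltzmann sums go
through the recursive enumerator (not the DP), the structure counter is
a separate recursion, and the maximum-clique oracle is a bitmask subset
sweep rather than Bron–Kerbosch.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np

from starkit.fold import EnergyModel, enumerate_structures, structure_score


def enumeration_oracle(
    seq_or_complex: Union[str, Tuple[str, str]], model: EnergyModel
):
    """(max score, pair-probability matrix, Z) by exhaustive enumeration."""
    if isinstance(seq_or_complex, tuple):
        seq = seq_or_complex[0] + seq_or_complex[1]
    else:
        seq = seq_or_complex
    structs = enumerate_structures(seq_or_complex, model)
    scores = [structure_score(s, seq, model) for s in structs]
    weights = [np.exp(sc / model.kT) for sc in scores]
    Z = float(sum(weights))
    n = len(seq)
    P = np.zeros((n, n))
    for s, w in zip(structs, weights):
        for i, j in s.pairs:
            P[i, j] += w / Z
    return max(scores), P + P.T, Z


def count_structures(seq: str, model: EnergyModel, brk: Optional[int] = None) -> int:
    """Count pseudoknot-free structures by an interval DP (not a generator)."""
    n = len(seq)
    idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    tab = model.score_table()

    def ok(i: int, j: int) -> bool:
        if tab[idx[seq[i]], idx[seq[j]]] <= 0:
            return False
        if brk is not None and i < brk <= j:
            return True
        return j - i - 1 >= model.min_loop

    memo: dict = {}

    def count(i: int, j: int) -> int:
        if i >= j:
            return 1
        key = (i, j)
        if key in memo:
            return memo[key]
        total = count(i + 1, j)
        for k in range(i + 1, j + 1):
            if ok(i, k):
                total += count(i + 1, k - 1) * count(k + 1, j)
        memo[key] = total
        return total

    return count(0, n - 1)


def max_clique_bruteforce(orth: np.ndarray) -> Tuple[int, Tuple[int, ...]]:
    """(size, lexicographically smallest maximum clique) over all 2^n subsets.

    A subset-DP over bitmasks: a mask is a clique iff the mask without its
    lowest bit is a clique and the lowest bit's adjacency covers the rest.
    """
    n = orth.shape[0]
    adj = [0] * n
    for i in range(n):
        for j in range(n):
            if i != j and orth[i, j]:
                adj[i] |= 1 << j
    is_clique = np.zeros(1 << n, dtype=bool)
    is_clique[0] = True
    best_size, best_mask = 0, 0
    for mask in range(1, 1 << n):
        low = mask & -mask
        i = low.bit_length() - 1
        rest = mask ^ low
        if is_clique[rest] and (adj[i] & rest) == rest:
            is_clique[mask] = True
            size = bin(mask).count("1")
            if size > best_size:
                best_size, best_mask = size, mask
            elif size == best_size:
                # lexicographically smallest sorted index tuple
                cand = tuple(b for b in range(n) if (mask >> b) & 1)
                cur = tuple(b for b in range(n) if (best_mask >> b) & 1)
                if cand < cur:
                    best_mask = mask
    members = tuple(b for b in range(n) if (best_mask >> b) & 1)
    return best_size, members


def random_rna_string(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(("A", "C", "G", "U"), size=length))
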