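"""Self-contained nucleic-acid secondary-structure engine.

The engine scores a pseudoknot-free structure as the plain sum of its base
pair scores (GC=3, AU=2, GU=1 by default, all other dinucleotides forbidden)
with a minimum hairpin loop of 3 unpaired nucleotides.  There are no dangle,
stacking or multiloop terms, so every quantity the engine reports — the
maximum-score ("MFE") structure, the Boltzmann partition function, and base
pair probabilities — is exactly reproducible by exhaustive enumeration,
which :func:`enumerate_structures` provides as a built-in oracle for short
sequences.

Two-strand complexes are folded over the ordered concatenation ``a‖b`` with
an explicit strand break (no linker nucleotides); pairs spanning the break
are exempt from the minimum-loop constraint, and the number of such
intermolecular pairs is the crosstalk currency used throughout the toolkit.

Indexing is 0-based internally; dot-bracket strings (``(``, ``)``, ``.`` and
``&`` at the strand break) are the external structure representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Tuple, Union

import numpy as np

from ._kernels import fill_mfe, traceback_mfe
from .errors import InputError, ModelError, SizeError
from .sequences import encode, normalize

__all__ = [
    "EnergyModel",
    "SecondaryStructure",
    "FoldResult",
    "ComplexFoldResult",
    "fold_mfe",
    "pair_probabilities",
    "cofold",
    "enumerate_structures",
    "ENUMERATION_MAX_LEN",
]

#: Hard guard on exhaustive enumeration (structure count explodes beyond this).
ENUMERATION_MAX_LEN = 14


@dataclass(frozen=True)
class EnergyModel:
    """Integer pair-score model.

    Parameters
    ----------
    gc, au, gu
        Scores for G:C, A:U and G:U pairs (dimensionless, higher = more
        stable).  All other combinations are forbidden.
    min_loop
        Minimum number of unpaired nucleotides enclosed by an intramolecular
        pair.  Pairs spanning a strand break are exempt.
    kT
        Boltzmann scale, in score units, used by the partition function.
    """

    gc: int = 3
    au: int = 2
    gu: int = 1
    min_loop: int = 3
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ModelError("min_loop must be >= 0")
        if self.kT <= 0:
            raise ModelError("kT must be positive")

    def score_table(self) -> np.ndarray:
        """4x4 score table over the A=0,C=1,G=2,U=3 encoding (0 = forbidden)."""
        t = np.zeros((4, 4), dtype=np.int64)
        t[2, 1] = t[1, 2] = self.gc
        t[0, 3] = t[3, 0] = self.au
        t[2, 3] = t[3, 2] = self.gu
        return t

    def pair_score(self, x: str, y: str) -> int:
        """Score of pairing nucleotides ``x`` and ``y`` (0 if forbidden)."""
        idx = {"A": 0, "C": 1, "G": 2, "U": 3}
        return int(self.score_table()[idx[x], idx[y]])


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs over one or two strands.

    ``pairs`` are 0-based ``(i, j)`` tuples with ``i < j`` over the
    (possibly concatenated) sequence; ``strand_break``, when set, is the
    index of the first position of the second strand.
    """

    length: int
    pairs: Tuple[Tuple[int, int], ...]
    strand_break: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(sorted(tuple(p) for p in self.pairs)))
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise InputError(f"pair {(i, j)} out of range for length {self.length}")
            if i in seen or j in seen:
                raise InputError(f"position in pair {(i, j)} occurs in two pairs")
            seen.update((i, j))
        ps = self.pairs
        for a in range(len(ps)):
            i, j = ps[a]
            for k, l in ps[a + 1 :]:
                if i < k < j < l:
                    raise InputError(f"pseudoknot between pairs {(i, j)} and {(k, l)}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def inter_pairs(self) -> int:
        """Number of pairs spanning the strand break (0 if single-stranded)."""
        b = self.strand_break
        if b is None:
            return 0
        return sum(1 for i, j in self.pairs if i < b <= j)

    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for pair in self.pairs for p in pair)

    def to_dot_bracket(self) -> str:
        """Render as a dot-bracket string, with ``&`` at the strand break."""
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        if self.strand_break is not None:
            chars.insert(self.strand_break, "&")
        return "".join(chars)

    @classmethod
    def from_dot_bracket(cls, s: str) -> "SecondaryStructure":
        """Parse a dot-bracket string (inverse of :meth:`to_dot_bracket`)."""
        strand_break: Optional[int] = None
        if "&" in s:
            if s.count("&") > 1:
                raise InputError("at most one strand break '&' allowed")
            strand_break = s.index("&")
            s = s.replace("&", "")
        stack: list[int] = []
        pairs: list[Tuple[int, int]] = []
        for idx, c in enumerate(s):
            if c == "(":
                stack.append(idx)
            elif c == ")":
                if not stack:
                    raise InputError(f"unbalanced ')' at position {idx}")
                pairs.append((stack.pop(), idx))
            elif c != ".":
                raise InputError(f"illegal dot-bracket symbol {c!r}")
        if stack:
            raise InputError(f"unbalanced '(' at position {stack[-1]}")
        return cls(length=len(s), pairs=tuple(pairs), strand_break=strand_break)


@dataclass(frozen=True)
class FoldResult:
    """Result of folding a single strand."""

    sequence: str
    mfe_score: int
    structure: SecondaryStructure
    pair_prob: Optional[np.ndarray] = field(default=None, compare=False)
    partition: Optional[float] = field(default=None, compare=False)


@dataclass(frozen=True)
class ComplexFoldResult:
    """Result of cofolding an ordered two-strand complex ``a‖b``."""

    strand_a: str
    strand_b: str
    mfe_score: int
    structure: SecondaryStructure
    inter_pairs: int
    pair_prob: Optional[np.ndarray] = field(default=None, compare=False)
    partition: Optional[float] = field(default=None, compare=False)


def _prepare(seq: str) -> np.ndarray:
    s = normalize(seq)
    if not s:
        raise InputError("empty sequence")
    return encode(s)


def _mask_matrix(n: int, forbidden_pairs) -> np.ndarray:
    mask = np.zeros((n, n), dtype=np.uint8)
    if forbidden_pairs:
        for i, j in forbidden_pairs:
            if not (0 <= i < n and 0 <= j < n):
                raise InputError(f"forbidden pair {(i, j)} out of range")
            mask[i, j] = mask[j, i] = 1
    return mask


def _run_mfe(enc: np.ndarray, model: EnergyModel, brk: int, mask: np.ndarray):
    score4 = model.score_table()
    M = fill_mfe(enc, score4, model.min_loop, brk, mask)
    pairs = traceback_mfe(M, enc, score4, model.min_loop, brk, mask)
    n = enc.shape[0]
    score = int(M[0, n - 1]) if n >= 2 else 0
    return score, tuple((int(i), int(j)) for i, j in pairs)


def fold_mfe(
    seq: str,
    model: EnergyModel = EnergyModel(),
    forbidden_pairs: Optional[Sequence[Tuple[int, int]]] = None,
) -> FoldResult:
    """Maximum-score pseudoknot-free structure of a single strand.

    The returned score is the global optimum under the model; the structure
    is the deterministic leftmost-pair traceback (see
    :func:`starkit._kernels.traceback_mfe` for the tie-break rule).
    ``forbidden_pairs`` optionally masks individual position pairs.
    """
    enc = _prepare(seq)
    mask = _mask_matrix(len(enc), forbidden_pairs)
    score, pairs = _run_mfe(enc, model, -1, mask)
    struct = SecondaryStructure(length=len(enc), pairs=pairs)
    return FoldResult(sequence=normalize(seq), mfe_score=score, structure=struct)


def cofold(
    a: str,
    b: str,
    model: EnergyModel = EnergyModel(),
    forbidden_pairs: Optional[Sequence[Tuple[int, int]]] = None,
    probabilities: bool = False,
) -> ComplexFoldResult:
    """Fold the ordered concatenation ``a‖b`` with a strand break.

    Pairs spanning the break are exempt from the minimum-loop constraint
    and counted as ``inter_pairs``.  With ``probabilities=True`` the base
    pair probability matrix of the complex ensemble is also computed.
    """
    na, nb = normalize(a), normalize(b)
    if not na or not nb:
        raise InputError("empty sequence")
    enc = encode(na + nb)
    brk = len(na)
    mask = _mask_matrix(len(enc), forbidden_pairs)
    score, pairs = _run_mfe(enc, model, brk, mask)
    struct = SecondaryStructure(length=len(enc), pairs=pairs, strand_break=brk)
    prob = Z = None
    if probabilities:
        prob, Z = _pair_prob_matrix(enc, model, brk, mask)
    return ComplexFoldResult(
        strand_a=na,
        strand_b=nb,
        mfe_score=score,
        structure=struct,
        inter_pairs=struct.inter_pairs(),
        pair_prob=prob,
        partition=Z,
    )


# ---------------------------------------------------------------------------
# Partition function (inside/outside over the pair-score ensemble)
# ---------------------------------------------------------------------------

def _weight_matrix(enc, model: EnergyModel, brk: int, mask: np.ndarray) -> np.ndarray:
    """Boltzmann factor q[i, j] = exp(score(i,j)/kT) for allowed pairs, else 0."""
    n = enc.shape[0]
    score4 = model.score_table()
    q = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = score4[enc[i], enc[j]]
            if s <= 0 or mask[i, j]:
                continue
            spans = brk >= 0 and i < brk <= j
            if spans or j - i - 1 >= model.min_loop:
                q[i, j] = np.exp(s / model.kT)
    return q


def _inside(q: np.ndarray) -> np.ndarray:
    """Half-open inside matrix: E[a, b] = partition function over [a, b).

    Decomposition on the last position j = b-1: either unpaired, or paired
    with some k in [a, j).  Includes the empty structure, so E >= 1.
    """
    n = q.shape[0]
    E = np.zeros((n + 1, n + 1))
    for a in range(n + 1):
        E[a, a] = 1.0
    for j in range(n):
        for i in range(j, -1, -1):
            total = E[i, j]  # j unpaired
            if j > i:
                ks = np.arange(i, j)
                total += np.sum(E[i, ks] * q[ks, j] * E[ks + 1, j])
            E[i, j + 1] = total
    return E


def _pair_prob_matrix(enc, model: EnergyModel, brk: int, mask: np.ndarray):
    """Exact base pair probabilities by inside/outside recursion.

    p(i,j) = q(i,j) * E[i+1, j] * O[i, j] / Z, where O[i, j] sums the
    Boltzmann weight of everything outside the pair (i, j).  O is built
    outermost-first: the top-level term E[0,i]*E[j+1,n] plus, for every
    directly-enclosing pair (h, l), q(h,l)*O[h,l] times the two flanking
    inside segments.
    """
    n = enc.shape[0]
    q = _weight_matrix(enc, model, brk, mask)
    E = _inside(q)
    Z = E[0, n]
    if not np.isfinite(Z):
        raise ModelError("partition function overflow; increase kT")
    O = np.zeros((n, n))
    idx = np.nonzero(q)
    order = np.argsort(idx[0] - idx[1])  # decreasing span first
    hs, ls = idx[0][order], idx[1][order]
    for i, j in zip(*np.nonzero(q)):
        O[i, j] = E[0, i] * E[j + 1, n]
    for h, l in zip(hs, ls):
        w = q[h, l] * O[h, l]
        if w == 0.0 or l - h < 2:
            continue
        iv = np.arange(h + 1, l)
        # E[h+1, i] spans (h, i); E[j+1, l] spans (j, l)
        O[np.ix_(iv, iv)] += w * np.outer(E[h + 1, iv], E[iv + 1, l])
    inner = np.zeros((n, n))
    for i in range(n):
        inner[i, i + 1 :] = E[i + 1, i + 1 : n]
    P = q * inner * O / Z
    P = np.triu(P, 1)
    return P + P.T, float(Z)


def pair_probabilities(
    seq: str,
    model: EnergyModel = EnergyModel(),
    forbidden_pairs: Optional[Sequence[Tuple[int, int]]] = None,
) -> FoldResult:
    """MFE fold plus exact Boltzmann base pair probabilities.

    The ensemble is every pseudoknot-free structure (including the empty
    one) weighted by ``exp(score/kT)``; ``pair_prob[i, j]`` is the marginal
    probability that positions i and j pair.  Rows sum to at most 1.
    """
    enc = _prepare(seq)
    mask = _mask_matrix(len(enc), forbidden_pairs)
    score, pairs = _run_mfe(enc, model, -1, mask)
    prob, Z = _pair_prob_matrix(enc, model, -1, mask)
    struct = SecondaryStructure(length=len(enc), pairs=pairs)
    return FoldResult(
        sequence=normalize(seq),
        mfe_score=score,
        structure=struct,
        pair_prob=prob,
        partition=Z,
    )


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_structures(
    seq_or_complex: Union[str, Tuple[str, str]],
    model: EnergyModel = EnergyModel(),
) -> list[SecondaryStructure]:
    """Every valid pseudoknot-free structure, exactly once (incl. empty).

    Accepts a single sequence or an ``(a, b)`` tuple for a two-strand
    complex.  Refuses totals longer than :data:`ENUMERATION_MAX_LEN`.
    """
    if isinstance(seq_or_complex, tuple):
        a, b = (normalize(s) for s in seq_or_complex)
        if not a or not b:
            raise InputError("empty sequence")
        seq, brk = a + b, len(a)
    else:
        seq = normalize(seq_or_complex)
        if not seq:
            raise InputError("empty sequence")
        brk = None
    n = len(seq)
    if n > ENUMERATION_MAX_LEN:
        raise SizeError(
            f"enumeration limited to length {ENUMERATION_MAX_LEN}, got {n}"
        )
    enc = encode(seq)
    score4 = model.score_table()

    def ok(i: int, j: int) -> bool:
        if score4[enc[i], enc[j]] <= 0:
            return False
        if brk is not None and i < brk <= j:
            return True
        return j - i - 1 >= model.min_loop

    def gen(i: int, j: int) -> Iterator[Tuple[Tuple[int, int], ...]]:
        if i >= j:
            yield ()
            return
        # position i unpaired
        yield from gen(i + 1, j)
        for k in range(i + 1, j + 1):
            if not ok(i, k):
                continue
            for left in gen(i + 1, k - 1):
                for right in gen(k + 1, j):
                    yield ((i, k),) + left + right

    return [
        SecondaryStructure(length=n, pairs=p, strand_break=brk)
        for p in gen(0, n - 1)
    ]


def structure_score(struct: SecondaryStructure, seq: str, model: EnergyModel) -> int:
    """Sum of pair scores of ``struct`` over ``seq`` (oracle helper)."""
    s = normalize(seq)
    return sum(model.pair_score(s[i], s[j]) for i, j in struct.pairs)
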