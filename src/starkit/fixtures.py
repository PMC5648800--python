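"""Synthetic fixtures: random sequences, toy scaffolds, toy libraries and
crosstalk matrices with planted orthogonal subsets.

Everything here is a pure function of its seed/spec, so every module of
the toolkit can be exercised without any external data.  The toy scaffold
imitates only the *shape* of an intrinsic terminator (GC-rich stem,
short loop, poly-U tract); it is synthetic and does not reproduce any
published terminator sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .crosstalk import CrosstalkMatrix
from .design import DesignConfig, StarDesign, TerminatorScaffold, validate_constraints
from .errors import InputError
from .sequences import hamming

__all__ = [
    "FixtureSpec",
    "random_rna",
    "toy_scaffold",
    "toy_library",
    "planted_crosstalk",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic crosstalk fixture."""

    seed: int = 0
    n: int = 10
    length: int = 30
    gc: float = 0.5
    planted_k: Optional[int] = None
    cutoff: int = 13

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise InputError("gc must be in [0, 1]")
        if self.planted_k is not None and self.planted_k > self.n:
            raise InputError("planted_k must be <= n")
        if self.n < 1:
            raise InputError("n must be >= 1")


def random_rna(seed: int, length: int, gc: float = 0.5) -> str:
    """Seeded random RNA with expected GC fraction ``gc``."""
    if length < 1:
        raise InputError("length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise InputError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = (gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2)
    return "".join(rng.choice(("G", "C", "A", "U"), size=length, p=p))


def toy_scaffold(
    stem_len: int = 8,
    loop_len: int = 4,
    u_len: int = 8,
    seed: int = 0,
    stem_gc: float = 1.0,
) -> TerminatorScaffold:
    """Synthetic terminator scaffold: GC-biased stem, inert loop, poly-U tract.

    With the default ``stem_gc=1.0`` the stem is all G/C, so its hairpin
    strength is exactly ``3 * stem_len`` under the default model.  The
    loop is built from nucleotides that cannot pair (Watson–Crick or
    wobble) with any stem nucleotide, so it stays inert.
    """
    if stem_len < 3:
        raise InputError("stem_len must be >= 3")
    if loop_len < 3:
        raise InputError("loop_len must be >= 3 (minimum hairpin loop)")
    if u_len < 4:
        raise InputError("u_len must be >= 4")
    rng = np.random.default_rng(seed)
    p = (stem_gc / 2, stem_gc / 2, (1 - stem_gc) / 2, (1 - stem_gc) / 2)
    stem5 = "".join(rng.choice(("G", "C", "A", "U"), size=stem_len, p=p))
    # partners of each stem letter under WC + GU wobble
    partners = {"G": {"C", "U"}, "C": {"G"}, "A": {"U"}, "U": {"A", "G"}}
    banned = set().union(*(partners[c] for c in set(stem5)))
    loop_choices = [c for c in "ACGU" if c not in banned] or ["A"]
    loop = "".join(rng.choice(loop_choices, size=loop_len))
    return TerminatorScaffold(
        name=f"toy-s{stem_len}l{loop_len}u{u_len}-{seed}",
        stem5=stem5,
        loop=loop,
        u_tract="U" * u_len,
    )


def toy_library(
    n: int,
    scaffold: TerminatorScaffold,
    linear_len: int = 22,
    seed: int = 0,
    min_hamming: int = 0,
    cfg: Optional[DesignConfig] = None,
) -> List[StarDesign]:
    """Random constraint-clean designs (no annealing) for scale tests.

    Linear regions are rejection-sampled until they pass the composition
    constraints of ``cfg`` (GC window, homopolymer cap) and, when
    ``min_hamming`` > 0, the mutual diversity bound.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    cfg = cfg or DesignConfig(
        linear_len=linear_len, diversity_min_hamming=min(12, linear_len)
    )
    rng = np.random.default_rng(seed)
    out: List[StarDesign] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise InputError("toy_library rejection sampling budget exhausted")
        lin = "".join(rng.choice(("A", "C", "G", "U"), size=linear_len))
        if validate_constraints(lin, cfg):
            continue
        if min_hamming and any(hamming(lin, d.linear) < min_hamming for d in out):
            continue
        out.append(
            StarDesign(name=f"v{len(out) + 1:03d}", linear=lin, scaffold=scaffold)
        )
    return out


def planted_crosstalk(spec: FixtureSpec) -> Tuple[CrosstalkMatrix, Tuple[int, ...]]:
    """Counts matrix with a planted pairwise-orthogonal subset.

    Within the planted subset every off-diagonal count (both directions)
    is below ``spec.cutoff``; every other off-diagonal entry is at or
    above it; the diagonal carries a large cognate count.  Returns the
    matrix and the planted (sorted, 0-based) index subset.
    """
    k = spec.planted_k if spec.planted_k is not None else max(1, spec.n // 3)
    if k > spec.n:
        raise InputError("planted_k must be <= n")
    rng = np.random.default_rng(spec.seed)
    planted = tuple(sorted(rng.choice(spec.n, size=k, replace=False).tolist()))
    in_set = np.zeros(spec.n, dtype=bool)
    in_set[list(planted)] = True
    low = rng.integers(0, spec.cutoff, size=(spec.n, spec.n))
    high = rng.integers(spec.cutoff, spec.cutoff + 20, size=(spec.n, spec.n))
    both = np.outer(in_set, in_set)
    counts = np.where(both, low, high)
    np.fill_diagonal(counts, spec.cutoff + 25)
    names = tuple(f"v{i + 1:03d}" for i in range(spec.n))
    return (
        CrosstalkMatrix(names=names, counts=counts, metric="mfe_pairs"),
        planted,
    )
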