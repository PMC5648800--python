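"""All-vs-all crosstalk prediction and orthogonal-subset selection.

Every STAR in a library is cofolded against every target (cognate and
non-cognate), and the number of predicted intermolecular base pairs is
recorded in an n x n counts matrix.  Two variants are classified
orthogonal when both directions of predicted crosstalk fall strictly
below a cut-off (default 13 base pairs).  Orthogonal subsets are cliques
of the resulting orthogonality graph; exact selection enumerates maximal
cliques by Bron–Kerbosch with pivoting (via networkx) and returns the
lexicographically smallest maximum clique, while greedy selection grows a
maximal clique highest-degree-first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .design import StarDesign
from .errors import ContractError, InputError
from .fold import EnergyModel, cofold

__all__ = [
    "CrosstalkMatrix",
    "OrthogonalSet",
    "crosstalk_matrix",
    "classify_orthogonal",
    "select_orthogonal_subset",
    "verify_orthogonal_set",
    "DEFAULT_CUTOFF",
    "EXACT_MODE_MAX_N",
]

#: Default orthogonality cut-off: fewer than this many predicted
#: intermolecular base pairs (strict inequality) counts as orthogonal.
DEFAULT_CUTOFF = 13

#: Above this size the exact clique solver falls back to greedy.
EXACT_MODE_MAX_N = 200

#: Posterior-probability threshold for the ``prob_pairs`` metric.
PROB_PAIR_THRESHOLD = 0.5


@dataclass(frozen=True)
class CrosstalkMatrix:
    """n x n predicted intermolecular base-pair counts.

    ``counts[i, j]`` is STAR_i folded against target_j; the diagonal holds
    the cognate interactions.  ``n_evaluations`` records how many
    STAR-vs-target cofolds were performed to build the matrix.
    """

    names: Tuple[str, ...]
    counts: np.ndarray
    metric: str = "mfe_pairs"
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        n = len(self.names)
        if c.shape != (n, n):
            raise ContractError(f"counts shape {c.shape} != ({n}, {n})")
        if (c < 0).any():
            raise ContractError("negative crosstalk count")
        if self.metric not in ("mfe_pairs", "prob_pairs"):
            raise ContractError(f"unknown metric {self.metric!r}")

    @property
    def n(self) -> int:
        return len(self.names)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrosstalkMatrix):
            return NotImplemented
        return (
            self.names == other.names
            and self.metric == other.metric
            and np.array_equal(self.counts, other.counts)
        )


def _count_inter(star: str, target: str, model: EnergyModel, metric: str) -> int:
    if metric == "mfe_pairs":
        return cofold(star, target, model).inter_pairs
    res = cofold(star, target, model, probabilities=True)
    brk = len(star)
    P = res.pair_prob
    return int(np.sum(P[:brk, brk:] >= PROB_PAIR_THRESHOLD))


def crosstalk_matrix(
    designs: Sequence[StarDesign],
    model: EnergyModel = EnergyModel(),
    metric: str = "mfe_pairs",
) -> CrosstalkMatrix:
    """Cofold every STAR against every target (n² evaluations).

    ``metric="mfe_pairs"`` counts intermolecular pairs in the optimal
    complex structure; ``metric="prob_pairs"`` counts intermolecular pairs
    with posterior probability >= 0.5 in the complex ensemble.
    """
    if not designs:
        raise InputError("need at least one design")
    if metric not in ("mfe_pairs", "prob_pairs"):
        raise InputError(f"unknown metric {metric!r}")
    n = len(designs)
    counts = np.zeros((n, n), dtype=np.int64)
    stars = [d.star_seq for d in designs]
    targets = [d.target_seq for d in designs]
    n_eval = 0
    for i in range(n):
        for j in range(n):
            try:
                counts[i, j] = _count_inter(stars[i], targets[j], model, metric)
            except Exception as exc:  # annotate the offending pair
                raise type(exc)(
                    f"crosstalk evaluation failed for STAR {designs[i].name!r} "
                    f"vs target {designs[j].name!r}: {exc}"
                ) from exc
            n_eval += 1
    return CrosstalkMatrix(
        names=tuple(d.name for d in designs),
        counts=counts,
        metric=metric,
        n_evaluations=n_eval,
    )


def classify_orthogonal(m: CrosstalkMatrix, cutoff: int = DEFAULT_CUTOFF) -> np.ndarray:
    """Boolean orthogonality matrix under a strict cut-off.

    Entry (i, j), i != j, is True iff counts[i, j] < cutoff AND
    counts[j, i] < cutoff — crosstalk in either direction breaks
    independence.  The diagonal is False by convention.
    """
    if cutoff < 1:
        raise InputError("cutoff must be >= 1")
    below = m.counts < cutoff
    orth = below & below.T
    np.fill_diagonal(orth, False)
    return orth


@dataclass(frozen=True)
class OrthogonalSet:
    """A certified pairwise-orthogonal index subset (0-based indices)."""

    indices: Tuple[int, ...]
    cutoff: int
    mode: str = "exact"
    k_min: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(sorted(self.indices)))

    @property
    def size(self) -> int:
        return len(self.indices)

    @property
    def satisfied(self) -> bool:
        """Whether the requested minimum size (if any) was met."""
        return self.k_min is None or self.size >= self.k_min


def _check_orth(orth: np.ndarray) -> np.ndarray:
    orth = np.asarray(orth, dtype=bool)
    if orth.ndim != 2 or orth.shape[0] != orth.shape[1]:
        raise ContractError("orthogonality matrix must be square")
    if not np.array_equal(orth, orth.T):
        raise ContractError("orthogonality matrix must be symmetric")
    if orth.diagonal().any():
        raise ContractError("orthogonality matrix diagonal must be False")
    return orth


def _greedy_clique(orth: np.ndarray) -> List[int]:
    degrees = orth.sum(axis=1)
    order = sorted(range(orth.shape[0]), key=lambda i: (-degrees[i], i))
    chosen: List[int] = []
    for i in order:
        if all(orth[i, j] for j in chosen):
            chosen.append(i)
    return chosen


def select_orthogonal_subset(
    orth: np.ndarray,
    mode: str = "exact",
    k_min: Optional[int] = None,
    cutoff: int = DEFAULT_CUTOFF,
) -> OrthogonalSet:
    """Select a pairwise-orthogonal subset from a classification matrix.

    ``mode="exact"`` returns a maximum clique of the orthogonality graph
    (lexicographically smallest index set among maximum cliques);
    ``mode="greedy"`` returns a maximal clique by highest-degree-first
    insertion.  If ``k_min`` is given and unmet, the best set found is
    still returned with ``satisfied`` False.
    """
    orth = _check_orth(orth)
    n = orth.shape[0]
    if n == 0:
        raise InputError("empty orthogonality matrix")
    if mode not in ("exact", "greedy"):
        raise InputError(f"unknown mode {mode!r}")
    if mode == "exact" and n > EXACT_MODE_MAX_N:
        warnings.warn(
            f"exact clique search limited to n <= {EXACT_MODE_MAX_N}; "
            "falling back to greedy",
            stacklevel=2,
        )
        mode = "greedy"
    if mode == "greedy":
        chosen = _greedy_clique(orth)
    else:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(zip(*np.nonzero(np.triu(orth, 1))))
        best: Optional[Tuple[int, ...]] = None
        for clique in nx.find_cliques(g):
            cand = tuple(sorted(int(v) for v in clique))
            if best is None or len(cand) > len(best) or (
                len(cand) == len(best) and cand < best
            ):
                best = cand
        chosen = list(best or ())
    return OrthogonalSet(indices=tuple(chosen), cutoff=cutoff, mode=mode, k_min=k_min)


def verify_orthogonal_set(
    m: CrosstalkMatrix, s: OrthogonalSet, cutoff: Optional[int] = None
) -> bool:
    """Re-check a selected subset directly against the counts matrix."""
    cut = s.cutoff if cutoff is None else cutoff
    for a in s.indices:
        for b in s.indices:
            if a != b and m.counts[a, b] >= cut:
                return False
    return True
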