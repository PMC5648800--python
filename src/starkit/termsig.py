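"""Termination-efficiency design-principle metrics.

Intrinsic termination is favoured by a strong hairpin and a proximal
U-tract, and disfavoured by secondary structure and base stacking in the
region upstream of the hairpin.  This module quantifies those four
signals for a designed target RNA and combines them into a single
``rank_score`` used to triage candidates:

    rank = w_h * hairpin_strength / (gc_score * stem_len)
         + w_u * u_tract_frac
         - w_s * stacking_frac
         - w_p * linear_paired_frac

The stacking term is a surrogate: the fraction of adjacent purine–purine
dinucleotides in the linear region (purine stacking dominates
single-strand base stacking).  The rank is a relative triage heuristic,
not a calibrated predictor of measured termination efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import StarDesign, TerminatorScaffold
from .errors import InputError
from .fold import EnergyModel, fold_mfe
from .sequences import PURINES, normalize

__all__ = [
    "TerminationMetrics",
    "RankWeights",
    "linear_structure_fraction",
    "stacking_fraction",
    "hairpin_strength",
    "u_tract_score",
    "termination_rank",
    "U_TRACT_WINDOW",
]

#: Proximal U-tract window (nt immediately after the 3' stem arm).
U_TRACT_WINDOW = 8


@dataclass(frozen=True)
class RankWeights:
    """Non-negative weights of the termination rank terms."""

    w_hairpin: float = 1.0
    w_utract: float = 1.0
    w_stacking: float = 1.0
    w_paired: float = 1.0

    def __post_init__(self) -> None:
        for f in ("w_hairpin", "w_utract", "w_stacking", "w_paired"):
            if getattr(self, f) < 0:
                raise InputError(f"{f} must be >= 0")


@dataclass(frozen=True)
class TerminationMetrics:
    """Per-design termination signals and the combined rank score."""

    linear_paired_frac: float
    stacking_frac: float
    hairpin_strength: int
    u_tract_frac: float
    rank_score: float


def linear_structure_fraction(d: StarDesign, model: EnergyModel = EnergyModel()) -> float:
    """Fraction of linear-region positions paired in the target MFE fold."""
    lin_len = len(d.linear)
    if lin_len == 0:
        return 0.0
    res = fold_mfe(d.target_seq, model)
    return sum(1 for p in res.structure.paired_positions() if p < lin_len) / lin_len


def stacking_fraction(linear: str) -> float:
    """Fraction of adjacent purine–purine dinucleotides (stacking surrogate)."""
    lin = normalize(linear)
    if len(lin) < 2:
        raise InputError("stacking fraction needs length >= 2")
    rr = sum(1 for a, b in zip(lin, lin[1:]) if a in PURINES and b in PURINES)
    return rr / (len(lin) - 1)


def hairpin_strength(s: TerminatorScaffold, model: EnergyModel = EnergyModel()) -> int:
    """Sum of pair scores over the positional stem5:stem3 pairs."""
    total = 0
    for k in range(s.stem_len):
        total += model.pair_score(s.stem5[k], s.stem3[s.stem_len - 1 - k])
    return total


def u_tract_score(s: TerminatorScaffold, window: int = U_TRACT_WINDOW) -> float:
    """U fraction of the first ``min(window, len)`` nt of the U-tract."""
    if not s.u_tract:
        raise InputError("empty U-tract")
    w = s.u_tract[: min(window, len(s.u_tract))]
    return w.count("U") / len(w)


def termination_rank(
    d: StarDesign,
    model: EnergyModel = EnergyModel(),
    weights: RankWeights = RankWeights(),
) -> TerminationMetrics:
    """Combine the four termination signals into a rank score.

    Hairpin strength is normalized by the strongest possible stem of the
    same length (all G:C pairs), so every term lies in [0, 1] and with
    unit weights the rank is bounded in [-2, 2].  The rank strictly
    decreases as linear-region pairing or stacking increases.
    """
    lin_paired = linear_structure_fraction(d, model)
    stacking = stacking_fraction(d.linear) if len(d.linear) >= 2 else 0.0
    strength = hairpin_strength(d.scaffold, model)
    stem_len = d.scaffold.stem_len
    norm = strength / (model.gc * stem_len) if stem_len else 0.0
    u_frac = u_tract_score(d.scaffold)
    rank = (
        weights.w_hairpin * norm
        + weights.w_utract * u_frac
        - weights.w_stacking * stacking
        - weights.w_paired * lin_paired
    )
    return TerminationMetrics(
        linear_paired_frac=lin_paired,
        stacking_frac=stacking,
        hairpin_strength=strength,
        u_tract_frac=u_frac,
        rank_score=rank,
    )
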