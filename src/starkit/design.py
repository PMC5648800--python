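"""De novo STAR design against a fixed intrinsic-terminator scaffold.

A *target RNA* is the cis-element placed upstream of a regulated gene: a
variable linear region followed by a terminator hairpin (5' stem arm, loop,
3' stem arm) and a poly-U tract.  By default it folds into the terminator
and shuts the gene OFF.  The cognate *STAR* is the reverse complement of
the linear region plus the 5' stem arm; binding this recognition region
prevents hairpin formation and switches the gene ON.

Design keeps the scaffold constant and searches linear-region sequence
space by seeded simulated annealing, minimizing a weighted sum of four
normalized defects:

* ``linear_paired_frac``   — intramolecular structure in the target's
  linear region (should be unstructured);
* ``star_self_frac``       — intramolecular structure in the STAR;
* ``duplex_deficit``       — shortfall of the STAR:target intermolecular
  duplex relative to the full recognition length;
* ``scaffold_disruption``  — terminator stem pairs missing from the target
  MFE structure (the hairpin must still form without the STAR).

Accepted designs must additionally be constraint-clean (GC window,
homopolymer cap, forbidden motifs), reach a cognate duplex of at least
``cognate_min_frac`` of the recognition length, and differ from every
previously accepted linear region by a minimum Hamming distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, DesignFailureError, InputError, ScaffoldError
from .fold import ComplexFoldResult, EnergyModel, FoldResult, cofold, fold_mfe
from .sequences import (
    gc_fraction,
    hamming,
    max_homopolymer_run,
    normalize,
    revcomp,
)

__all__ = [
    "TerminatorScaffold",
    "StarDesign",
    "DesignScore",
    "DesignConfig",
    "Violation",
    "derive_star",
    "assemble_target",
    "validate_constraints",
    "score_design",
    "design_library",
    "design_split_star",
    "scaffold_stem_pairs",
]

_NTS = ("A", "C", "G", "U")


@dataclass(frozen=True)
class TerminatorScaffold:
    """The fixed terminator shared by all library members.

    ``stem3`` must be the strict Watson–Crick reverse complement of
    ``stem5`` (wobble pairs in the scaffold are out of scope), the loop
    must be at least 3 nt, and the U-tract at least 75% uridine.
    """

    name: str
    stem5: str
    loop: str
    u_tract: str
    stem3: str = ""

    def __post_init__(self) -> None:
        for f in ("stem5", "loop", "u_tract", "stem3"):
            object.__setattr__(self, f, normalize(getattr(self, f)))
        if not self.stem3:
            object.__setattr__(self, "stem3", revcomp(self.stem5))
        if self.stem3 != revcomp(self.stem5):
            raise ScaffoldError(
                f"scaffold {self.name!r}: stem3 is not the reverse complement of stem5"
            )
        if len(self.loop) < 3:
            raise ScaffoldError(f"scaffold {self.name!r}: loop shorter than 3 nt")
        if not self.u_tract:
            raise ScaffoldError(f"scaffold {self.name!r}: empty U-tract")
        ufrac = self.u_tract.count("U") / len(self.u_tract)
        if ufrac < 0.75:
            raise ScaffoldError(
                f"scaffold {self.name!r}: U-tract U-fraction {ufrac:.2f} < 0.75"
            )

    @property
    def hairpin_seq(self) -> str:
        return self.stem5 + self.loop + self.stem3 + self.u_tract

    @property
    def stem_len(self) -> int:
        return len(self.stem5)


def derive_star(linear: str, scaffold: TerminatorScaffold) -> str:
    """STAR sequence: reverse complement of linear region + 5' stem arm."""
    lin = normalize(linear)
    if not lin:
        raise InputError("empty linear region")
    return revcomp(lin + scaffold.stem5)


def assemble_target(linear: str, scaffold: TerminatorScaffold) -> str:
    """Target RNA: linear‖stem5‖loop‖stem3‖u_tract (empty linear allowed)."""
    return normalize(linear) + scaffold.hairpin_seq


def scaffold_stem_pairs(linear_len: int, scaffold: TerminatorScaffold) -> list[Tuple[int, int]]:
    """0-based positional stem5:stem3 pairs in target coordinates,
    outermost to innermost."""
    s, lo = scaffold.stem_len, len(scaffold.loop)
    out = []
    for k in range(s):
        i = linear_len + k
        j = linear_len + s + lo + (s - 1 - k)
        out.append((i, j))
    return out


@dataclass(frozen=True)
class StarDesign:
    """One designed unit: a linear region on a scaffold, with its scores."""

    name: str
    linear: str
    scaffold: TerminatorScaffold
    score: Optional["DesignScore"] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "linear", normalize(self.linear))
        if not self.linear:
            raise InputError(f"design {self.name!r}: empty linear region")

    @property
    def target_seq(self) -> str:
        return assemble_target(self.linear, self.scaffold)

    @property
    def star_seq(self) -> str:
        return derive_star(self.linear, self.scaffold)

    @property
    def recognition_len(self) -> int:
        return len(self.linear) + self.scaffold.stem_len


@dataclass(frozen=True)
class DesignScore:
    """The four normalized defect components and their weighted sum."""

    linear_paired_frac: float
    star_self_frac: float
    duplex_deficit: float
    scaffold_disruption: float
    composite: float
    cognate_inter_pairs: int

    def as_dict(self) -> dict:
        return {
            "linear_paired_frac": self.linear_paired_frac,
            "star_self_frac": self.star_self_frac,
            "duplex_deficit": self.duplex_deficit,
            "scaffold_disruption": self.scaffold_disruption,
            "composite": self.composite,
            "cognate_inter_pairs": self.cognate_inter_pairs,
        }


@dataclass(frozen=True)
class Violation:
    """One constraint violation (data, not an exception)."""

    kind: str  # gc | homopolymer | motif
    message: str


@dataclass(frozen=True)
class DesignConfig:
    """Tunable design parameters with library-wide defaults.

    ``linear_len`` is the length of the designed variable region;
    ``gc_min``/``gc_max`` bound its GC content; ``max_homopolymer`` caps
    single-nucleotide runs; ``forbidden_motifs`` are excluded substrings
    (e.g. add "AUG" to avoid spurious start codons — off by default).
    The annealing schedule is geometric: temperature
    ``anneal_temp0 * cooling**step`` over ``anneal_steps`` moves.
    """

    linear_len: int = 40
    gc_min: float = 0.3
    gc_max: float = 0.7
    max_homopolymer: int = 4
    forbidden_motifs: Tuple[str, ...] = ()
    anneal_steps: int = 1000
    anneal_temp0: float = 0.05
    cooling: float = 0.995
    seed: int = 0
    accept_composite_max: float = 0.65
    diversity_min_hamming: int = 12
    cognate_min_frac: float = 0.8
    w_linear: float = 1.0
    w_star_self: float = 1.0
    w_duplex: float = 1.0
    w_disruption: float = 1.0
    cutoff: int = 13
    interaction_len: int = 20
    max_attempts_per_design: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "forbidden_motifs", tuple(normalize(m) for m in self.forbidden_motifs)
        )
        self.validate()

    def validate(self) -> None:
        if self.linear_len < 1:
            raise ConfigError("linear_len must be >= 1")
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ConfigError(
                f"gc bounds invalid: gc_min={self.gc_min} gc_max={self.gc_max}"
            )
        if self.max_homopolymer < 1:
            raise ConfigError("max_homopolymer must be >= 1")
        if self.linear_len < self.diversity_min_hamming:
            raise ConfigError(
                "linear_len must be >= diversity_min_hamming "
                f"({self.linear_len} < {self.diversity_min_hamming})"
            )
        if not (0 < self.cooling <= 1.0):
            raise ConfigError("cooling must be in (0, 1]")
        if self.anneal_temp0 < 0:
            raise ConfigError("anneal_temp0 must be >= 0")
        for w in ("w_linear", "w_star_self", "w_duplex", "w_disruption"):
            if getattr(self, w) < 0:
                raise ConfigError(f"{w} must be >= 0")
        if not (0.0 <= self.cognate_min_frac <= 1.0):
            raise ConfigError("cognate_min_frac must be in [0, 1]")
        if self.cutoff < 1:
            raise ConfigError("cutoff must be >= 1")
        if self.interaction_len < 6:
            raise ConfigError("interaction_len must be >= 6")

    def weights(self) -> Tuple[float, float, float, float]:
        return (self.w_linear, self.w_star_self, self.w_duplex, self.w_disruption)


def validate_constraints(linear: str, cfg: DesignConfig) -> List[Violation]:
    """Sequence-composition hygiene checks; empty list means clean."""
    lin = normalize(linear)
    out: List[Violation] = []
    gc = gc_fraction(lin)
    if not (cfg.gc_min <= gc <= cfg.gc_max):
        out.append(
            Violation("gc", f"GC fraction {gc:.3f} outside [{cfg.gc_min}, {cfg.gc_max}]")
        )
    run = max_homopolymer_run(lin)
    if run > cfg.max_homopolymer:
        out.append(
            Violation("homopolymer", f"homopolymer run {run} > {cfg.max_homopolymer}")
        )
    for motif in cfg.forbidden_motifs:
        if motif and motif in lin:
            out.append(Violation("motif", f"forbidden motif {motif} present"))
    return out


def score_design(
    d: StarDesign, model: EnergyModel = EnergyModel(), cfg: DesignConfig = DesignConfig()
) -> DesignScore:
    """Score one design from target MFE, STAR MFE and STAR:target cofold."""
    target = fold_mfe(d.target_seq, model)
    star = fold_mfe(d.star_seq, model)
    duplex = cofold(d.star_seq, d.target_seq, model)
    return _score_from_folds(d, target, star, duplex, cfg)


def _score_from_folds(
    d: StarDesign,
    target: FoldResult,
    star: FoldResult,
    duplex: ComplexFoldResult,
    cfg: DesignConfig,
) -> DesignScore:
    lin_len = len(d.linear)
    paired = target.structure.paired_positions()
    if lin_len:
        linear_paired = sum(1 for p in paired if p < lin_len) / lin_len
    else:
        linear_paired = 0.0
    star_len = len(d.star_seq)
    star_self = len(star.structure.paired_positions()) / star_len if star_len else 0.0
    rec = d.recognition_len
    deficit = 1.0 - min(duplex.inter_pairs, rec) / rec if rec else 0.0
    stem_pairs = scaffold_stem_pairs(lin_len, d.scaffold)
    if stem_pairs:
        present = sum(1 for p in stem_pairs if p in set(target.structure.pairs))
        disruption = 1.0 - present / len(stem_pairs)
    else:
        disruption = 0.0
    w = cfg.weights()
    composite = (
        w[0] * linear_paired + w[1] * star_self + w[2] * deficit + w[3] * disruption
    )
    return DesignScore(
        linear_paired_frac=linear_paired,
        star_self_frac=star_self,
        duplex_deficit=deficit,
        scaffold_disruption=disruption,
        composite=composite,
        cognate_inter_pairs=duplex.inter_pairs,
    )


def _random_linear(rng: np.random.Generator, cfg: DesignConfig) -> str:
    """Seed sequence for annealing, biased to the middle of the GC window."""
    gc = 0.5 * (cfg.gc_min + cfg.gc_max)
    out = []
    for _ in range(cfg.linear_len):
        if rng.random() < gc:
            out.append("G" if rng.random() < 0.5 else "C")
        else:
            out.append("A" if rng.random() < 0.5 else "U")
    return "".join(out)


def _anneal_linear(
    start: str,
    scaffold: TerminatorScaffold,
    model: EnergyModel,
    cfg: DesignConfig,
    rng: np.random.Generator,
    avoid: Sequence[str] = (),
) -> Tuple[str, DesignScore]:
    """Simulated annealing on the linear region.

    Moves are single-nucleotide substitutions; the objective is the
    composite defect plus one penalty unit per composition violation and
    per diversity clash with the already-accepted linear regions in
    ``avoid``, so the search is driven back inside the constraint region
    and away from previous solutions.
    """

    def energy(lin: str) -> Tuple[float, DesignScore]:
        d = StarDesign(name="_anneal", linear=lin, scaffold=scaffold)
        sc = score_design(d, model, cfg)
        clashes = sum(
            1 for prev in avoid if hamming(lin, prev) < cfg.diversity_min_hamming
        )
        return sc.composite + len(validate_constraints(lin, cfg)) + clashes, sc

    cur = start
    e_cur, sc_cur = energy(cur)
    best, e_best, sc_best = cur, e_cur, sc_cur
    temp = cfg.anneal_temp0
    for _ in range(cfg.anneal_steps):
        pos = int(rng.integers(len(cur)))
        new_nt = _NTS[int(rng.integers(4))]
        if cur[pos] == new_nt:
            temp *= cfg.cooling
            continue
        cand = cur[:pos] + new_nt + cur[pos + 1 :]
        e_new, sc_new = energy(cand)
        dE = e_new - e_cur
        if dE <= 0 or (temp > 0 and rng.random() < math.exp(-dE / temp)):
            cur, e_cur, sc_cur = cand, e_new, sc_new
            if e_cur < e_best:
                best, e_best, sc_best = cur, e_cur, sc_cur
        temp *= cfg.cooling
    return best, sc_best


def design_library(
    n: int,
    scaffold: TerminatorScaffold,
    model: EnergyModel = EnergyModel(),
    cfg: DesignConfig = DesignConfig(),
) -> List[StarDesign]:
    """Design ``n`` mutually diverse STAR:target variants.

    Each variant is annealed independently from a seeded random start and
    accepted only if it is constraint-clean, its composite defect is at
    most ``cfg.accept_composite_max``, its cognate duplex reaches
    ``cfg.cognate_min_frac`` of the recognition length, and its linear
    region is at Hamming distance >= ``cfg.diversity_min_hamming`` from
    every previously accepted one.  Identical seeds reproduce the library
    byte-identically; the attempt budget is
    ``n * cfg.max_attempts_per_design``.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    accepted: List[StarDesign] = []
    budget = n * cfg.max_attempts_per_design
    attempts = 0
    reject_reasons: dict[str, int] = {}
    while len(accepted) < n:
        if attempts >= budget:
            binding = max(reject_reasons, key=reject_reasons.get) if reject_reasons else "none"
            raise DesignFailureError(
                f"design budget of {budget} attempts exhausted with "
                f"{len(accepted)}/{n} designs; most frequent rejection: {binding} "
                f"({reject_reasons})"
            )
        attempts += 1
        lin, sc = _anneal_linear(
            _random_linear(rng, cfg),
            scaffold,
            model,
            cfg,
            rng,
            avoid=[d.linear for d in accepted],
        )
        if validate_constraints(lin, cfg):
            reject_reasons["constraints"] = reject_reasons.get("constraints", 0) + 1
            continue
        if sc.composite > cfg.accept_composite_max:
            reject_reasons["composite"] = reject_reasons.get("composite", 0) + 1
            continue
        rec = len(lin) + scaffold.stem_len
        if sc.cognate_inter_pairs < cfg.cognate_min_frac * rec:
            reject_reasons["cognate"] = reject_reasons.get("cognate", 0) + 1
            continue
        if any(hamming(lin, d.linear) < cfg.diversity_min_hamming for d in accepted):
            reject_reasons["diversity"] = reject_reasons.get("diversity", 0) + 1
            continue
        name = f"star{len(accepted) + 1:03d}"
        accepted.append(StarDesign(name=name, linear=lin, scaffold=scaffold, score=sc))
    return accepted


def design_split_star(
    d: StarDesign,
    interaction_len: int = 20,
    model: EnergyModel = EnergyModel(),
    cfg: DesignConfig = DesignConfig(),
    seed: Optional[int] = None,
) -> Tuple[str, str]:
    """Split a STAR into AND-gate halves A and B with designed tails.

    The STAR is cut between its linear-region binder and its stem-arm
    binder: A = revcomp(linear)‖x and B = y‖revcomp(stem5), where x and y
    are complementary interaction tails of length ``interaction_len``.
    The returned pair satisfies, under the engine:

    * ``cofold(A, B).inter_pairs >= interaction_len`` (the halves
      assemble), and
    * neither half alone reaches the cognate duplex threshold
      ``ceil(cognate_min_frac * recognition_len)`` against the target.

    The tail is searched by seeded simulated annealing on x (y is kept as
    revcomp(x)); infeasible geometries (e.g. a linear region long enough
    that A alone is a full cognate mimic) exhaust the budget and raise
    :class:`DesignFailureError`.
    """
    if interaction_len < 6:
        raise InputError("interaction_len must be >= 6")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    a_core = revcomp(d.linear)
    b_core = revcomp(d.scaffold.stem5)
    target = d.target_seq
    thr = math.ceil(cfg.cognate_min_frac * d.recognition_len)

    def penalty(x: str) -> Tuple[float, Tuple[str, str]]:
        A = a_core + x
        B = revcomp(x) + b_core
        ab = cofold(A, B, model).inter_pairs
        a_t = cofold(A, target, model).inter_pairs
        b_t = cofold(B, target, model).inter_pairs
        p = (
            max(0, interaction_len - ab)
            + max(0, a_t - (thr - 1))
            + max(0, b_t - (thr - 1))
        )
        return float(p), (A, B)

    x = "".join(_NTS[int(rng.integers(4))] for _ in range(interaction_len))
    e_cur, halves = penalty(x)
    if e_cur == 0:
        return halves
    temp = max(cfg.anneal_temp0, 0.5)
    for _ in range(cfg.anneal_steps * cfg.max_attempts_per_design):
        pos = int(rng.integers(interaction_len))
        nt = _NTS[int(rng.integers(4))]
        if x[pos] == nt:
            temp *= cfg.cooling
            continue
        cand = x[:pos] + nt + x[pos + 1 :]
        e_new, halves_new = penalty(cand)
        if e_new == 0:
            return halves_new
        dE = e_new - e_cur
        if dE <= 0 or (temp > 0 and rng.random() < math.exp(-dE / temp)):
            x, e_cur = cand, e_new
        temp *= cfg.cooling
    raise DesignFailureError(
        f"split-STAR tail search exhausted its budget (residual penalty {e_cur}); "
        f"threshold {thr} vs linear length {len(d.linear)} may be infeasible"
    )
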