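# Methods

## The regulatory system being modeled

A STAR:target pair is two RNAs. The target RNA is transcribed upstream of a
gene and contains, 5'→3': a variable *linear region* of length L, a terminator
hairpin (5' stem arm of length S, loop, 3' stem arm = reverse complement of
the 5' arm), and a poly-U tract. Folding of the hairpin plus the U-tract
terminates transcription (gene OFF). The STAR is defined as the reverse
complement of the first L + S nucleotides of the target (linear region + 5'
stem arm, the *recognition region*); its binding prevents hairpin formation
(gene ON). Everything in this package operates at the level of equilibrium
secondary structure of these two RNAs; transcription, termination and
fluorescent readouts are not simulated.

## Secondary-structure engine

**Model.** A structure is a pseudoknot-free set of base pairs. Its score is
the plain sum of pair scores: G:C = 3, A:U = 2, G:U = 1 (dimensionless;
higher = more stable); all other pairs are forbidden. Intramolecular pairs
must enclose at least `min_loop = 3` unpaired nucleotides. There are no
dangle, coaxial-stacking or multiloop terms. This deliberate simplification
buys exact verifiability: every engine output can be reproduced by exhaustive
enumeration (`enumerate_structures`, guarded to total length ≤ 14), and the
test suite does exactly that. The engine interface (MFE structure, pair
probabilities, intermolecular pair counts) is the contract all higher modules
depend on, so a nearest-neighbor thermodynamic engine can be substituted
without touching them.

**MFE folding** is a Nussinov-style interval dynamic program (O(n³)),
JIT-compiled with numba (a pure-Python fallback in `_kernels.py` produces
identical results). Co-optimal structures are common in an integer model, so
the traceback is deterministic by rule: at each interval, pairing the
leftmost position beats leaving it unpaired, and among co-optimal partners
the smallest index wins — the reported structure is the co-optimal structure
with the lexicographically smallest pair list.

**Partition function.** The Boltzmann ensemble weights each structure by
`exp(score/kT)` with `kT = 1.0` by default; Z includes the empty structure.
Inside values are computed over half-open intervals by conditioning on the
pairing of the last position; outside values are accumulated outermost-first
over directly-enclosing pairs (an O(n⁴) step, vectorized; exact, and fast for
the ≤ ~150-nt sequences this toolkit folds). Pair probabilities are then
`p(i,j) = q(i,j) · inside(i+1,j-1) · outside(i,j) / Z`. Probabilities are
computed in linear (not log) space; with default `kT` this is safe far beyond
the sequence lengths used here, and an overflow raises an explicit error
suggesting a larger `kT`.

**Cofolding** folds the ordered concatenation a‖b with an explicit strand
break (no linker nucleotides, so no spurious linker pairing). Pairs spanning
the break are exempt from the minimum-loop rule; their count (`inter_pairs`)
is the crosstalk currency. Because spanning pairs must be mutually nested,
they form an antiparallel duplex register, as they should.

**A property worth knowing:** with a pure max-score objective, *any*
available pair adds score, so MFE structures are densely paired and ties are
everywhere. Three consequences are documented and tested rather than hidden:
(1) "unstructured" fractions rarely reach 0 — e.g. a poly-A linear region
always pairs the mandatory poly-U tract; (2) a full STAR:target duplex and a
terminator-hairpin-plus-partial-duplex are exactly co-optimal whenever both
use the same complementary arms, and the tie-break decides; (3) absolute
crosstalk counts run higher than those of a thermodynamic engine, which is
why the orthogonality cut-off is exposed as a parameter.

## Design procedure

Each library member is designed by simulated annealing on its linear region
(single-nucleotide substitution moves, geometric cooling `T = T0·c^step`,
defaults T0 = 0.05, c = 0.995, 1000 steps). The objective is a weighted sum
of four defects in [0, 1], all weights 1 by default:

* `linear_paired_frac` — fraction of linear-region positions paired in the
  target MFE structure;
* `star_self_frac` — fraction of STAR positions paired in the STAR MFE
  structure;
* `duplex_deficit` — 1 − inter_pairs(STAR, target)/(L + S);
* `scaffold_disruption` — fraction of positional stem pairs missing from the
  target MFE structure;

plus one penalty unit per composition violation (GC outside [0.3, 0.7],
homopolymer run > 4, forbidden motif) and per diversity clash with an
already-accepted member, which steers independent anneals apart instead of
discarding finished candidates.

A candidate is accepted only if, re-scored from scratch, it is
constraint-clean, its composite is ≤ `accept_composite_max`, its cognate
duplex reaches ≥ 80% of the recognition length (`cognate_min_frac = 0.8`,
tolerating minor end fraying), and its linear region is ≥ 12 substitutions
(Hamming) from every accepted member. The attempt budget is 12 anneals per
requested design; exhausting it raises an error naming the most frequent
rejection reason. Identical seed and configuration reproduce a library
byte-identically.

`accept_composite_max` defaults to 0.65. Rationale: on GC-stem scaffolds the
max-score model floors `star_self_frac` near 0.33 (the STAR's stem-binder
head always finds weak partners), so attainable composites floor around
0.45–0.55, while random constraint-clean linear regions score around 0.9; the
default sits between the two, rejecting unoptimized sequences without
rejecting the attainable optimum. It is a filter on *this* engine's scale,
not a thermodynamic quantity.

**Split-STAR AND gates.** The STAR is cut between its linear-region binder
and its stem binder: A = revcomp(linear)‖x, B = y‖revcomp(stem5), with
complementary interaction tails x, y (default 20 nt, y = revcomp(x)). The
tail is annealed until cofold(A, B) reaches the tail length while neither
half alone reaches the cognate threshold ⌈0.8·(L+S)⌉ against the target.
Geometry matters: half A alone always recovers ~L intermolecular pairs, so
the contract is only satisfiable when L < 0.8·(L+S), i.e. the stem is longer
than a quarter of the linear region. With the 8-bp toy stem this means
linear regions up to ~31 nt; the 22-nt default used throughout the examples
satisfies it, while a 40-nt linear region on the same stem is provably
infeasible and correctly fails with a design error.

## Crosstalk and orthogonal subsets

The crosstalk matrix evaluates every STAR against every target — n² cofolds,
10,201 for a 101-member library. The default metric counts intermolecular
pairs in the optimal complex (`mfe_pairs`); `prob_pairs` instead counts
intermolecular pairs with posterior probability ≥ 0.5 in the complex
ensemble. Variants i ≠ j are *orthogonal* when counts[i,j] < cutoff **and**
counts[j,i] < cutoff (either direction of crosstalk breaks independence);
the inequality is strict and the default cutoff is 13 predicted base pairs.
Because this engine over-counts weak pairs relative to a thermodynamic
model, the cutoff is a calibratable parameter, not a universal constant.

Orthogonal-subset selection is maximum clique on the orthogonality graph.
Exact mode enumerates maximal cliques (Bron–Kerbosch with pivoting, via
networkx) and returns the lexicographically smallest maximum clique; it is
used up to n = 200, beyond which the tool warns and falls back to greedy
(highest-degree-first insertion, always a clique, never larger than exact).
Every returned set is re-verified directly against the counts matrix.

## Termination-signal metrics

Intrinsic termination favours a strong hairpin and proximal U-tract and is
hurt by upstream structure and stacking. Per design:
`hairpin_strength` = positional sum of stem pair scores; `u_tract_frac` =
U fraction of the first 8 nt after the 3' stem arm (proximal-dominance
window, configurable); `linear_paired_frac` as above; `stacking_frac` =
fraction of adjacent purine–purine dinucleotides in the linear region — a
deliberate surrogate for single-strand base stacking, in which purines
dominate. The rank is

```
rank = w_h·strength/(3·S) + w_u·u_frac − w_s·stacking − w_p·linear_paired
```

bounded in [−2, 2] with unit weights, and strictly decreasing in the two
defect terms. It is a relative triage heuristic for candidate ordering; it
makes no quantitative claim about measured termination efficiencies.

## Synthetic fixtures

`toy_scaffold` builds shape-realistic terminators: an all-G/C stem by default
(hairpin strength exactly 3·S), a loop drawn only from letters that cannot
pair any stem letter (Watson–Crick or wobble), and a pure poly-U tract. The
`planted_crosstalk` fixture plants a subset whose pairwise counts fall below
the cutoff and drowns everything else at or above it, making the planted set
the unique maximum clique — ground truth for selector tests. All fixtures
are pure functions of their seed. What passing tests on these fixtures show
is algorithmic correctness under the declared model; they do not show that
designed sequences will perform in cells, nor that the integer model ranks
real terminators as a nearest-neighbor model (or an experiment) would.

## Problem sizes and numerical choices

Tests and the acceptance script use 22-nt linear regions on an 8-bp-stem
toy scaffold (30-nt recognition regions), 101-member libraries for the
crosstalk scale check, 500 random sequences of length ≤ 12 for
engine-vs-enumeration agreement (tolerance 1e−9 on probabilities, exact on
scores), and 100 random 10–15-node instances for clique-vs-brute-force
agreement. Ties, tie-breaks and degenerate inputs (empty linear region,
empty stem, single-nucleotide sequences) are all defined and tested; 0-based
indices internally, dot-bracket with `&` at the strand break externally.

## Known limitations

* The integer pair-score model is not a thermodynamic model: absolute
  counts, probabilities and "unstructured-ness" floors differ from
  nearest-neighbor engines, and the orthogonality cutoff must be
  recalibrated for any substituted engine.
* Equilibrium only: STAR regulation in vivo is substantially
  cotranscriptional/kinetic; nothing here models folding pathways.
* Pseudoknots are excluded by construction.
* The design objective is a weighted sum of normalized defects, not an
  ensemble-defect optimization.
* Scaffold stems are strict Watson–Crick; wobble-containing stems are out of
  scope.
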