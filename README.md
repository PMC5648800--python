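# starkit

Computational design of **Small Transcription Activating RNAs (STARs)** —
bacterial riboregulators that turn a gene ON by preventing formation of an
intrinsic transcription terminator.

A *target RNA* sits upstream of the regulated gene and consists of a variable
**linear region** followed by a fixed **terminator scaffold** (a hairpin of a
5' stem arm, loop and 3' stem arm, then a poly-U tract). Left alone, the
terminator folds and transcription stops (OFF). The cognate *STAR* is the
reverse complement of the linear region plus the 5' stem arm; by invading this
**recognition region** it blocks hairpin formation and lets RNA polymerase read
through (ON). Because recognition is pure Watson–Crick complementarity, whole
libraries of independently acting STAR:target pairs can be designed *de novo*
by varying the linear region while keeping the scaffold constant.

starkit provides, for RNA synthetic biologists building such libraries:

* **`starkit.fold`** — a self-contained secondary-structure engine: Nussinov-style
  maximum-score folding, an exact McCaskill-style partition function with base
  pair probabilities, two-strand cofolding with an explicit strand break, and an
  exhaustive enumeration oracle. The energy model is a transparent integer pair
  score (G:C = 3, A:U = 2, G:U = 1, minimum loop 3), so every number the engine
  produces can be verified by brute force.
* **`starkit.design`** — seeded simulated-annealing design of linear regions
  against four structural objectives (unstructured linear region, unstructured
  STAR, full-length STAR:target duplex, intact terminator hairpin), plus
  split-STAR AND-gate design.
* **`starkit.crosstalk`** — the orthogonality workflow: all-vs-all intermolecular
  base-pair prediction (n² cofolds), classification against a strict cut-off
  (default: fewer than 13 predicted base pairs in **both** directions), and
  maximum-clique selection of orthogonal subsets (exact Bron–Kerbosch or greedy).
* **`starkit.termsig`** — termination design-principle metrics: hairpin strength,
  proximal U-tract quality, linear-region structure and purine-stacking
  surrogate, combined into a triage rank score.
* **`starkit.fixtures`** — seeded synthetic scaffolds, libraries and crosstalk
  matrices (with planted orthogonal subsets), so everything is testable offline.

## Worked example

```bash
# a synthetic terminator scaffold (8-bp GC stem, 4-nt loop, U8 tract)
star fixtures --kind scaffold --seed 0 --out toy_scaffold.yaml

# design three STAR:target pairs with 22-nt linear regions
printf 'linear_len: 22\nseed: 1\n' > config.yaml
star design --n 3 --scaffold toy_scaffold.yaml --config config.yaml --out lib

# all-vs-all crosstalk and orthogonal subset selection
star crosstalk --library lib.json --out crosstalk.tsv
star select --matrix crosstalk.tsv --cutoff 28 --mode exact

# termination-signal metrics
star score --library lib.json --out metrics.tsv
```

which prints

```
wrote 3 designs to lib.fasta and lib.json
wrote 3x3 matrix (9 evaluations) to crosstalk.tsv
orthogonal subset (size 3, cutoff 28, mode exact): star001 star002 star003
```

`crosstalk.tsv` holds the predicted intermolecular base-pair counts, rows =
STARs, columns = targets:

```
star\target  star001  star002  star003
star001      30       27       26
star002      24       30       24
star003      25       25       30
```

The diagonal entries (30) are the cognate duplexes — each STAR pairs its own
target across the full 30-nt recognition region (22-nt linear + 8-bp stem).
Off-diagonal entries are predicted crosstalk; `star select` keeps a subset in
which every pair stays strictly below the cut-off in both directions. Because
all variants share one scaffold, an all-GC stem contributes heavy off-diagonal
counts under this engine; the cut-off is a calibratable parameter (`--cutoff`,
default 13) and here the example uses 28 to illustrate selection.

`metrics.tsv` reports the termination signals per design:

```
name     linear_paired_frac  stacking_frac  hairpin_strength  u_tract_frac  rank_score
star001  0.136364            0.000000       24                1.000000      1.863636
star002  0.136364            0.000000       24                1.000000      1.863636
star003  0.181818            0.000000       24                1.000000      1.818182
```

A rank near its maximum of 2 means a strong hairpin (24 = 8 G:C pairs × 3),
a perfect proximal U-tract, and an almost unstructured, stacking-free linear
region — the profile associated with tight OFF states.

Single sequences fold directly:

```bash
$ star fold GGGAAACCC
score=9
(((...)))
```

See `docs/methods.md` for the model, its assumptions and limitations.

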