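# Methods

This note records the model implemented by `zukerfold`, the numerical
conventions, the design decisions that required a judgement call, and
the problem sizes the implementation was validated at.

## Model

Sequences are strings over `{A, C, G, U}` indexed from 1.  A secondary
structure is a set of base pairs `(i, j)`, `i < j`, that is nested (no
two pairs cross) and uses each position at most once.  Admissible pairs
are `A·U`, `G·C` and — on by default — the wobble pair `G·U`, each in
both orientations.  A pair must enclose at least `min_hairpin = 3`
unpaired-capable positions (`j − i − 1 ≥ 3`).

The free energy of a structure is the sum over its loops:

- hairpin closed by `i·j`: `eH(i, j)`, a function of loop size;
- stacked pair `i·j` on `(i+1)·(j−1)`: `eS(i, j)`, a function of the
  two pairs;
- interior/bulge loop closed by `i·j` with inner pair `k·l`:
  `eL(i, j, k, l)`, a function of the two side sizes; loops with both
  sides empty are stacks, one empty side makes a bulge;
- multibranch loop: `a + b·(number of branches) + c·(unpaired bases)`
  with constants `(a, b, c) = (multibranch_closing, multibranch_branch,
  multibranch_unpaired)`.

The optimum is computed by the standard five-table recursion:

```
W(j)      = min{ W(j−1),  min_i [ V(i, j) + W(i−1) ] }
V(i, j)   = min{ eH(i,j),
                 eS(i,j) + V(i+1, j−1),
                 VBI(i, j),
                 VM(i+1, j−1) + a }          if i·j admissible, else ∞
VBI(i, j) = min_{i<k<l<j} [ eL(i,j,k,l) + V(k, l) ]
VM(i, j)  = min_{i≤k<j}  [ WM(i, k) + WM(k+1, j) ]
WM(i, j)  = min{ VM(i,j), WM(i+1,j) + c, WM(i,j−1) + c, V(i,j) + b }
```

One deliberate indexing choice deserves emphasis: the multibranch
option of `V(i, j)` uses the **enclosed** interval, `VM(i+1, j−1) + a`.
Using `VM(i, j)` directly would let the bifurcation re-use positions
`i` or `j` as a branch while they are already consumed by the closing
pair; this double-booking produces energies unattainable by any legal
structure (the exhaustive oracle catches it immediately, e.g. on
`UGCAGGAGGAGGGCGG` under the unit-score preset, −4.0 vs the true −3.0)
and tracebacks that violate the position-uniqueness invariant.  `VM`
itself remains the full-interval bifurcation table because that is what
`WM`'s decomposition needs.

Interior/bulge loops are capped at a combined side span of
`max_internal_span = 30` unpaired bases, the standard device that keeps
the whole fill at `O(n³)` time and makes `VBI` a bounded local scan.

## Energy presets and parameters

Energies are **integers in deci-units** (tenths of the model's energy
unit); all comparisons are exact and ties are broken deterministically.
Two presets ship with the package:

- `nussinov` — every admissible pair contributes exactly −10
  (pair bonus, stack default and multibranch closing are all −10; the
  branch and unpaired constants are 0).  Under this preset
  `−W(n)/10` equals the maximum number of admissible pairs, which gives
  an independent check against a separately written maximum-pairing
  recurrence.  Setting the multibranch closing constant to −10 (rather
  than 0) is required for this identity: a pair that closes a
  multibranch loop must score like any other pair.
- `simple` — a small authored table set (sequence-dependent stacks, all
  stabilizing; size-dependent hairpin/bulge/interior penalties;
  multibranch constants `(34, 4, 0)`).  It is a plausible, well-behaved
  toy model for exercising every loop type, not a fit to thermodynamic
  measurements; predictions should not be read as physical free
  energies.

Size tables are extrapolated beyond their last entry by clamping to the
final value.  Custom parameter files use a small plain-text grammar
(`[hairpin]`, `[bulge]`, `[internal]`, `[stack]` blocks) with
line-numbered errors; `save_params`/`load_params` round-trip.

Infinity is the integer `1 << 40`; additions saturate, and any value at
or above `1 << 39` is classified as infinite so that vectorized adds of
"infinity plus a finite bonus" never wrap or leak back into the finite
range.

## Fill strategies

Three evaluation orders fill the same recurrences and are verified
bit-identical cell-for-cell:

- `naive` — `i` descending, `j` ascending;
- `wavefront` — cells grouped into `s × s` tiles; tile waves proceed by
  tile-grid anti-diagonal, and within a wave cells are emitted in global
  anti-diagonal slices ("phases"), so every cell's dependencies
  (`(i+1, j)` and `(i, j−1)`, the cover relation of the dependency
  order) lie in strictly earlier phases.  `validate_schedule` checks
  the cover relation (and optionally all dependencies exhaustively);
- `tiled` — the wavefront order with the `VM` bifurcation minimum
  computed in fixed-size chunks, emulating a blocked reduction.

The wavefront order is the one a parallel device would execute (all
cells of a phase are independent); here it serves as an executable
correctness argument rather than a speed gain.

## Traceback

Traceback is iterative over an explicit agenda and re-derives each
minimizing option in a fixed order (hairpin, stack, interior, then
multibranch; splits scanned left to right), so the reported structure
is deterministic and identical across fill strategies.  The invariant
`evaluate_structure(traceback(m)) == W(n)` — the structure's
independently recomputed energy equals the table optimum, exactly — is
enforced in the test suite on every random input.

## Validation oracles

- **Exhaustive enumeration**: all nested structures over the admissible
  pairing rules are generated (each exactly once, checked against an
  independent counting recurrence) and scored; the DP must match the
  exhaustive minimum.  Feasible to length ~16; a safety cap guards
  against accidental combinatorial blow-ups.
- **Maximum-pairing reduction**: under the `nussinov` preset the DP
  must reproduce an independently written max-pairing recurrence.
- **Exhaustive boundary search**: the scheduler's `boundary` must beat
  every integer split.

## Scheduling and execution

For two worker classes with per-sequence times `t_slow ≥ t_fast`:
`speedup K = t_slow / t_fast`, `allocation_ratio = 1 / (K + 1)`, and
`boundary(N, t_slow, t_fast)` returns the integer `B` minimizing the
makespan `max(t_slow·B, t_fast·(N−B))`.  Only `floor` and `ceil` of
`N/(K+1)` can be optimal; ties are broken by smaller busy-time
imbalance, then by smaller `B`.  Minimizing makespan and minimizing
imbalance are *not* the same objective — e.g. `t_slow = 10, t_fast = 1,
N = 20` has its best makespan at `B = 1` (19) while `B = 2` balances
better (20 vs 18) but finishes later — and makespan is the quantity
that matters, so it is the primary key.  `allocate_multi` generalizes
to any number of classes by largest-remainder apportionment over
processing rates, assigning contiguous index ranges.

Per-class `WorkerProfile`s store measured times per length and
extrapolate unknown lengths cubically (`(L/L₀)³` from the nearest
measured length), matching the fill's `O(n³)` cost.  Reported figures
are rounded half-up (via `decimal`), matching how the benchmark tables
round; banker's rounding would differ on exact halves.

`run_hybrid` executes a plan in two modes with identical results:
`simulated` advances a virtual clock using the profiles (round-robin
over each class's `capacity` workers) and is fully deterministic;
`real` uses thread pools and wall-clock timing.  Events are recorded in
the order dispatch (fast batch) → process (slow batch) → collect →
traceback.  `sweep_ratio` is timing-only: it evaluates the simulated
makespan across a grid of slow-class shares without folding anything.

## Synthetic data

`generate_random_sequences` draws i.i.d. bases (uniform by default,
arbitrary composition on request) with a seeded `numpy` generator.
This emulates batches of same-length RNAs as used in throughput
benchmarks; it does not emulate biological base composition, codon
structure or conserved secondary structure, so synthetic minimum
energies are systematically shallower than those of real structured
RNAs of the same length.

## Problem sizes used in validation

- Oracle equivalence: > 400 sequences of length 8–16, both presets.
- Strategy invariance: 50 sequences of length 40 × 6 fill variants,
  all five matrices compared element-wise.
- Maximum-pairing reduction: 100 sequences of length 30.
- Scheduler optimality: 1000 random `(t_slow, t_fast, N ≤ 5000)`
  instances, exhaustive.
- Benchmark arithmetic: the four published length groups
  (`L = 68/120/154/221`, `N = 20000`), reproducing speedups
  15.90/16.17/11.17/5.83 and ratios 5.92 %/5.83 %/8.22 %/14.64 %, the
  aggregate-time speedups 15.93×/6.75×/1.16×, the boundary `B = 2929`,
  and the 14 % sweep minimum.

The entire suite runs in well under a minute on one CPU.

## Limitations

- No pseudoknots, coaxial stacking, dangling ends or
  temperature-dependent parameters; the `simple` preset is a toy model.
- Single optimal structure only — no suboptimal ensembles or partition
  function.
- The static allocation assumes same-length (or similar-cost)
  sequences per batch, as the profiles are per-length; strongly mixed
  batches should be grouped by length first.
- The real execution mode shares one Python process, so its timings
  reflect thread scheduling, not device-level parallel fills.
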