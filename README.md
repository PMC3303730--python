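# zukerfold

Minimum-free-energy RNA secondary-structure prediction by the Zuker
dynamic program, plus the static task-allocation arithmetic needed to
split large batches of sequences across heterogeneous worker classes
(e.g. a multi-core host and a throughput accelerator).

## The scientific problem

An RNA molecule is a string over `{A, C, G, U}` that folds back on
itself through Watson–Crick (`A·U`, `G·C`) and wobble (`G·U`) base
pairs.  Restricting attention to pseudoknot-free (nested) structures,
the structure of minimum free energy under a loop-decomposition energy
model can be found exactly by the Zuker dynamic program.  Five mutually
recursive tables are filled over all intervals `[i, j]` of the sequence:

- `W(j)` — best energy of the prefix `1..j`,
- `V(i, j)` — best energy of the interval given that `i·j` pair,
- `VBI(i, j)` — best interior/bulge loop closed by `i·j`,
- `VM(i, j)` and `WM(i, j)` — multibranch-loop decompositions.

`V` takes the minimum over four loop types closed by the pair `i·j`:
hairpin `eH(i, j)`, stacked pair `eS(i, j) + V(i+1, j-1)`, interior or
bulge loop `min_{k,l} eL(i, j, k, l) + V(k, l)`, and a multibranch loop
built from the enclosed interval, `VM(i+1, j-1) + closing penalty`.
Energies are integers in tenths of the model unit (deci-units), so
every comparison is exact.  A single traceback through the filled
tables recovers one optimal structure.

Filling the tables costs `O(n³)` time (interior loops are capped at a
fixed span, the standard device that keeps `VBI` from adding a fourth
factor).  When the task is not one long sequence but a batch of many
independent sequences — the common situation in genome-scale screens —
the natural acceleration is to run the batch on two worker classes at
once.  If one class folds a sequence in `t_slow` and the other in
`t_fast`, the speedup is `K = t_slow / t_fast`, and giving the slow
class a fraction `1 / (K + 1)` of the batch makes both classes finish
together.  For a batch of `N`, the integer boundary `B ≈ N / (K + 1)`
minimizing the makespan is computed exactly.  This package implements
both halves: the folding engine (with several provably equivalent fill
orders, including a wavefront/tiled order suitable for parallel
hardware) and the allocation/execution machinery, with a simulated
virtual-clock executor and a real thread-pool executor.

## Worked example

Folding two sequences with the bundled `simple` energy preset:

```
$ printf '>hp\nGGGAAACCC\n>tRNA_like\nGCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAAGA\
UCUGGAGGUCCUGUGUUCGAUCCACAGAAUUCGCACCA\n' > demo.fa
$ zukerfold fold demo.fa -p simple
>hp
GGGAAACCC
(((...))) (-0.9)
>tRNA_like
GCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAAGAUCUGGAGGUCCUGUGUUCGAUCCACAGAAUUCGCACCA
(((((((...((..((..(((((((((((((.......)))))........)))))..)))))))))))))).... (-15.5)
```

The same from Python:

```python
from zukerfold import RnaSequence, fill_matrices, simple_params, to_dot_bracket, traceback

seq = RnaSequence("hp", "GGGAAACCC")
params = simple_params()
m = fill_matrices(seq, params)
s = traceback(m, seq, params)
print(to_dot_bracket(s), m.mfe() / 10)   # (((...))) -0.9
```

Allocating a 20 000-sequence batch between a slow and a fast class
whose measured per-sequence times are 19.059 ms and 3.270 ms:

```
$ zukerfold allocate --t-slow 19.059 --t-fast 3.270 -n 20000
speedup K = 5.83
allocation ratio = 14.64%
boundary B = 2929 of 20000
```

Sweeping the slow-class share confirms the analytic ratio empirically —
the simulated makespan bottoms out at 14 % on a 2 % grid:

```
$ zukerfold sweep --t-slow 19.059 --t-fast 3.270 -n 20000 --length 221
  2.0%     64092.000 ms
  ...
 12.0%     57552.000 ms
 14.0%     56244.000 ms  <- minimum
 16.0%     60988.800 ms
  ...
```

The scripts in `examples/` walk through folding, allocation, and a full
simulated hybrid run (`python examples/hybrid_demo.py`).

## Package layout

- `zukerfold.energy` — energy presets, parameter files, loop energies
- `zukerfold.sequences` — sequence type, FASTA I/O, synthetic batches
- `zukerfold.dp` — matrix fill (naive / wavefront / tiled, bit-identical)
- `zukerfold.structures` — traceback, structure scoring, dot-bracket, CT
- `zukerfold.oracle` — exhaustive enumeration used to validate the DP
- `zukerfold.scheduler` — speedup / ratio / boundary / multi-class plans
- `zukerfold.executor` — simulated and thread-pool batch execution
- `zukerfold.io`, `zukerfold.cli` — result writers and the `zukerfold` CLI

See `docs/methods.md` for the model details, numerical conventions and
design decisions.
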