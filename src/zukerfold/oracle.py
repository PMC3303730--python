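"""Brute-force ground truth for short sequences.

Enumerates every legal nested structure exactly once by interval
recursion (the last base is unpaired, or paired with each admissible
partner), scores each with the same loop decomposition the package
exposes, and reports the exhaustive minimum. Deliberately naive: this
module exists to check the dynamic program, not to be fast.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterator

from .energy import EnergyParams, can_pair
from .sequences import RnaSequence
from .structures import SecondaryStructure, evaluate_structure

__all__ = ["enumerate_structures", "brute_force_mfe", "count_structures"]

DEFAULT_CAP = 20


def _check_cap(seq: RnaSequence, cap: int) -> None:
    if seq.n > cap:
        raise ValueError(
            f"sequence length {seq.n} exceeds the enumeration cap {cap}; "
            "brute force is exponential and meant for short sequences only"
        )


def enumerate_structures(
    seq: RnaSequence, params: EnergyParams, cap: int = DEFAULT_CAP
) -> Iterator[SecondaryStructure]:
    """Yield every non-crossing structure (including the empty one) once.

    Pairing rules and the minimum hairpin size from ``params`` are
    respected at generation time.
    """
    _check_cap(seq, cap)
    mh = params.min_hairpin

    def rec(i: int, j: int) -> Iterator[frozenset]:
        if j - i < mh + 1:  # too short to hold any pair
            yield frozenset()
            return
        yield from rec(i, j - 1)  # j unpaired
        for p in range(i, j - mh):
            if can_pair(seq[p], seq[j], params):
                for left in rec(i, p - 1):
                    for inner in rec(p + 1, j - 1):
                        yield left | inner | {(p, j)}

    for pairset in rec(1, seq.n):
        yield SecondaryStructure(n=seq.n, pairs=pairset)


def count_structures(seq: RnaSequence, params: EnergyParams) -> int:
    """Number of legal structures via an independent counting recurrence
    (a Motzkin-style interval DP), without generating them."""
    mh = params.min_hairpin

    @lru_cache(maxsize=None)
    def c(i: int, j: int) -> int:
        if j - i < mh + 1:
            return 1
        total = c(i, j - 1)
        for p in range(i, j - mh):
            if can_pair(seq[p], seq[j], params):
                total += c(i, p - 1) * c(p + 1, j - 1)
        return total

    return c(1, seq.n)


def brute_force_mfe(
    seq: RnaSequence, params: EnergyParams, cap: int = DEFAULT_CAP
) -> tuple[int, SecondaryStructure]:
    """Exhaustive minimum of evaluate_structure over all structures.

    Returns (energy in deci-units, one arg-min); the empty structure
    (energy 0) wins when nothing is stabilising, so the energy is <= 0.
    """
    _check_cap(seq, cap)
    best_e = 0
    best_s = SecondaryStructure(n=seq.n, pairs=frozenset())
    for s in enumerate_structures(seq, params, cap=cap):
        e = evaluate_structure(seq, s, params)
        if e < best_e:
            best_e, best_s = e, s
    return best_e, best_s
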