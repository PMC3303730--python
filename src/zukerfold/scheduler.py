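"""Static task allocation between heterogeneous worker classes.

For a batch of N similar-length sequences split between a slow class
(host processor) and a fast class (accelerator), balance requires
t_slow * B = t_fast * (N - B), giving the boundary B = N / (K + 1) where
K = t_slow / t_fast is the fast-over-slow speedup and 1 / (K + 1) is the
allocation ratio: the workload fraction handed to the slow class.
Sequences 1..B go to the slow class, B+1..N to the fast one. The scheme
generalises to more than two classes by splitting N proportionally to
each class's processing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "WorkerProfile",
    "AllocationPlan",
    "speedup",
    "allocation_ratio",
    "boundary",
    "partition",
    "make_plan",
    "allocate_multi",
    "round_half_up",
    "load_profiles",
    "save_profiles",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places (printed convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class WorkerProfile:
    """Estimated per-sequence fill time (ms) by length for one worker class."""

    name: str
    t_per_seq: Mapping[int, float]
    capacity: int = 1

    def __post_init__(self) -> None:
        if not self.t_per_seq:
            raise ValueError(f"profile {self.name!r} has no time estimates")
        if any(t <= 0 for t in self.t_per_seq.values()):
            raise ValueError(f"profile {self.name!r} has non-positive times")
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")

    def time_for(self, length: int) -> float:
        """Per-sequence estimate; unknown lengths scale cubically from the
        nearest calibrated length (matrix fill cost grows as n^3)."""
        if length in self.t_per_seq:
            return self.t_per_seq[length]
        nearest = min(self.t_per_seq, key=lambda L: (abs(L - length), L))
        return self.t_per_seq[nearest] * (length / nearest) ** 3


@dataclass(frozen=True)
class AllocationPlan:
    """Partition of sequence indices 1..N across worker classes."""

    N: int
    batches: dict[str, list[int]] = field(default_factory=dict)
    K: float | None = None       # fast-over-slow speedup (two-class plans)
    ratio: float | None = None   # 1 / (K + 1)
    B: int | None = None         # boundary: size of the slow batch

    def __post_init__(self) -> None:
        flat = [i for ids in self.batches.values() for i in ids]
        if sorted(flat) != list(range(1, self.N + 1)):
            raise ValueError("batches must partition 1..N")


def speedup(t_slow: float, t_fast: float) -> float:
    """K = t_slow / t_fast, the fast class's speedup over the slow one."""
    if t_slow <= 0 or t_fast <= 0:
        raise ValueError("per-sequence times must be positive")
    return t_slow / t_fast


def allocation_ratio(K: float) -> float:
    """Fraction of the workload for the slow class, 1 / (K + 1)."""
    if K <= 0:
        raise ValueError("speedup must be positive")
    return 1.0 / (K + 1.0)


def _makespan(B: int, N: int, t_slow: float, t_fast: float) -> float:
    return max(t_slow * B, t_fast * (N - B))


def boundary(N: int, t_slow: float, t_fast: float) -> int:
    """Integer boundary B minimising makespan max(t_slow*B, t_fast*(N-B)).

    The continuous balance point is N / (K + 1); because the two loads
    are monotone in B the integer optimum is its floor or ceiling. Ties
    break toward the smaller load imbalance, then the smaller B.
    """
    if N < 0:
        raise ValueError("N must be >= 0")
    if t_slow <= 0 or t_fast <= 0:
        raise ValueError("per-sequence times must be positive")
    if N == 0:
        return 0
    x = N * allocation_ratio(speedup(t_slow, t_fast))
    lo = max(0, min(N, int(x)))
    candidates = sorted({lo, min(N, lo + 1)})
    return min(
        candidates,
        key=lambda b: (
            _makespan(b, N, t_slow, t_fast),
            abs(t_slow * b - t_fast * (N - b)),
            b,
        ),
    )


def partition(sequence_ids: Sequence[int], B: int) -> dict[str, list[int]]:
    """Slow class takes the first B ids, fast class the rest."""
    if not 0 <= B <= len(sequence_ids):
        raise ValueError(f"boundary {B} outside 0..{len(sequence_ids)}")
    ids = list(sequence_ids)
    return {"slow": ids[:B], "fast": ids[B:]}


def make_plan(N: int, t_slow: float, t_fast: float) -> AllocationPlan:
    """Full two-class plan from per-sequence time estimates."""
    K = speedup(t_slow, t_fast)
    B = boundary(N, t_slow, t_fast)
    return AllocationPlan(
        N=N,
        batches=partition(list(range(1, N + 1)), B),
        K=K,
        ratio=allocation_ratio(K),
        B=B,
    )


def allocate_multi(
    profiles: Sequence[WorkerProfile], N: int, length: int | None = None
) -> AllocationPlan:
    """Split N sequences across any number of classes, proportional to
    each class's rate (capacity / per-sequence time), integerised by
    largest remainder; contiguous index ranges in profile order."""
    if not profiles:
        raise ValueError("need at least one worker profile")
    if N < 0:
        raise ValueError("N must be >= 0")
    if length is None:
        lengths = {L for p in profiles for L in p.t_per_seq}
        if len(lengths) != 1:
            raise ValueError("ambiguous profiles: pass the sequence length")
        length = lengths.pop()
    rates = [p.capacity / p.time_for(length) for p in profiles]
    total = sum(rates)
    quotas = [N * r / total for r in rates]
    sizes = [int(q) for q in quotas]
    # largest remainder, ties to the earlier profile
    order = sorted(
        range(len(profiles)), key=lambda idx: (-(quotas[idx] - sizes[idx]), idx)
    )
    for idx in order[: N - sum(sizes)]:
        sizes[idx] += 1
    batches: dict[str, list[int]] = {}
    start = 1
    for p, size in zip(profiles, sizes):
        batches[p.name] = list(range(start, start + size))
        start += size
    plan = AllocationPlan(N=N, batches=batches, B=sizes[0] if profiles else None)
    return plan


# -- profile config files (YAML) ---------------------------------------


def load_profiles(path: str | Path) -> list[WorkerProfile]:
    """Read worker profiles from a YAML file::

        classes:
          - name: cpu
            capacity: 1
            times: {68: 1.081, 120: 4.737}
    """
    data = yaml.safe_load(Path(path).read_text())
    try:
        return [
            WorkerProfile(
                name=c["name"],
                t_per_seq={int(k): float(v) for k, v in c["times"].items()},
                capacity=int(c.get("capacity", 1)),
            )
            for c in data["classes"]
        ]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed profile config ({exc})") from None


def save_profiles(path: str | Path, profiles: Sequence[WorkerProfile]) -> None:
    data = {
        "classes": [
            {
                "name": p.name,
                "capacity": p.capacity,
                "times": {int(k): float(v) for k, v in p.t_per_seq.items()},
            }
            for p in profiles
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
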