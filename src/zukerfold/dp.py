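"""Minimum-free-energy folding recurrences over triangular energy matrices.

The model fills five objects for a sequence r1..rn:

* ``W(j)``   — optimal energy of the prefix r1..rj (W(0) = 0); the MFE of
  the whole sequence is W(n).
* ``V(i,j)`` — optimal energy of ri..rj given that (i, j) is paired;
  the minimum of a hairpin closure, a stack on (i+1, j-1), an internal
  loop/bulge closure (VBI) and a multibranch closure (VM).
* ``VBI(i,j)`` — best internal loop: min over i<k<l<j of eL(i,j,k,l) + V(k,l),
  with the total unpaired span capped at ``max_internal_span`` (this cap
  is what brings the fill to O(n^3)).
* ``VM(i,j)`` — best bifurcation: min over i<k<j of WM(i,k) + WM(k+1,j).
* ``WM(i,j)`` — best arrangement of >=1 branches in ri..rj, used inside
  multiloops: min of VM(i,j), WM(i+1,j) and WM(i,j-1) (each plus the
  per-unpaired-base constant) and V(i,j) (plus the per-branch constant).

V's multibranch option closes the loop around the enclosed interval:
V(i,j) = VM(i+1, j-1) + closing constant. VM itself is the pure
bifurcation minimum of its interval (no constant), which is also the
multi-branch route inside WM; indexing the closure through the interior
keeps the closing pair's own positions out of the branches. With all
multibranch constants zero (the default) the scores are the classical
literal recurrences.

Three fill orders are provided and produce bit-identical matrices:
``naive`` (row/column sweep), ``wavefront`` (anti-diagonal phases) and
``tiled`` (anti-diagonal waves of square tiles with chunked bifurcation
minima, the host-side analogue of a shared-memory tiling scheme).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .energy import INF, INF_CAP, EnergyParams, eadd
from .sequences import RnaSequence

__all__ = [
    "EnergyMatrices",
    "TileSchedule",
    "fill_matrices",
    "compute_W",
    "compute_V",
    "compute_VBI",
    "compute_VM",
    "compute_WM",
    "wavefront_order",
    "validate_schedule",
    "dump_matrices",
    "ConfigurationError",
]

FILL_STRATEGIES = ("naive", "wavefront", "tiled")
VM_STRATEGIES = ("naive", "two_step", "tiled")


class ConfigurationError(ValueError):
    """Unknown strategy or invalid run configuration."""


@dataclass
class EnergyMatrices:
    """Filled triangular matrices; all arrays 1-based (index 0 unused)."""

    n: int
    W: np.ndarray    # shape (n+1,), W[0] == 0
    V: np.ndarray    # shape (n+2, n+2), INF outside i<j
    VBI: np.ndarray
    VM: np.ndarray
    WM: np.ndarray

    @classmethod
    def empty(cls, n: int) -> "EnergyMatrices":
        def tri() -> np.ndarray:
            return np.full((n + 2, n + 2), INF, dtype=np.int64)

        W = np.zeros(n + 1, dtype=np.int64)
        return cls(n=n, W=W, V=tri(), VBI=tri(), VM=tri(), WM=tri())

    def mfe(self) -> int:
        """Minimum free energy of the whole sequence, W(n), deci-units."""
        return int(self.W[self.n])


@dataclass(frozen=True)
class TileSchedule:
    """Ordered phases of mutually independent cells covering the triangle.

    Every cell appears in exactly one phase and depends only on cells in
    strictly earlier phases. Tiles are ``tile_size`` x ``tile_size``
    blocks; waves of tiles move away from the main diagonal and each
    phase is the slice of one anti-diagonal inside the current wave.
    With tile_size 1 phase d is exactly the anti-diagonal j - i = d.
    """

    n: int
    tile_size: int
    phases: tuple[tuple[tuple[int, int], ...], ...]

    def cells(self) -> Iterator[tuple[int, int]]:
        for phase in self.phases:
            yield from phase


def wavefront_order(n: int, tile_size: int = 1) -> TileSchedule:
    if n < 1 or tile_size < 1:
        raise ValueError("need n >= 1 and tile_size >= 1")
    s = tile_size
    buckets: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for i in range(1, n):
        ti = (i - 1) // s
        for j in range(i + 1, n + 1):
            wave = (j - 1) // s - ti
            buckets.setdefault((wave, j - i), []).append((i, j))
    phases = tuple(tuple(buckets[key]) for key in sorted(buckets))
    return TileSchedule(n=n, tile_size=s, phases=phases)


def validate_schedule(schedule: TileSchedule, exhaustive: bool = False) -> bool:
    """Check the TileSchedule invariants; raises AssertionError on failure.

    The cover check (each cell later than (i+1, j) and (i, j-1)) implies
    the full nested-dependency property by transitivity; ``exhaustive``
    additionally verifies every nested cell directly.
    """
    n = schedule.n
    phase_of: dict[tuple[int, int], int] = {}
    for p, phase in enumerate(schedule.phases):
        for cell in phase:
            assert cell not in phase_of, f"cell {cell} scheduled twice"
            phase_of[cell] = p
    assert len(phase_of) == n * (n - 1) // 2, "schedule does not cover the triangle"
    for (i, j), p in phase_of.items():
        for dep in ((i + 1, j), (i, j - 1)):
            if dep[0] < dep[1]:
                assert phase_of[dep] < p, f"{(i, j)} not after its dependency {dep}"
    if exhaustive:
        for (i, j), p in phase_of.items():
            for i2 in range(i, j + 1):
                for j2 in range(i2 + 1, j + 1):
                    if (i2, j2) != (i, j):
                        assert phase_of[(i2, j2)] < p
    return True


def _chunked_min(sums: np.ndarray, chunk: int) -> int:
    """Min of per-chunk minima; the tiled (precomputed-partials) reduction."""
    best = INF
    for off in range(0, sums.size, chunk):
        part = int(sums[off:off + chunk].min())
        if part < best:
            best = part
    return best


class _Filler:
    """Per-sequence fill state: encoded bases, pair mask, penalty arrays."""

    def __init__(self, seq: RnaSequence, params: EnergyParams):
        self.seq = seq
        self.params = params
        n = seq.n
        self.n = n
        bases = " " + seq.bases  # 1-based
        allowed = params.pairs
        P = np.zeros((n + 2, n + 2), dtype=bool)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                P[i, j] = (bases[i], bases[j]) in allowed
        self.P = P
        self.bases = bases
        span = params.max_internal_span
        self.hp = np.array(
            [params.hairpin(s) for s in range(n + 1)], dtype=np.int64
        )
        self.bulge = np.array(
            [params.bulge(s) for s in range(span + 1)], dtype=np.int64
        )
        self.internal = np.array(
            [params.internal(s) for s in range(span + 1)], dtype=np.int64
        )
        self.m = EnergyMatrices.empty(n)

    # -- per-cell recurrences (order-independent pure minima) ---------

    def cell_vbi(self, i: int, j: int) -> int:
        if not self.P[i, j] or j - i < 4:
            return INF
        params, V = self.params, self.m.V
        span = params.max_internal_span
        best = INF
        kmax = min(j - 2, i + 1 + span)
        for k in range(i + 1, kmax + 1):
            n1 = k - i - 1
            rem = span - n1
            l_hi = j - 1 if n1 >= 1 else j - 2  # n1 == n2 == 0 is the stack case
            l_lo = max(k + 1, j - 1 - rem)
            if l_lo > l_hi:
                continue
            vrow = V[k, l_lo:l_hi + 1]
            n2 = j - 1 - np.arange(l_lo, l_hi + 1)
            if n1 == 0:
                pen = self.bulge[n2]
            else:
                pen = self.internal[n1 + n2]
                if n2[-1] == 0:
                    pen = pen.copy()
                    pen[-1] = self.bulge[n1]
            cand = int((vrow + pen).min())
            if cand < best:
                best = cand
        return INF if best >= INF_CAP else best + params.pair_bonus

    def cell_vm(self, i: int, j: int, chunk: int | None = None) -> int:
        if j - i < 2:
            return INF
        WM = self.m.WM
        sums = WM[i, i + 1:j] + WM[i + 2:j + 1, j]
        best = _chunked_min(sums, chunk) if chunk else int(sums.min())
        return INF if best >= INF_CAP else best

    def cell_v(self, i: int, j: int, vbi: int) -> int:
        # The multibranch option bifurcates over the *enclosed* interval:
        # V = closing + VM(i+1, j-1). Reusing VM(i, j) here would book
        # the closing pair's own positions into a branch.
        if not self.P[i, j]:
            return INF
        params = self.params
        loop = j - i - 1
        v = INF
        if loop >= params.min_hairpin:
            v = self.hp[loop] + params.pair_bonus
        if j - i >= 3 and self.P[i + 1, j - 1]:
            stk = params.stack_energy(
                (self.bases[i], self.bases[j]),
                (self.bases[i + 1], self.bases[j - 1]),
            )
            v = min(v, eadd(stk, int(self.m.V[i + 1, j - 1])))
        v = min(v, vbi)
        if j - i >= 2:
            v = min(v, eadd(int(self.m.VM[i + 1, j - 1]), params.multibranch_closing))
        return INF if v >= INF_CAP else int(v)

    def cell_wm(self, i: int, j: int, v: int, vm: int) -> int:
        params = self.params
        wm = min(
            vm,
            eadd(int(self.m.WM[i + 1, j]), params.multibranch_unpaired),
            eadd(int(self.m.WM[i, j - 1]), params.multibranch_unpaired),
            eadd(v, params.multibranch_branch),
        )
        return INF if wm >= INF_CAP else wm

    def fill_cell(self, i: int, j: int, vm_chunk: int | None = None) -> None:
        m = self.m
        vbi = self.cell_vbi(i, j)
        vm = self.cell_vm(i, j, chunk=vm_chunk)
        v = self.cell_v(i, j, vbi)
        m.VBI[i, j] = vbi
        m.VM[i, j] = vm
        m.V[i, j] = v
        m.WM[i, j] = self.cell_wm(i, j, v, vm)

    def fill_w(self) -> None:
        m, n = self.m, self.n
        m.W[0] = 0
        for j in range(1, n + 1):
            w = int(m.W[j - 1])
            if j > 1:
                cand = int((m.V[1:j, j] + m.W[0:j - 1]).min())
                if cand < w:
                    w = cand
            m.W[j] = w


def fill_matrices(
    seq: RnaSequence,
    params: EnergyParams,
    strategy: str = "wavefront",
    tile_size: int = 1,
) -> EnergyMatrices:
    """Fill all energy matrices; W(n) is the sequence's MFE.

    The result is independent of ``strategy`` and ``tile_size``; they
    select provably equivalent evaluation orders.
    """
    if seq.n < 1:
        raise ValueError("sequence must have length >= 1")
    if strategy not in FILL_STRATEGIES:
        raise ConfigurationError(
            f"unknown fill strategy {strategy!r}; choose from {FILL_STRATEGIES}"
        )
    f = _Filler(seq, params)
    if strategy == "naive":
        for i in range(seq.n, 0, -1):
            for j in range(i + 1, seq.n + 1):
                f.fill_cell(i, j)
    else:
        chunk = tile_size if strategy == "tiled" else None
        for i, j in wavefront_order(seq.n, tile_size).cells():
            f.fill_cell(i, j, vm_chunk=chunk)
    f.fill_w()
    return f.m


# -- standalone recurrence evaluators (read already-filled matrices) --


def compute_W(j: int, matrices: EnergyMatrices) -> int:
    """W(j) = min{ W(j-1), min over 1<=i<j of V(i,j) + W(i-1) }."""
    if j < 1 or j > matrices.n:
        raise ValueError(f"j out of range 1..{matrices.n}")
    w = int(matrices.W[j - 1])
    for i in range(1, j):
        w = min(w, eadd(int(matrices.V[i, j]), int(matrices.W[i - 1])))
    return w


def compute_V(
    i: int, j: int, seq: RnaSequence, params: EnergyParams, matrices: EnergyMatrices
) -> int:
    f = _filler_view(seq, params, matrices)
    return f.cell_v(i, j, int(matrices.VBI[i, j]))


def compute_VBI(
    i: int, j: int, seq: RnaSequence, params: EnergyParams, matrices: EnergyMatrices
) -> int:
    return _filler_view(seq, params, matrices).cell_vbi(i, j)


def compute_VM(
    i: int,
    j: int,
    matrices: EnergyMatrices,
    strategy: str = "naive",
    tile_size: int = 4,
) -> int:
    """Bifurcation minimum min over i<k<j of WM(i,k) + WM(k+1,j).

    ``naive`` is a scalar loop (the reference), ``two_step`` adds the
    WM row to the WM column and then reduces (the vectorised form) and
    ``tiled`` reduces per chunk before combining; all bit-identical.
    """
    if strategy not in VM_STRATEGIES:
        raise ConfigurationError(
            f"unknown VM strategy {strategy!r}; choose from {VM_STRATEGIES}"
        )
    if j - i < 2:
        return INF
    WM = matrices.WM
    if strategy == "naive":
        best = INF
        for k in range(i + 1, j):
            cand = eadd(int(WM[i, k]), int(WM[k + 1, j]))
            if cand < best:
                best = cand
        return best
    sums = WM[i, i + 1:j] + WM[i + 2:j + 1, j]
    best = _chunked_min(sums, tile_size) if strategy == "tiled" else int(sums.min())
    return INF if best >= INF_CAP else best


def compute_WM(
    i: int, j: int, matrices: EnergyMatrices, params: EnergyParams
) -> int:
    return min(
        int(matrices.VM[i, j]) if int(matrices.VM[i, j]) < INF_CAP else INF,
        eadd(int(matrices.WM[i + 1, j]), params.multibranch_unpaired),
        eadd(int(matrices.WM[i, j - 1]), params.multibranch_unpaired),
        eadd(int(matrices.V[i, j]), params.multibranch_branch),
    )


def _filler_view(seq: RnaSequence, params: EnergyParams, matrices: EnergyMatrices):
    f = _Filler(seq, params)
    f.m = matrices
    return f


def dump_matrices(matrices: EnergyMatrices, path: str | Path) -> None:
    """Plain-text triangular dump of W and V ('inf' for forbidden cells)."""
    n = matrices.n
    lines = ["# W vector: j value", *(
        f"{j} {int(matrices.W[j])}" for j in range(n + 1)
    ), "# V matrix: i j value"]
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            v = int(matrices.V[i, j])
            lines.append(f"{i} {j} {'inf' if v >= INF_CAP else v}")
    Path(path).write_text("\n".join(lines) + "\n")
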