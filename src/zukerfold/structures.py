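"""Secondary structures: traceback, loop-decomposition scoring, notation.

A secondary structure is a set of non-crossing (nested, pseudoknot-free)
base pairs. ``traceback`` recovers one optimal structure from filled
matrices; ``evaluate_structure`` independently re-scores any structure
by decomposing it into hairpins, stacks, internal loops/bulges and
multibranch loops, so that evaluate(traceback(fill(...))) == W(n) is an
exact integer identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .energy import INF, INF_CAP, EnergyParams, eH, eL, eS, eadd
from .dp import EnergyMatrices
from .sequences import RnaSequence

__all__ = [
    "SecondaryStructure",
    "TracebackError",
    "traceback",
    "evaluate_structure",
    "to_dot_bracket",
    "from_dot_bracket",
    "write_ct",
    "read_ct",
]


class TracebackError(RuntimeError):
    """No recurrence option reproduces a stored minimum (corrupt matrices)."""


@dataclass(frozen=True)
class SecondaryStructure:
    """Non-crossing pair set over positions 1..n."""

    n: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise ValueError(f"pair ({i}, {j}) outside 1..{self.n}")
            if i in seen or j in seen:
                raise ValueError(f"position reused by pair ({i}, {j})")
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1:]:
                if k >= j:
                    break
                if not l < j:  # i < k < j < l
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")

    @classmethod
    def make(cls, n: int, pairs) -> "SecondaryStructure":
        return cls(n=n, pairs=frozenset(tuple(sorted(p)) for p in pairs))

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def to_dot_bracket(structure: SecondaryStructure) -> str:
    chars = ["."] * structure.n
    for i, j in structure.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def from_dot_bracket(s: str) -> SecondaryStructure:
    stack: list[int] = []
    pairs = set()
    for pos, c in enumerate(s, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif c != ".":
            raise ValueError(f"illegal dot-bracket character {c!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(n=len(s), pairs=frozenset(pairs))


# -- loop decomposition ------------------------------------------------


def _children(
    structure: SecondaryStructure,
) -> tuple[list[tuple[int, int]], dict[tuple[int, int], list[tuple[int, int]]]]:
    """Direct inner pairs of each pair, plus the exterior branch list."""
    kids: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in structure.pairs}
    exterior: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for pair in sorted(structure.pairs):
        while stack and pair[0] > stack[-1][1]:
            stack.pop()
        (kids[stack[-1]] if stack else exterior).append(pair)
        stack.append(pair)
    return exterior, kids


def evaluate_structure(
    seq: RnaSequence, structure: SecondaryStructure, params: EnergyParams
) -> int:
    """Total energy by loop decomposition; INF if any pair is disallowed.

    Exterior (unpaired-in-W) bases carry zero energy; a loop with >= 2
    inner branches is a multibranch loop scored by the affine constants.
    """
    if structure.n != seq.n:
        raise ValueError("structure length does not match the sequence")
    _, kids = _children(structure)
    total = 0
    for (i, j), cs in kids.items():
        if not cs:
            total = eadd(total, eH(i, j, seq, params))
        elif len(cs) == 1:
            k, l = cs[0]
            if k == i + 1 and l == j - 1:
                total = eadd(total, eS(i, j, seq, params))
            else:
                total = eadd(total, eL(i, j, k, l, seq, params))
        else:
            if (seq[i], seq[j]) not in params.pairs:
                return INF
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in cs)
            total = eadd(
                total,
                params.multibranch_closing,
                params.multibranch_branch * len(cs),
                params.multibranch_unpaired * unpaired,
            )
        if total >= INF_CAP:
            return INF
    return total


# -- traceback ---------------------------------------------------------


def traceback(
    matrices: EnergyMatrices, seq: RnaSequence, params: EnergyParams
) -> SecondaryStructure:
    """Recover one optimal structure whose energy is exactly W(n).

    Options are re-tested in the canonical order (hairpin, stack,
    internal loop with ascending k then descending l, multibranch;
    bifurcations by ascending k), so the result is deterministic.
    """
    n = seq.n
    V, VBI, VM, WM, W = matrices.V, matrices.VBI, matrices.VM, matrices.WM, matrices.W
    pairs: set[tuple[int, int]] = set()
    agenda: list[tuple] = [("W", n)]

    def fail(kind: str, i: int, j: int) -> TracebackError:
        return TracebackError(f"no option reproduces {kind}({i},{j})")

    while agenda:
        task = agenda.pop()
        kind = task[0]
        if kind == "W":
            j = task[1]
            if j <= 0:
                continue
            target = int(W[j])
            if target == int(W[j - 1]):
                agenda.append(("W", j - 1))
                continue
            for i in range(1, j):
                if eadd(int(V[i, j]), int(W[i - 1])) == target:
                    agenda.append(("V", i, j))
                    agenda.append(("W", i - 1))
                    break
            else:
                raise fail("W", 0, j)
        elif kind == "V":
            _, i, j = task
            target = int(V[i, j])
            pairs.add((i, j))
            if eH(i, j, seq, params) == target:
                continue
            if j - i >= 3 and eadd(eS(i, j, seq, params), int(V[i + 1, j - 1])) == target:
                agenda.append(("V", i + 1, j - 1))
                continue
            if int(VBI[i, j]) == target:
                if _trace_internal(i, j, target, seq, params, V, agenda):
                    continue
            if (
                j - i >= 2
                and eadd(int(VM[i + 1, j - 1]), params.multibranch_closing) == target
            ):
                agenda.append(("VMsplit", i + 1, j - 1))
                continue
            raise fail("V", i, j)
        elif kind == "VMsplit":
            _, i, j = task
            target = int(VM[i, j])
            for k in range(i + 1, j):
                if eadd(int(WM[i, k]), int(WM[k + 1, j])) == target:
                    agenda.append(("WM", i, k))
                    agenda.append(("WM", k + 1, j))
                    break
            else:
                raise fail("VM", i, j)
        else:  # WM
            _, i, j = task
            target = int(WM[i, j])
            if eadd(int(V[i, j]), params.multibranch_branch) == target:
                agenda.append(("V", i, j))
            elif int(VM[i, j]) == target:
                agenda.append(("VMsplit", i, j))
            elif eadd(int(WM[i + 1, j]), params.multibranch_unpaired) == target:
                agenda.append(("WM", i + 1, j))
            elif eadd(int(WM[i, j - 1]), params.multibranch_unpaired) == target:
                agenda.append(("WM", i, j - 1))
            else:
                raise fail("WM", i, j)
    return SecondaryStructure(n=n, pairs=frozenset(pairs))


def _trace_internal(i, j, target, seq, params, V, agenda) -> bool:
    span = params.max_internal_span
    for k in range(i + 1, min(j - 1, i + 2 + span)):
        n1 = k - i - 1
        for l in range(j - 1, k, -1):
            n2 = j - l - 1
            if n1 + n2 < 1 or n1 + n2 > span:
                continue
            if eadd(eL(i, j, k, l, seq, params), int(V[k, l])) == target:
                agenda.append(("V", k, l))
                return True
    return False


# -- CT (connect) format ----------------------------------------------


def write_ct(
    path: str | Path,
    seq: RnaSequence,
    structure: SecondaryStructure,
    energy_deci: int | None = None,
) -> None:
    """Write the connect format: header 'n  id', then per-position rows
    'index base prev next pair_index index' (0 for unpaired/ends)."""
    partner = structure.partner()
    header = f"{seq.n}  {seq.id}"
    if energy_deci is not None and energy_deci < INF_CAP:
        header += f"  dG = {energy_deci / 10:.1f}"
    rows = [header]
    for i in range(1, seq.n + 1):
        nxt = i + 1 if i < seq.n else 0
        rows.append(f"{i} {seq[i]} {i - 1} {nxt} {partner.get(i, 0)} {i}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_ct(path: str | Path) -> tuple[RnaSequence, SecondaryStructure]:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    head = lines[0].split()
    n, sid = int(head[0]), head[1]
    bases = []
    pairs = set()
    for row in lines[1:n + 1]:
        tok = row.split()
        idx, base, pair_idx = int(tok[0]), tok[1], int(tok[4])
        bases.append(base)
        if pair_idx and idx < pair_idx:
            pairs.add((idx, pair_idx))
    return (
        RnaSequence(id=sid, bases="".join(bases)),
        SecondaryStructure(n=n, pairs=frozenset(pairs)),
    )
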