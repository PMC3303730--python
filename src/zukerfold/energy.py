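"""Thermodynamic energy model for nested RNA secondary structures.

Everything the folding recurrences consume lives here: the pairing rules,
the three loop free-energy functions ``eH`` (hairpin), ``eS`` (stacked
pair) and ``eL`` (internal loop / bulge), the affine multibranch
constants, and the parameter presets.

Energies are integers in *deci-units*: 10 deci-units equal one printed
energy unit (conventionally kcal/mol). Integer arithmetic makes
min-reductions and traceback tie-breaking exactly reproducible. Infinity
is a large integer sentinel with saturating addition, see :data:`INF`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "INF",
    "is_inf",
    "eadd",
    "BASES",
    "EnergyParams",
    "can_pair",
    "eH",
    "eS",
    "eL",
    "load_params",
    "save_params",
    "nussinov_params",
    "simple_params",
]

#: Infinity sentinel (deci-units). Any value >= INF_CAP is treated as
#: infinite, so that INF plus a small finite term still saturates.
INF: int = 1 << 40
INF_CAP: int = INF >> 1

BASES = ("A", "C", "G", "U")

WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE = frozenset({("G", "U"), ("U", "G")})


def is_inf(x: int) -> bool:
    """True when ``x`` represents an infinite (forbidden) energy."""
    return x >= INF_CAP


def eadd(*terms: int) -> int:
    """Saturating sum: infinite if any term is infinite."""
    total = 0
    for t in terms:
        if t >= INF_CAP:
            return INF
        total += t
    return total


def _norm(x: int) -> int:
    return INF if x >= INF_CAP else x


class ParameterError(ValueError):
    """Malformed preset name or parameter file."""


@dataclass(frozen=True)
class EnergyParams:
    """All tunable constants of the nearest-neighbour energy model.

    Size-penalty tables are sparse maps size -> deci-units; lookups
    outside the tabulated range hold the nearest tabulated value
    constant (clamped extrapolation), and an empty table means zero for
    every size.
    """

    name: str = "custom"
    pairs: frozenset[tuple[str, str]] = WATSON_CRICK | WOBBLE
    min_hairpin: int = 3
    max_internal_span: int = 30
    #: added for the closing pair inside eH and eL (and, via
    #: multibranch_closing, for multiloop-closing pairs)
    pair_bonus: int = 0
    stack: Mapping[tuple[str, str], int] = field(default_factory=dict)
    #: fallback stacking energy when a pair combination is not tabulated;
    #: None means untabulated combinations are forbidden (infinite)
    stack_default: int | None = None
    hairpin_penalty: Mapping[int, int] = field(default_factory=dict)
    bulge_penalty: Mapping[int, int] = field(default_factory=dict)
    internal_penalty: Mapping[int, int] = field(default_factory=dict)
    multibranch_closing: int = 0
    multibranch_branch: int = 0
    multibranch_unpaired: int = 0

    def __post_init__(self) -> None:
        if self.min_hairpin < 1:
            raise ParameterError("min_hairpin must be >= 1")
        if self.max_internal_span < 2:
            raise ParameterError("max_internal_span must be >= 2")
        for a, b in self.pairs:
            if a not in BASES or b not in BASES:
                raise ParameterError(f"pair rule with non-RNA base: {a}{b}")

    # -- lookups -----------------------------------------------------

    def size_penalty(self, table: Mapping[int, int], size: int) -> int:
        """Clamped table lookup; empty table scores 0 for all sizes."""
        if not table:
            return 0
        if size in table:
            return table[size]
        lo, hi = min(table), max(table)
        return table[lo] if size < lo else table[hi]

    def hairpin(self, size: int) -> int:
        return self.size_penalty(self.hairpin_penalty, size)

    def bulge(self, size: int) -> int:
        return self.size_penalty(self.bulge_penalty, size)

    def internal(self, size: int) -> int:
        return self.size_penalty(self.internal_penalty, size)

    def stack_energy(self, outer: tuple[str, str], inner: tuple[str, str]) -> int:
        key = (outer[0] + outer[1], inner[0] + inner[1])
        if key in self.stack:
            return self.stack[key]
        if self.stack_default is None:
            return INF
        return self.stack_default


def can_pair(a: str, b: str, params: EnergyParams) -> bool:
    """Whether bases ``a`` and ``b`` may form a pair; symmetric by rule set."""
    if a not in BASES or b not in BASES:
        raise ValueError(f"invalid RNA base: {a!r}/{b!r}")
    return (a, b) in params.pairs


def _check_range(seq, *positions: int) -> None:
    for p in positions:
        if not 1 <= p <= seq.n:
            raise ValueError(f"position {p} out of range 1..{seq.n}")


def eH(i: int, j: int, seq, params: EnergyParams) -> int:
    """Hairpin loop closed by pair (i, j); 1-based positions."""
    _check_range(seq, i, j)
    if i >= j:
        raise ValueError(f"need i < j, got ({i}, {j})")
    loop = j - i - 1
    if loop < params.min_hairpin or not can_pair(seq[i], seq[j], params):
        return INF
    return _norm(params.hairpin(loop) + params.pair_bonus)


def eS(i: int, j: int, seq, params: EnergyParams) -> int:
    """Stacking of pair (i, j) on the adjacent inner pair (i+1, j-1)."""
    _check_range(seq, i, j)
    if j - i < 3:
        raise ValueError(f"stack needs j - i >= 3, got ({i}, {j})")
    if not can_pair(seq[i], seq[j], params):
        return INF
    if not can_pair(seq[i + 1], seq[j - 1], params):
        return INF
    return _norm(params.stack_energy((seq[i], seq[j]), (seq[i + 1], seq[j - 1])))


def eL(i: int, j: int, k: int, l: int, seq, params: EnergyParams) -> int:
    """Internal loop or bulge between outer pair (i, j) and inner (k, l)."""
    _check_range(seq, i, j, k, l)
    if not (i < k < l < j):
        raise ValueError(f"need i < k < l < j, got ({i}, {k}, {l}, {j})")
    n1, n2 = k - i - 1, j - l - 1
    if n1 + n2 < 1:
        raise ValueError("(i+1, j-1) is the stacking case, not an internal loop")
    if not can_pair(seq[i], seq[j], params) or not can_pair(seq[k], seq[l], params):
        return INF
    if n1 + n2 > params.max_internal_span:
        return INF
    pen = params.bulge(n1 + n2) if (n1 == 0 or n2 == 0) else params.internal(n1 + n2)
    return _norm(pen + params.pair_bonus)


# -- presets ---------------------------------------------------------


def nussinov_params(wobble: bool = True) -> EnergyParams:
    """Unit-per-pair model: every allowed pair contributes -10 deci-units.

    Every closing role of a pair (hairpin, stack, internal loop,
    multiloop) scores exactly -10, so -W(n)/10 is the maximum number of
    nested pairs; used as the pair-maximisation cross-check preset.
    """
    pairs = WATSON_CRICK | WOBBLE if wobble else WATSON_CRICK
    return EnergyParams(
        name="nussinov",
        pairs=frozenset(pairs),
        pair_bonus=-10,
        stack_default=-10,
        multibranch_closing=-10,
    )


_SIMPLE_PAIRS = ("AU", "CG", "GC", "UA", "GU", "UG")

# Stacking deci-energies, outer pair (5'->3') over inner pair; authored
# for this package (negative throughout, strongest for CG/GC cores).
_SIMPLE_STACK = {
    "AU": {"AU": -9, "CG": -22, "GC": -21, "UA": -11, "GU": -6, "UG": -14},
    "CG": {"AU": -21, "CG": -33, "GC": -24, "UA": -21, "GU": -14, "UG": -21},
    "GC": {"AU": -24, "CG": -34, "GC": -33, "UA": -22, "GU": -15, "UG": -25},
    "UA": {"AU": -13, "CG": -24, "GC": -21, "UA": -9, "GU": -10, "UG": -13},
    "GU": {"AU": -13, "CG": -25, "GC": -21, "UA": -14, "GU": -5, "UG": -1},
    "UG": {"AU": -10, "CG": -15, "GC": -14, "UA": -6, "GU": -3, "UG": -5},
}

_SIMPLE_HAIRPIN = {3: 57, 4: 56, 5: 56, 6: 54, 7: 59, 8: 56, 9: 64}
_SIMPLE_BULGE = {1: 38, 2: 28, 3: 32, 4: 36, 5: 40, 6: 44}
_SIMPLE_INTERNAL = {2: 41, 3: 51, 4: 42, 5: 49, 6: 54, 7: 57, 8: 60}


def simple_params() -> EnergyParams:
    """Compact realistic preset: destabilising loop-size penalties,
    stabilising stack table, affine multibranch costs."""
    stack = {
        (o, i): v for o, row in _SIMPLE_STACK.items() for i, v in row.items()
    }
    return EnergyParams(
        name="simple",
        pairs=frozenset((p[0], p[1]) for p in _SIMPLE_PAIRS),
        stack=stack,
        hairpin_penalty=dict(_SIMPLE_HAIRPIN),
        bulge_penalty=dict(_SIMPLE_BULGE),
        internal_penalty=dict(_SIMPLE_INTERNAL),
        multibranch_closing=34,
        multibranch_branch=4,
        multibranch_unpaired=0,
    )


_PRESETS = {"nussinov": nussinov_params, "simple": simple_params}


def load_params(source: str | Path) -> EnergyParams:
    """Load a preset by name ("nussinov", "simple") or a parameter file."""
    if isinstance(source, str) and source in _PRESETS:
        return _PRESETS[source]()
    path = Path(source)
    if not path.exists():
        raise ParameterError(
            f"unknown preset {source!r} (presets: {sorted(_PRESETS)}) "
            "and no such parameter file"
        )
    return _parse_params_file(path)


# -- parameter file format -------------------------------------------
#
#   Scalar lines:    key value          (see _SCALAR_KEYS)
#   Pair rules:      pairs AU UA GC CG GU UG
#   Table blocks:    [hairpin] / [bulge] / [internal]  -> "size value"
#                    [stack]                           -> "OUTER INNER value"
#   '#' starts a comment; blank lines ignored. Writer and reader are
#   inverses (see save_params).

_SCALAR_KEYS = {
    "min_hairpin": int,
    "max_internal_span": int,
    "pair_bonus": int,
    "multibranch_closing": int,
    "multibranch_branch": int,
    "multibranch_unpaired": int,
}
_SIZE_TABLES = {"hairpin": "hairpin_penalty", "bulge": "bulge_penalty",
                "internal": "internal_penalty"}


def _parse_params_file(path: Path) -> EnergyParams:
    kwargs: dict = {"name": path.stem}
    tables: dict[str, dict] = {v: {} for v in _SIZE_TABLES.values()}
    stack: dict[tuple[str, str], int] = {}
    section = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        err = ParameterError(f"{path}:{lineno}: malformed line: {raw.strip()!r}")
        m = re.fullmatch(r"\[(\w+)\]", line)
        if m:
            section = m.group(1)
            if section not in _SIZE_TABLES and section != "stack":
                raise ParameterError(f"{path}:{lineno}: unknown table [{section}]")
            continue
        tok = line.split()
        try:
            if section is None:
                key = tok[0]
                if key == "name":
                    kwargs["name"] = tok[1]
                elif key == "pairs":
                    kwargs["pairs"] = frozenset((p[0], p[1]) for p in tok[1:])
                elif key == "stack_default":
                    kwargs["stack_default"] = None if tok[1] == "inf" else int(tok[1])
                elif key in _SCALAR_KEYS:
                    kwargs[key] = _SCALAR_KEYS[key](tok[1])
                else:
                    raise err
            elif section == "stack":
                outer, inner, val = tok
                stack[(outer, inner)] = int(val)
            else:
                size, val = tok
                tables[_SIZE_TABLES[section]][int(size)] = int(val)
        except (ValueError, IndexError):
            raise err from None
    kwargs.update(tables)
    kwargs["stack"] = stack
    if "stack_default" not in kwargs and not stack:
        kwargs["stack_default"] = 0
    try:
        return EnergyParams(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ParameterError(f"{path}: {exc}") from None


def save_params(params: EnergyParams, path: str | Path) -> None:
    """Write ``params`` in the plain-text format read by load_params."""
    lines = [f"# zukerfold energy parameters", f"name {params.name}"]
    lines.append("pairs " + " ".join(sorted(a + b for a, b in params.pairs)))
    for key in _SCALAR_KEYS:
        lines.append(f"{key} {getattr(params, key)}")
    sd = params.stack_default
    lines.append(f"stack_default {'inf' if sd is None else sd}")
    for section, attr in _SIZE_TABLES.items():
        table = getattr(params, attr)
        if table:
            lines.append(f"[{section}]")
            lines.extend(f"{s} {v}" for s, v in sorted(table.items()))
    if params.stack:
        lines.append("[stack]")
        lines.extend(
            f"{o} {i} {v}" for (o, i), v in sorted(params.stack.items())
        )
    Path(path).write_text("\n".join(lines) + "\n")


def with_overrides(params: EnergyParams, **overrides) -> EnergyParams:
    """Copy of ``params`` with selected fields replaced (e.g. min_hairpin)."""
    return replace(params, **{k: v for k, v in overrides.items() if v is not None})
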