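"""Result writers: dot-bracket blocks and connect (CT) files.

Energies are printed in whole units with one decimal (deci-units / 10);
negative values are stabilising.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from .energy import INF_CAP
from .sequences import RnaSequence
from .structures import SecondaryStructure, to_dot_bracket, write_ct

__all__ = ["format_energy", "write_results", "RESULT_FORMATS"]

RESULT_FORMATS = ("dot_bracket", "ct")


def format_energy(deci: int) -> str:
    """Deci-units rendered in printed units: -30 -> '-3.0'."""
    if deci >= INF_CAP:
        return "inf"
    return f"{deci / 10:.1f}"


def write_results(
    path: str | Path,
    records: Sequence[tuple[RnaSequence, int, SecondaryStructure]],
    format: str = "dot_bracket",
) -> None:
    """Write (sequence, energy, structure) records.

    dot_bracket: three lines per record — '>id', the sequence, then the
    structure with the energy in parentheses, e.g. '(((...))) (-3.0)'.
    ct: concatenated connect-format blocks.
    """
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    if format == "dot_bracket":
        lines = []
        for seq, energy, structure in records:
            lines.append(f">{seq.id}")
            lines.append(seq.bases)
            lines.append(f"{to_dot_bracket(structure)} ({format_energy(energy)})")
        path.write_text("\n".join(lines) + "\n")
    elif format == "ct":
        blocks = []
        for seq, energy, structure in records:
            tmp = path.parent / (path.name + ".part")
            write_ct(tmp, seq, structure, energy_deci=energy)
            blocks.append(tmp.read_text())
            tmp.unlink()
        path.write_text("".join(blocks))
    else:
        raise ValueError(f"unknown result format {format!r}; use {RESULT_FORMATS}")
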