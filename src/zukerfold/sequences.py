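"""RNA sequence container, FASTA input and the synthetic-sequence generator.

Positions are 1-based throughout the public API, matching the r1..rn
convention of the folding recurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .energy import BASES

__all__ = ["RnaSequence", "FastaError", "read_fasta", "write_fasta",
           "generate_random_sequences"]

_VALID = set("ACGU")
_INPUT_OK = set("ACGUTacgut")


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA sequence over {A, C, G, U}, addressed 1..n."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("empty sequence")
        bad = set(self.bases) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-RNA characters {sorted(bad)}; "
                "normalize with RnaSequence.from_raw"
            )
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a whitespace-free token: {self.id!r}")

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "RnaSequence":
        """Normalize raw input: uppercase and DNA T mapped to U."""
        return cls(id=id, bases=raw.upper().replace("T", "U"))

    @property
    def n(self) -> int:
        return len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, pos: int) -> str:
        """1-based base access: seq[1] is r1, seq[n] is rn."""
        if not 1 <= pos <= len(self.bases):
            raise IndexError(f"position {pos} out of range 1..{len(self.bases)}")
        return self.bases[pos - 1]

    def codes(self) -> np.ndarray:
        """Integer encoding A,C,G,U -> 0..3, padded so codes()[i] is ri."""
        lut = {b: i for i, b in enumerate(BASES)}
        arr = np.empty(len(self.bases) + 1, dtype=np.int8)
        arr[0] = -1
        arr[1:] = [lut[b] for b in self.bases]
        return arr


class FastaError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a multi-record FASTA file into normalized RnaSequences.

    T is mapped to U and case is folded; duplicate ids and non-nucleotide
    characters are rejected with the line number of the offence.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    first_content = next((s for s in lines if s.strip()), None)
    if first_content is None:
        raise FastaError(f"{path}:1: empty file, expected FASTA records")
    if not first_content.lstrip().startswith(">"):
        raise FastaError(f"{path}:1: not FASTA (first record lacks '>' header)")
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(">") or not line.strip():
            continue
        bad = set(line.strip()) - _INPUT_OK
        if bad:
            raise FastaError(
                f"{path}:{lineno}: illegal sequence character(s) {sorted(bad)}"
            )
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            lineno = next(
                i for i, s in enumerate(lines, start=1)
                if s.startswith(">") and s[1:].split()[:1] == [rec.id]
            )
            raise FastaError(f"{path}:{lineno}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(RnaSequence.from_raw(rec.id, str(rec.seq)))
    return records


def write_fasta(path: str | Path, seqs: Sequence[RnaSequence], width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for off in range(0, s.n, width):
                fh.write(s.bases[off:off + width] + "\n")


def generate_random_sequences(
    count: int,
    length: int,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> list[RnaSequence]:
    """Seeded i.i.d. random RNA sequences, ids ``synthL{length}_{k}``.

    ``composition`` gives the A, C, G, U probabilities; the default
    uniform mix mirrors randomly generated benchmark batches.
    """
    if count < 1 or length < 1:
        raise ValueError("count and length must be >= 1")
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be a probability vector over A,C,G,U")
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=(count, length), p=comp)
    alphabet = np.array(list(BASES))
    return [
        RnaSequence(id=f"synthL{length}_{k + 1}", bases="".join(alphabet[row]))
        for k, row in enumerate(draws)
    ]
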