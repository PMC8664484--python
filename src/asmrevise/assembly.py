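"""Core assembly container and sequence/FASTA utilities.

An :class:`Assembly` is an ordered collection of named DNA sequences
(pseudomolecules or scaffolds) over the alphabet ``{A, C, G, T, N}``.
Joins between components are encoded as runs of ``N``; the gap registry
is derived from sequence content by :mod:`asmrevise.gapcensus`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_CHARS = frozenset("ACGTNacgtn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceFormatError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


def check_alphabet(seq: str, name: str = "sequence") -> None:
    """Raise :class:`SequenceFormatError` naming the first offending position."""
    bad = set(seq) - VALID_CHARS
    if bad:
        for i, c in enumerate(seq):
            if c not in VALID_CHARS:
                raise SequenceFormatError(
                    f"{name}: invalid character {c!r} at position {i}"
                )


@dataclass
class Assembly:
    """Ordered named sequences with an edit-provenance trail.

    Parameters
    ----------
    sequences
        Mapping of sequence id to uppercase DNA string. Insertion order is
        the assembly order and is preserved through I/O.
    provenance
        Human-readable log of edits applied to reach this assembly.
    """

    sequences: dict[str, str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}

    @property
    def seq_ids(self) -> list[str]:
        return list(self.sequences)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def copy(self) -> "Assembly":
        return Assembly(dict(self.sequences), list(self.provenance))

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_fasta(cls, path: str | Path | io.TextIOBase) -> "Assembly":
        records = {}
        for rec in SeqIO.parse(path, "fasta"):
            records[rec.id] = str(rec.seq).upper()
        return cls(records)

    def to_fasta(self, path: str | Path | io.TextIOBase, width: int = 80) -> None:
        records = [
            SeqRecord(Seq(s), id=name, description="")
            for name, s in self.sequences.items()
        ]
        if isinstance(path, (str, Path)):
            with open(path, "w") as fh:
                SeqIO.write(records, fh, "fasta")
        else:
            SeqIO.write(records, path, "fasta")
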