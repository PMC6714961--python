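"""FASTA input and normalization.

All downstream analysis operates on :class:`SequenceRecord` objects: one per
FASTA entry, with residues uppercased and RNA ``U`` mapped to ``T``.  Any
residue outside ``{A, C, G, T}`` (IUPAC ambiguity codes, ``N``) is kept in
place so that window coordinates stay aligned to the input, but is excluded
from base and dinucleotide counts by the index layer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, List, Union

from Bio import SeqIO

__all__ = ["SequenceRecord", "FastaFormatError", "read_fasta", "write_fasta", "normalize_residue"]

# uppercase everything; U (RNA) is treated as T
_CANONICALIZE = str.maketrans(
    "abcdefghijklmnopqrstuvwxyzU",
    "ABCDEFGHIJKLMNOPQRSTTVWXYZT",
)

UNAMBIGUOUS = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Raised for inputs that cannot be interpreted as usable FASTA."""


def normalize_residue(c: str) -> str:
    """Normalize a single residue character.

    Lowercase is mapped to uppercase and ``U``/``u`` to ``T``.  Every other
    character (ambiguity codes, unexpected symbols) is returned verbatim
    after case-folding; counting operations treat non-ACGT characters as
    ambiguous rather than erroring.
    """
    return c.translate(_CANONICALIZE)


def normalize_sequence(s: str) -> str:
    """Vectorized :func:`normalize_residue` over a whole string."""
    return s.translate(_CANONICALIZE)


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry with normalized residues.

    Parameters
    ----------
    id:
        First whitespace-delimited token of the FASTA header line.
    description:
        Remainder of the header line (may be empty).
    residues:
        Uppercase residue string; ``U`` already mapped to ``T``.
    """

    id: str
    description: str
    residues: str = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FastaFormatError(f"record {self.id!r} has zero residues")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: Union[str, os.PathLike]) -> List[SequenceRecord]:
    """Read a (possibly multi-record, possibly line-wrapped) FASTA file.

    Residues are concatenated across wrapped lines, uppercased and U→T
    normalized; record order is preserved.

    Raises
    ------
    FastaFormatError
        If the file contains no FASTA records, a record has no residues,
        or two records share an id.
    """
    records: List[SequenceRecord] = []
    seen = set()
    try:
        parsed = list(SeqIO.parse(os.fspath(path), "fasta"))
    except ValueError as e:
        raise FastaFormatError(f"{path}: {e}") from e
    for rec in parsed:
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        description = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            SequenceRecord(
                id=rec.id,
                description=description,
                residues=normalize_sequence(str(rec.seq)),
            )
        )
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found (empty file or missing '>' header)")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, os.PathLike], width: int = 70) -> None:
    """Write records back out as wrapped FASTA (used for fixtures and round-trips)."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i:i + width] + "\n")
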