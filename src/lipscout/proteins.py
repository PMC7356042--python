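"""Protein sequence records and FASTA I/O.

Residue coordinates are 1-based and inclusive everywhere in this package,
matching the bracketed span notation used for limited-proteolysis peptides
(e.g. residues 275-286 of CPS1).  Converters to half-open 0-based slices are
provided for use at I/O boundaries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .constants import CANONICAL_RESIDUES


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed or contains non-canonical residues."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue coordinates.

    Parameters
    ----------
    id : str
        Sequence identifier (the FASTA header token before the first space).
    sequence : str
        Residues over the 20-letter amino-acid alphabet.
    description : str
        Free-text remainder of the header line.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-canonical residue(s) {sorted(bad)}"
            )
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} out of range 1..{self.length} for {self.id}"
            )
        return self.sequence[position - 1]

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start..end``, 1-based inclusive."""
        if not (1 <= start <= end <= self.length):
            raise IndexError(
                f"span [{start},{end}] out of range 1..{self.length} for {self.id}"
            )
        return self.sequence[start - 1 : end]


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive span -> half-open 0-based slice bounds."""
    return start - 1, end


def to_one_based(lo: int, hi: int) -> tuple[int, int]:
    """Half-open 0-based slice bounds -> 1-based inclusive span."""
    return lo + 1, hi


def _find_bad_residue_line(path: Path, record_id: str, bad: set[str]) -> int | None:
    """Locate the first offending line for an error message (best effort)."""
    in_record = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
                continue
            if in_record and (set(line.strip().upper()) & bad):
                return lineno
    return None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-entry FASTA file into :class:`ProteinRecord` objects.

    Wrapped and unwrapped sequence lines are both accepted.  A header without
    an identifier, or a sequence containing anything outside the 20 canonical
    one-letter codes, raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: FASTA entry with empty header")
        seq = str(rec.seq).upper()
        bad = set(seq) - CANONICAL_RESIDUES
        if bad:
            lineno = _find_bad_residue_line(path, rec.id, bad)
            where = f"line {lineno}" if lineno is not None else "unknown line"
            raise FastaParseError(
                f"{path}: entry {rec.id!r} contains non-canonical residue(s) "
                f"{sorted(bad)} ({where})"
            )
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA with fixed line wrapping (round-trip safe)."""
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            for i in range(0, rec.length, width):
                handle.write(rec.sequence[i : i + width] + "\n")
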