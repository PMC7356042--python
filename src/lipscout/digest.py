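"""In silico proteolysis and tryptic-status classification.

The digestion model covers trypsin (cleaves C-terminal to K or R, but not
when the next residue is proline) and the trypsin/LysC mixture commonly used
for the denaturing digestion step of limited-proteolysis workflows: LysC
additionally cleaves after lysine even when proline follows.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .proteins import ProteinRecord

N_TERMINUS = "-"
C_TERMINUS = "-"


class TrypticStatus(str, Enum):
    FULLY_TRYPTIC = "fully_tryptic"
    SEMI_TRYPTIC = "semi_tryptic"
    NON_TRYPTIC = "non_tryptic"


@dataclass(frozen=True)
class Enzyme:
    """Cleavage rule set: cut after ``residues`` unless proline follows,
    except that residues in ``ignore_proline_for`` cut regardless."""

    name: str
    residues: frozenset[str]
    ignore_proline_for: frozenset[str] = frozenset()

    def cleaves_after(self, sequence: str, pos: int) -> bool:
        """True if the bond after 1-based position ``pos`` is cleavable."""
        if pos >= len(sequence):
            return False
        aa = sequence[pos - 1]
        if aa not in self.residues:
            return False
        if sequence[pos] == "P" and aa not in self.ignore_proline_for:
            return False
        return True


TRYPSIN = Enzyme("trypsin", frozenset("KR"))
#: Trypsin/LysC mix: LysC cleaves after K even before P.
TRYPSIN_LYSC = Enzyme("trypsin/lysc", frozenset("KR"), ignore_proline_for=frozenset("K"))

ENZYMES = {"trypsin": TRYPSIN, "trypsin/lysc": TRYPSIN_LYSC}


@dataclass(frozen=True)
class Peptide:
    """A residue span of a protein, 1-based inclusive coordinates."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    preceding_residue: str  # residue letter, or "-" at the N-terminus
    following_residue: str  # residue letter, or "-" at the C-terminus
    tryptic_status: TrypticStatus = TrypticStatus.FULLY_TRYPTIC

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span [{self.start},{self.end}]")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match span")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def span_label(self) -> str:
        """Compact label in the field's span notation, e.g. ``G-[275-286]-K``
        (flanking letters are the peptide's own termini)."""
        return f"{self.sequence[0]}-[{self.start}-{self.end}]-{self.sequence[-1]}"


def peptide_from_span(protein: ProteinRecord, start: int, end: int,
                      enzyme: Enzyme = TRYPSIN) -> Peptide:
    """Build a :class:`Peptide` for an arbitrary span, classifying its status."""
    seq = protein.subsequence(start, end)
    pep = Peptide(
        protein_id=protein.id,
        start=start,
        end=end,
        sequence=seq,
        missed_cleavages=_internal_missed(protein, start, end, enzyme),
        preceding_residue=protein.residue(start - 1) if start > 1 else N_TERMINUS,
        following_residue=protein.residue(end + 1) if end < protein.length else C_TERMINUS,
        tryptic_status=TrypticStatus.NON_TRYPTIC,
    )
    status = annotate_tryptic_status(pep, protein, enzyme)
    return Peptide(**{**pep.__dict__, "tryptic_status": status})


def cleavage_sites(protein: ProteinRecord, enzyme: Enzyme = TRYPSIN) -> list[int]:
    """1-based positions P such that the enzyme cuts between P and P+1."""
    seq = protein.sequence
    return [i for i in range(1, protein.length) if enzyme.cleaves_after(seq, i)]


def _internal_missed(protein: ProteinRecord, start: int, end: int, enzyme: Enzyme) -> int:
    seq = protein.sequence
    return sum(1 for i in range(start, end) if enzyme.cleaves_after(seq, i))


def _nterm_conforms(protein: ProteinRecord, start: int, enzyme: Enzyme) -> bool:
    return start == 1 or enzyme.cleaves_after(protein.sequence, start - 1)


def _cterm_conforms(protein: ProteinRecord, end: int, enzyme: Enzyme) -> bool:
    return end == protein.length or enzyme.cleaves_after(protein.sequence, end)


def annotate_tryptic_status(peptide: Peptide, protein: ProteinRecord,
                            enzyme: Enzyme = TRYPSIN) -> TrypticStatus:
    """Classify a peptide span as fully/semi/non tryptic.

    Fully tryptic means both termini conform to the enzyme's specificity (or
    coincide with the protein termini), with the not-before-proline rule
    respected at both junctions; semi-tryptic means exactly one conforming
    terminus.
    """
    if not (1 <= peptide.start <= peptide.end <= protein.length):
        raise IndexError(
            f"span [{peptide.start},{peptide.end}] out of range for {protein.id}"
        )
    if protein.subsequence(peptide.start, peptide.end) != peptide.sequence:
        raise ValueError("peptide sequence does not match protein at its span")
    n_ok = _nterm_conforms(protein, peptide.start, enzyme)
    c_ok = _cterm_conforms(protein, peptide.end, enzyme)
    if n_ok and c_ok:
        return TrypticStatus.FULLY_TRYPTIC
    if n_ok or c_ok:
        return TrypticStatus.SEMI_TRYPTIC
    return TrypticStatus.NON_TRYPTIC


def digest(protein: ProteinRecord, enzyme: Enzyme = TRYPSIN,
           max_missed: int = 2) -> list[Peptide]:
    """All fully tryptic peptides with at most ``max_missed`` missed cleavages.

    The zero-missed peptides tile the protein sequence without gaps or
    overlaps; peptides with missed cleavages are concatenations of adjacent
    zero-missed peptides.  Results are ordered by start position, then by
    missed-cleavage count.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if protein.length == 0:
        raise ValueError("empty sequence")
    sites = cleavage_sites(protein, enzyme)
    # boundaries of the zero-missed tiling: [b_i + 1 .. b_{i+1}]
    bounds = [0] + sites + [protein.length]
    peptides: list[Peptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(min(max_missed, n_frag - 1 - i) + 1):
            start = bounds[i] + 1
            end = bounds[i + 1 + m]
            peptides.append(
                Peptide(
                    protein_id=protein.id,
                    start=start,
                    end=end,
                    sequence=protein.subsequence(start, end),
                    missed_cleavages=m,
                    preceding_residue=(
                        protein.residue(start - 1) if start > 1 else N_TERMINUS
                    ),
                    following_residue=(
                        protein.residue(end + 1) if end < protein.length else C_TERMINUS
                    ),
                    tryptic_status=TrypticStatus.FULLY_TRYPTIC,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides
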