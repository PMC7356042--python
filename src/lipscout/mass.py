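"""Monoisotopic peptide masses and precursor m/z.

``mz = (M + z * proton) / z`` with ``M`` the monoisotopic neutral mass:
the sum of residue masses, one water, and any modification deltas.  The
default fixed modification is carbamidomethylation of cysteine (+57.02146 Da),
standard for iodoacetamide-alkylated samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import (
    DEFAULT_FIXED_MODS,
    MONOISOTOPIC_RESIDUE_MASS,
    PROTON_MASS,
    WATER_MONO,
)
from .digest import Peptide


def sequence_mass(sequence: str, fixed_mods: dict[str, float] | None = None) -> float:
    """Monoisotopic neutral mass of a peptide sequence.

    ``fixed_mods`` maps residue letters to mass deltas applied at every
    occurrence of that residue; deltas for residues absent from the peptide
    are ignored.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    mods = DEFAULT_FIXED_MODS if fixed_mods is None else fixed_mods
    mass = WATER_MONO
    for aa in sequence:
        try:
            mass += MONOISOTOPIC_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"non-canonical residue {aa!r}") from None
        mass += mods.get(aa, 0.0)
    return mass


def mass_to_mz(mass: float, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + charge * PROTON_MASS) / charge


def mz_to_mass(mz: float, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return mz * charge - charge * PROTON_MASS


@dataclass(frozen=True)
class PrecursorIon:
    """A protonated peptide selected in Q1."""

    peptide: Peptide
    charge: int
    fixed_modifications: tuple[tuple[str, float], ...]
    monoisotopic_mass: float
    mz: float

    @property
    def id(self) -> str:
        return f"{self.peptide.protein_id}:{self.peptide.span_label()}/{self.charge}"

    @property
    def mods_dict(self) -> dict[str, float]:
        return dict(self.fixed_modifications)


def precursor_mz(peptide: Peptide, charge: int = 2,
                 mods: dict[str, float] | None = None) -> PrecursorIon:
    """Build a :class:`PrecursorIon` for a peptide at a given charge state.

    Doubly protonated ions are the default, the common charge state of
    tryptic peptides in the 7-25 residue range.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    mods = DEFAULT_FIXED_MODS if mods is None else mods
    mass = sequence_mass(peptide.sequence, mods)
    return PrecursorIon(
        peptide=peptide,
        charge=charge,
        fixed_modifications=tuple(sorted(mods.items())),
        monoisotopic_mass=mass,
        mz=mass_to_mz(mass, charge),
    )
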