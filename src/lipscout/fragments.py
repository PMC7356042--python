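"""b/y fragment-ion enumeration for MRM transition planning."""

from __future__ import annotations

from dataclasses import dataclass

from .constants import MONOISOTOPIC_RESIDUE_MASS, PROTON_MASS, WATER_MONO
from .mass import PrecursorIon


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series fragment.

    ``ordinal`` counts residues from the relevant terminus (N for b, C for y)
    and runs 1..n-1 for a peptide of n residues.  Modification deltas are
    carried into whichever fragment contains the modified residue.
    """

    series: str  # "b" or "y"
    ordinal: int
    charge: int
    mz: float

    @property
    def label(self) -> str:
        suffix = "+" * self.charge
        return f"{self.series}{self.ordinal}{suffix}"


def _residue_masses(sequence: str, mods: dict[str, float]) -> list[float]:
    return [MONOISOTOPIC_RESIDUE_MASS[aa] + mods.get(aa, 0.0) for aa in sequence]


def enumerate_fragments(precursor: PrecursorIon) -> list[FragmentIon]:
    """All b and y ions of a precursor.

    Singly charged fragments are always produced; doubly charged fragments
    are added when the precursor charge is 3 or higher (lower charge states
    rarely yield useful 2+ products on triple quadrupoles).  A single-residue
    peptide has no backbone bond to fragment and yields an empty list.
    """
    seq = precursor.peptide.sequence
    n = len(seq)
    if n < 2:
        return []
    mods = precursor.mods_dict
    res = _residue_masses(seq, mods)
    charges = [1] if precursor.charge < 3 else [1, 2]
    out: list[FragmentIon] = []
    b_sum = 0.0
    for i in range(1, n):
        b_sum += res[i - 1]
        for z in charges:
            out.append(FragmentIon("b", i, z, (b_sum + z * PROTON_MASS) / z))
    y_sum = WATER_MONO
    for i in range(1, n):
        y_sum += res[n - i]
        for z in charges:
            out.append(FragmentIon("y", i, z, (y_sum + z * PROTON_MASS) / z))
    return out
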