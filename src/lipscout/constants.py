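"""Pinned physical constants for peptide mass arithmetic.

All monoisotopic residue masses, the proton mass and the mass of water are
pinned here, in one place, so that every m/z the package emits is
bit-reproducible and independent of any external library version.
"""

#: Monoisotopic masses of amino-acid *residues* (Da), i.e. the free amino
#: acid minus one water.  Values to five decimals, standard IUPAC alphabet.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: The 20 canonical one-letter codes; anything else is rejected at parse time.
CANONICAL_RESIDUES: frozenset[str] = frozenset(MONOISOTOPIC_RESIDUE_MASS)

#: Monoisotopic mass of water (Da), added once per peptide chain.
WATER_MONO = 18.010565

#: Mass of a proton (Da), added once per positive charge.
PROTON_MASS = 1.007276

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), Da.
CARBAMIDOMETHYL_DELTA = 57.02146

#: Fixed-modification map used by default throughout the package: every
#: cysteine carries the carbamidomethyl group.
DEFAULT_FIXED_MODS: dict[str, float] = {"C": CARBAMIDOMETHYL_DELTA}

#: Common variable modifications, accepted as configuration for mass
#: computation but excluded from default MRM planning.
OXIDATION_DELTA = 15.994915
PHOSPHO_DELTA = 79.966331
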