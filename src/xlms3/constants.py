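"""Physical constants and residue masses used throughout the package.

All masses are monoisotopic and in Dalton. Envelope arithmetic is done in
neutral-mass space with a fixed proton mass and an averaged C12/C13 isotope
spacing, which is the convention of most deisotoping code for peptides.
"""

from pyteomics import mass as _pmass

#: Charge carrier (proton) mass, Da.
PROTON = 1.00728

#: Average isotope envelope spacing (~C13-C12), Da.
NEUTRON = 1.00336

#: Monoisotopic mass of water, Da.
WATER = 18.010565

#: Monoisotopic residue masses for the 20 canonical amino acids, Da.
RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

#: Carbamidomethylation of cysteine, the usual fixed alkylation modification.
CARBAMIDOMETHYL = 57.02146


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    """m/z of an ion of the given neutral mass and positive charge."""
    return neutral_mass / charge + PROTON


def neutral_from_mz(mz: float, charge: int) -> float:
    """Neutral mass corresponding to an observed m/z at the given charge."""
    return charge * (mz - PROTON)


def ppm_width(mz: float, ppm: float) -> float:
    """Absolute half-window in Th for a relative tolerance in ppm at ``mz``."""
    return mz * ppm * 1e-6
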