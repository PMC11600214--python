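"""Physical constants and fixed residue-level parameter tables.

Internal units throughout the package: nm, kJ/mol, ps, K.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.008314

#: Angstrom -> nm conversion factor.
ANG_TO_NM = 0.1

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: The 20 standard residues in a fixed order (one-letter).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# Mean residue volumes in A^3 (Zamyatnin-type consensus values).  Used to
# assign an effective sphere radius to each Calpha bead for the approximate
# solvent-accessible surface area: r = (3V / 4 pi)^(1/3).
_RESIDUE_VOLUME_A3 = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: Effective residue sphere radius in nm, indexed by one-letter code.
RESIDUE_RADIUS_NM = {
    aa: ANG_TO_NM * (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    for aa, vol in _RESIDUE_VOLUME_A3.items()
}

#: Fixed polar / hydrophobic partition of the 20 residues (side-chain
#: chemistry based; every residue belongs to exactly one class).
POLAR_RESIDUES = frozenset("STYNQDEKRH")
HYDROPHOBIC_RESIDUES = frozenset("AVLIPFMWGC")

assert POLAR_RESIDUES | HYDROPHOBIC_RESIDUES == set(AA_ORDER)
assert not POLAR_RESIDUES & HYDROPHOBIC_RESIDUES


def residue_radius(aa: str, default: float = 0.25) -> float:
    """Effective sphere radius (nm) for a one-letter residue code."""
    return RESIDUE_RADIUS_NM.get(aa, default)
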