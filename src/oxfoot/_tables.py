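"""Shipped default tables: reactivities, reference areas, radii, masses.

All of these are *configuration with defaults*, not constants of the method
(except the monoisotopic masses, which are physical). The intrinsic
reactivities are the free-amino-acid second-order rate constants for
reaction with the hydroxyl radical (pulse-radiolysis compilation values),
expressed in units of 1e9 M^-1 s^-1. Protection factors are homogeneous of
degree +1 in this scale, so substituting another reactivity table shifts
only the intercept of the ln PF vs fSASA calibration, never its slope or
Pearson correlation.
"""

from __future__ import annotations

#: Free-amino-acid hydroxyl-radical rate constants, 1e9 M^-1 s^-1.
#: Residues listed here are treated as oxidizable; the four very slow
#: residues (G, A, D, N) are omitted, i.e. declared non-oxidizable.
HYDROXYL_REACTIVITY: dict[str, float] = {
    "C": 34.0,
    "W": 13.0,
    "Y": 13.0,
    "M": 8.5,
    "F": 6.9,
    "H": 4.8,
    "R": 3.5,
    "I": 1.8,
    "L": 1.7,
    "V": 0.85,
    "P": 0.65,
    "Q": 0.54,
    "T": 0.51,
    "K": 0.35,
    "S": 0.32,
    "E": 0.23,
}

#: Side-chain reference accessible areas (A^2), Gly-X-Gly tripeptide
#: standard. Gly, having no heavy side-chain atom, gets a small positive
#: sentinel so the fSASA ratio stays defined; Gly is non-oxidizable and
#: never enters protection-factor analysis.
SASA_REF_SIDECHAIN: dict[str, float] = {
    "A": 67.0, "R": 196.0, "N": 113.0, "D": 106.0, "C": 104.0,
    "Q": 144.0, "E": 138.0, "G": 1.0, "H": 151.0, "I": 140.0,
    "L": 137.0, "K": 167.0, "M": 160.0, "F": 175.0, "P": 105.0,
    "S": 80.0, "T": 102.0, "W": 217.0, "Y": 187.0, "V": 117.0,
}

#: Whole-residue theoretical maximum accessible areas (A^2).
SASA_REF_TOTAL: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Van der Waals radii (A) for heavy elements common in proteins.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.10,
}

#: Monoisotopic residue masses (Da); peptide mass = sum + water.
MONOISOTOPIC_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MONOISOTOPIC = 18.010565

AA_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA_1TO3: dict[str, str] = {v: k for k, v in AA_3TO1.items()}

STANDARD_AA = set(AA_1TO3)
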