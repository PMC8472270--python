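"""Physical constants and amino-acid property tables.

Residue masses are average (isotope-abundance-weighted) masses of the
*residues*, i.e. the free amino acid minus one water, as used by ProtParam.
Hydrophobicity scales are free-energy-of-transfer values (kcal/mol) on the
conventions named after their authors.
"""

BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

WATER_MASS = 18.0153  # Da, added once per chain (free-acid C-terminus)
AMIDE_DELTA = 0.984  # Da removed when the C-terminus is amidated (-OH -> -NH2)

#: Average residue masses in Da (ExPASy convention).
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

CANONICAL_RESIDUES = frozenset(AVERAGE_RESIDUE_MASS)

# Molar extinction coefficients at 280 nm, M^-1 cm^-1 (Pace/ProtParam).
EPSILON_TRP = 5500.0
EPSILON_TYR = 1490.0
EPSILON_CYSTINE = 125.0

#: Fauchere–Pliska octanol/water transfer scale.
FAUCHERE_PLISKA = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

#: Eisenberg consensus scale.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

HYDROPHOBICITY_SCALES = {
    "fauchere_pliska": FAUCHERE_PLISKA,
    "eisenberg": EISENBERG,
}
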