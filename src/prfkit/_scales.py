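"""Per-residue scales: hydrophobicity and formal charge.

Two hydrophobicity conventions are shipped. ``BIOLOGICAL`` is the
translocon (apparent transfer free energy) scale measured in the Sec61
glycosylation assay, stored here as *hydrophobicity* (the negated
water->bilayer transfer free energy, kcal/mol, so larger = more
hydrophobic). ``KYTE_DOOLITTLE`` is the classic hydropathy index.
"""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Apparent transfer free energies (water -> bilayer, kcal/mol) from the
# biological hydrophobicity scale; positive = unfavorable insertion.
TRANSFER_DG = {
    "A": 0.11, "C": -0.13, "D": 3.49, "E": 2.68, "F": -0.32,
    "G": 0.74, "H": 2.06, "I": -0.60, "K": 2.71, "L": -0.55,
    "M": -0.10, "N": 2.05, "P": 2.23, "Q": 2.36, "R": 2.58,
    "S": 0.84, "T": 0.52, "V": -0.31, "W": 0.30, "Y": 0.68,
}

BIOLOGICAL = {aa: -dg for aa, dg in TRANSFER_DG.items()}

KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

HYDROPHOBICITY_SCALES = {
    "biological": BIOLOGICAL,
    "kyte_doolittle": KYTE_DOOLITTLE,
}

# Formal charges at neutral pH (His treated as neutral).
CHARGE = {aa: 0 for aa in AMINO_ACIDS}
CHARGE.update({"K": 1, "R": 1, "D": -1, "E": -1})
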