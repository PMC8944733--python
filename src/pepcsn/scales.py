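"""Published per-residue scales used by the descriptor set.

All tables are keyed by one-letter amino-acid code over the canonical
20-letter alphabet.
"""

from __future__ import annotations

# Lehninger pKa values for ionizable groups (terminal groups are generic).
PKA_NTERM = 9.69
PKA_CTERM = 2.34
PKA_POSITIVE = {"K": 10.53, "R": 12.48, "H": 6.00}
PKA_NEGATIVE = {"D": 3.65, "E": 4.25, "C": 8.33, "Y": 10.07}

# Boman (2003) protein-interaction scale: residue solubility values
# (kcal/mol); the Boman index is their mean over the sequence. Derived from
# Radzicka–Wolfenden water/cyclohexane transfer free energies; proline,
# unmeasured in that series, is assigned 0.
BOMAN = {
    "L": -4.92, "I": -4.92, "V": -4.04, "F": -2.98, "M": -2.35,
    "W": -2.33, "A": -1.81, "C": -1.28, "G": -0.94, "Y": 0.14,
    "T": 2.57, "S": 3.40, "H": 4.66, "Q": 5.54, "K": 5.55,
    "N": 6.64, "E": 6.81, "D": 8.72, "R": 14.92, "P": 0.0,
}

# Eisenberg consensus hydrophobicity (used for the helical hydrophobic
# moment and the hydrophobic-periodicity spectrum).
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Hopp–Woods hydrophilicity.
HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}
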