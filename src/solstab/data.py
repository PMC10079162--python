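"""Reference amino-acid property tables used across the package.

All tables are plain dicts keyed by one-letter amino-acid code.  The
physicochemical scales feed the solubility and stability surrogates; the
maximum-accessibility table normalises raw solvent-accessible surface
areas into relative exposures; the van der Waals radii drive the sphere
sampling of accessible area.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Kyte & Doolittle hydropathy (positive = hydrophobic).
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Chou & Fasman beta-sheet conformational propensity (P_beta x 100).
BETA_PROPENSITY = {
    "A": 83.0, "R": 93.0, "N": 89.0, "D": 54.0, "C": 119.0,
    "Q": 110.0, "E": 37.0, "G": 75.0, "H": 87.0, "I": 160.0,
    "L": 130.0, "K": 74.0, "M": 105.0, "F": 138.0, "P": 55.0,
    "S": 75.0, "T": 119.0, "W": 137.0, "Y": 147.0, "V": 170.0,
}

# Net side-chain charge at pH 7 (His carries a small positive fraction).
CHARGE = {
    "D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1,
}

# Residue volumes in cubic Angstrom (Zamyatnin).
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Theoretical maximum accessible surface area (Angstrom^2) of residue X
# in an extended Gly-X-Gly tripeptide (Tien et al. 2013, theoretical).
MAX_ASA_GXG = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
MEAN_MAX_ASA = float(np.mean(list(MAX_ASA_GXG.values())))

# Heavy-atom van der Waals radii (Angstrom), by element symbol.
VDW_RADIUS = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.80

UNIFORM_BACKGROUND = np.full(20, 0.05)


def zscored_scale(table: dict[str, float]) -> dict[str, float]:
    """Z-score a 20-value amino-acid scale (population statistics)."""
    values = np.array([table[aa] for aa in AMINO_ACIDS], dtype=float)
    mu = values.mean()
    sigma = values.std()
    return {aa: float((table[aa] - mu) / sigma) for aa in AMINO_ACIDS}


HYDROPATHY_Z = zscored_scale(HYDROPATHY)
BETA_PROPENSITY_Z = zscored_scale(BETA_PROPENSITY)
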