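"""Static per-residue reference data.

Average (natural-abundance) residue masses, random-coil chemical shifts,
helix secondary-shift offsets, side-chain torsion definitions and rotamer
well priors, and scattering factors used across the package.
"""

from __future__ import annotations

# Average residue masses in Da (amino acid minus one water), IUPAC values.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = 18.0153

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# Static random-coil chemical shifts (ppm) for CA/CB/HA.  Values follow the
# commonly used aqueous random-coil reference scale; Gly has no CB entry.
# This table serves both as the coil reference for secondary shifts and as
# the baseline of the two-state (coil + helix-offset) shift model.
RANDOM_COIL_SHIFTS = {
    #       CA     CB     HA
    "A": (52.5, 19.1, 4.32),
    "R": (56.0, 30.9, 4.34),
    "N": (52.8, 37.9, 4.74),
    "D": (54.2, 41.1, 4.64),
    "C": (58.2, 28.0, 4.55),
    "E": (56.6, 29.9, 4.35),
    "Q": (55.7, 29.4, 4.34),
    "G": (45.1, None, 3.96),
    "H": (55.0, 29.0, 4.73),
    "I": (61.1, 38.8, 4.17),
    "L": (55.1, 42.4, 4.38),
    "K": (56.2, 33.1, 4.32),
    "M": (55.4, 32.9, 4.48),
    "F": (57.7, 39.6, 4.62),
    "P": (63.3, 32.1, 4.42),
    "S": (58.3, 63.8, 4.47),
    "T": (61.8, 69.8, 4.35),
    "W": (57.5, 29.6, 4.70),
    "Y": (57.9, 38.8, 4.55),
    "V": (62.2, 32.9, 4.12),
}

# Default helix secondary-shift offsets Delta-delta(helix) in ppm.
HELIX_SHIFT_OFFSETS = {"CA": 3.1, "CB": -0.5, "HA": -0.35}

# Electrons per element, used as constant atomic scattering factors.
ELEMENT_ELECTRONS = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0}

ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

# Side-chain torsion (chi) definitions: ordered atom-name quadruples.
CHI_DEFINITIONS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "PRO": [], "GLY": [], "ALA": [],
}

# Rotamer-well priors per chi: (well centers deg, weights, jitter sigma deg).
_DEFAULT_WELLS = ((-60.0, 180.0, 60.0), (0.50, 0.35, 0.15), 10.0)
_RING_WELLS = ((90.0, -90.0), (0.5, 0.5), 15.0)
_PLANAR_TERMINAL = (None, None, None)  # uniform over (-180, 180]

CHI_WELL_PRIORS = {
    "PHE": [_DEFAULT_WELLS, _RING_WELLS],
    "TYR": [_DEFAULT_WELLS, _RING_WELLS],
    "TRP": [_DEFAULT_WELLS, _RING_WELLS],
    "HIS": [_DEFAULT_WELLS, _RING_WELLS],
    "ASP": [_DEFAULT_WELLS, _PLANAR_TERMINAL],
    "ASN": [_DEFAULT_WELLS, _PLANAR_TERMINAL],
    "GLU": [_DEFAULT_WELLS, _DEFAULT_WELLS, _PLANAR_TERMINAL],
    "GLN": [_DEFAULT_WELLS, _DEFAULT_WELLS, _PLANAR_TERMINAL],
    "ARG": [_DEFAULT_WELLS, _DEFAULT_WELLS, _DEFAULT_WELLS,
            ((180.0, -90.0, 90.0), (0.5, 0.25, 0.25), 12.0)],
}


def chi_well_priors(res_name: str):
    """Well priors for every chi of a residue type (generic default)."""
    n_chi = len(CHI_DEFINITIONS.get(res_name, []))
    priors = list(CHI_WELL_PRIORS.get(res_name, []))
    while len(priors) < n_chi:
        priors.append(_DEFAULT_WELLS)
    return priors[:n_chi]
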