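"""Per-residue tables for the coarse-grained representation.

Backbone particles are atomistic (N, H, CA, C, O); each non-glycine side
chain is lumped into a single bead whose nonbonded parameters are
aggregated from the heavy atoms it contains (pairwise-additive
construction: bead epsilon = sum of constituent atom epsilons, bead sigma
= tabulated side-chain gyration radius + a 1.9 A base radius). Bead
hydrophobicity follows the Kyte-Doolittle scale (positive = hydrophobic,
burial rewarded) and is converted to kcal/mol by the force-field
``solv_scale`` parameter at evaluation time.

All values here are declared, overridable package defaults.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Kyte-Doolittle hydropathy (dimensionless).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# United-atom Lennard-Jones well depths per side-chain heavy atom (kcal/mol).
ATOM_EPS = {"C": 0.15, "N": 0.15, "O": 0.15, "S": 0.25}

# Side-chain heavy-atom element composition (beyond the backbone).
SIDECHAIN_ATOMS = {
    "A": {"C": 1},
    "R": {"C": 4, "N": 3},
    "N": {"C": 2, "N": 1, "O": 1},
    "D": {"C": 2, "O": 2},
    "C": {"C": 1, "S": 1},
    "Q": {"C": 3, "N": 1, "O": 1},
    "E": {"C": 3, "O": 2},
    "G": {},
    "H": {"C": 4, "N": 2},
    "I": {"C": 4},
    "L": {"C": 4},
    "K": {"C": 4, "N": 1},
    "M": {"C": 3, "S": 1},
    "F": {"C": 7},
    "P": {"C": 3},
    "S": {"C": 1, "O": 1},
    "T": {"C": 2, "O": 1},
    "W": {"C": 9, "N": 1},
    "Y": {"C": 7, "O": 1},
    "V": {"C": 3},
}

# Side-chain mass including hydrogens (amu).
SIDECHAIN_MASS = {
    "A": 15.03, "R": 100.14, "N": 58.06, "D": 59.04, "C": 47.10,
    "Q": 72.09, "E": 73.07, "G": 1.01, "H": 81.10, "I": 57.11,
    "L": 57.11, "K": 72.13, "M": 75.15, "F": 91.13, "P": 41.07,
    "S": 31.03, "T": 45.06, "W": 130.17, "Y": 107.13, "V": 43.09,
}

# Radius of gyration of the side-chain heavy atoms about their centroid (A),
# coarse literature-typical values; single-atom side chains have rg = 0.
SIDECHAIN_RG = {
    "A": 0.0, "R": 2.0, "N": 1.1, "D": 1.1, "C": 0.7,
    "Q": 1.5, "E": 1.5, "G": 0.0, "H": 1.5, "I": 1.3,
    "L": 1.3, "K": 1.7, "M": 1.5, "F": 1.7, "P": 1.0,
    "S": 0.6, "T": 0.8, "W": 2.1, "Y": 1.9, "V": 0.85,
}

BEAD_BASE_RADIUS = 2.5  # A, added to the side-chain gyration radius


def bead_sigma(one: str) -> float:
    return SIDECHAIN_RG[one] + BEAD_BASE_RADIUS


def bead_epsilon(one: str) -> float:
    """Pairwise-additive bead well depth: sum over constituent heavy atoms."""
    return sum(n * ATOM_EPS[el] for el, n in SIDECHAIN_ATOMS[one].items())


def bead_mass(one: str) -> float:
    return SIDECHAIN_MASS[one]


# Backbone particle parameters: kind -> (mass amu, sigma A, eps kcal/mol,
# solvation reference dG kcal/mol; negative = hydrophilic, burial penalised).
# Hydrogen mass is repartitioned from the bonded nitrogen (H 1->8, N 14->7)
# so the stiffest modes the amide hydrogen feels (N-H stretch plus the
# hydrogen-bond well) stay stable at a 10 fs timestep.
BACKBONE_PARAMS = {
    "N": (7.0, 3.2, 0.12, -0.15),
    "H": (8.0, 1.2, 0.02, 0.0),
    "CA": (13.0, 3.4, 0.10, 0.10),
    "C": (12.0, 3.2, 0.10, 0.0),
    "O": (16.0, 3.0, 0.14, -0.20),
}

# Particle kind codes used throughout the particle arrays.
KIND_CODES = {"N": 0, "H": 1, "CA": 2, "C": 3, "O": 4, "SC": 5}
KIND_NAMES = {v: k for k, v in KIND_CODES.items()}

BACKBONE_ATOM_NAMES = {"N", "H", "CA", "C", "O", "OXT", "H1", "H2", "H3", "HA"}
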