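"""Physical constants and element tables.

Units across the package: coordinates in angstrom, energies in kcal/mol,
charges in elementary charges (e), polarizabilities in cubic angstrom.
"""

from __future__ import annotations

# Coulomb constant in kcal * angstrom / (mol * e^2)
COULOMB_CONSTANT = 332.0637157

# IUPAC standard atomic weights (conventional values), g/mol
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "O": 15.999,
    "F": 18.998403163,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.90447,
}

HALIDES = frozenset({"F", "Cl", "Br", "I"})

#: formal charge of the halide anion, e
HALIDE_CHARGE = -1.0

# Dipole polarizabilities of the halide anions (A^3), from coupled-cluster
# atomic values commonly used in polarizable ion-water models.
HALIDE_POLARIZABILITY: dict[str, float] = {
    "F": 2.47,
    "Cl": 5.48,
    "Br": 7.27,
    "I": 10.27,
}

# Default O-H bonding cutoff for monomer detection (A): generous enough for
# distorted monomers, short enough to exclude hydrogen bonds (~1.7 A and up).
DEFAULT_OH_CUTOFF = 1.3

# Rigid-water reference geometry (gas-phase equilibrium values)
WATER_ROH = 0.9572  # A
WATER_HOH = 104.52  # degrees
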