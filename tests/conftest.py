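"""Shared fixtures: toy parameter sets, dimers, and small water clusters."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ionwater.dataset import dimer_from_spherical, rigid_water_monomer
from ionwater.geometry import Atom, ClusterConfiguration
from ionwater.parameters import (
    SITE_H,
    SITE_ION,
    SITE_M,
    SITE_O,
    ElectrostaticSite,
    IonWaterParameters,
    PairShortRange,
    toy_parameters,
)


@pytest.fixture
def params_cl() -> IonWaterParameters:
    return toy_parameters("Cl")


@pytest.fixture
def dimer() -> ClusterConfiguration:
    """Cl- + rigid water at R = 3 A on the hydrogen side."""
    return dimer_from_spherical("Cl", 3.0, 180.0, 0.0)


def make_params(
    ion: str = "Cl",
    a_o: float = 6.0e4,
    b_o: float = 3.2,
    c6_o: float = 3.0e3,
    a_h: float = 8.0e3,
    b_h: float = 2.9,
    c6_h: float = 8.0e2,
    q_h: float = 0.574,
    width: float = 0.4,
    alpha_o: float = 0.837,
    alpha_h: float = 0.496,
    alpha_ion: float = 5.48,
    ion_width: float = 0.6,
) -> IonWaterParameters:
    """Build a parameter set with full control over every knob."""
    return IonWaterParameters(
        ion=ion,
        pair_terms={
            "ion-O": PairShortRange(a=a_o, beta=b_o, c6=c6_o),
            "ion-H": PairShortRange(a=a_h, beta=b_h, c6=c6_h),
        },
        sites={
            SITE_H: ElectrostaticSite(SITE_H, charge=q_h, smearing_width=width,
                                      polarizability=alpha_h),
            SITE_M: ElectrostaticSite(SITE_M, charge=-2 * q_h, smearing_width=width),
            SITE_O: ElectrostaticSite(SITE_O, charge=0.0, polarizability=alpha_o),
            SITE_ION: ElectrostaticSite(SITE_ION, charge=-1.0, smearing_width=ion_width,
                                        polarizability=alpha_ion),
        },
    )


def water_cluster(n: int, seed: int = 0, spacing: float = 3.0) -> ClusterConfiguration:
    """n rigid waters with random orientations on a loose cubic lattice."""
    rng = np.random.default_rng(seed)
    mono = rigid_water_monomer()
    atoms: list[Atom] = []
    side = int(np.ceil(n ** (1 / 3)))
    placed = 0
    for i in range(side):
        for j in range(side):
            for k in range(side):
                if placed >= n:
                    break
                rot = Rotation.random(random_state=int(rng.integers(2**31)))
                origin = spacing * np.array([i, j, k]) + rng.uniform(-0.3, 0.3, 3)
                for a in mono.atoms:
                    atoms.append(Atom(a.element, rot.apply(a.position) + origin))
                placed += 1
    return ClusterConfiguration(atoms=atoms, label=f"(H2O){n}")


@pytest.fixture
def water4() -> ClusterConfiguration:
    return water_cluster(4, seed=7)
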