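"""Pluggable water models.

The potential assembly only needs four things from a water model: the
intramolecular energy, the intermolecular non-induction water-water energy,
and the charges and polarizabilities of the water sites (order [H1, H2, O,
M] per monomer). Any object with ``energies``/``site_properties`` (or the
one-shot ``evaluate``) satisfies the contract.

The registered model names (i-TTM2, i-TTM3, i-TTM4, i-MBpol, custom) all
resolve to :class:`SimpleRigidWater`, a simplified reference water model:
fixed point charges in the TTM site layout, harmonic monomer distortion,
smeared water-water electrostatics and an O-O Born-Mayer + damped-dispersion
pair term. It is not a re-implementation of the published TTM2/TTM3/TTM4-F
or MB-pol water-water potentials, which carry their own parameter tables;
users with such a potential can register it under a custom name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import WATER_HOH, WATER_ROH
from .errors import ConfigurationError
from .geometry import ClusterConfiguration, WaterMonomer, identify_waters
from .parameters import SITE_H, SITE_M, SITE_O, IonWaterParameters

__all__ = ["WaterModelResult", "SimpleRigidWater", "register_water_model", "get_water_model"]


@dataclass
class WaterModelResult:
    """One-shot water-model evaluation (the plug-in contract's return value)."""

    e_intra: float  # kcal/mol
    e_inter: float  # kcal/mol, non-induction water-water
    charges: np.ndarray  # per site, [H1, H2, O, M] x n_waters, e
    alphas: np.ndarray  # per site, A^3


class SimpleRigidWater:
    """Simplified reference water model behind the plug-in interface.

    Intramolecular distortion is harmonic around the rigid reference geometry
    (r_OH = 0.9572 A, HOH = 104.52 deg); on rigid geometries it is exactly 0.
    Water-water interactions are smeared permanent electrostatics between the
    TTM-style sites plus an O-O Born-Mayer repulsion and damped dispersion.
    Charges and polarizabilities are taken from the ion-water parameter
    document so one JSON file describes the whole system.
    """

    #: harmonic force constants (SPC/Fw-like magnitudes)
    K_R = 1059.162  # kcal/mol/A^2
    K_THETA = 75.90  # kcal/mol/rad^2
    #: O-O short-range pair term
    A_OO = 1.0e5  # kcal/mol
    BETA_OO = 3.55  # 1/A
    C6_OO = 1500.0  # kcal*A^6/mol

    def __init__(self, params: IonWaterParameters):
        self.params = params
        self.r0 = WATER_ROH
        self.theta0 = math.radians(WATER_HOH)

    # -- contract ----------------------------------------------------------
    def site_properties(self, n_waters: int):
        """(charges, alphas) arrays for n_waters monomers, [H1,H2,O,M] order."""
        p = self.params
        q_h = p.sites[SITE_H].charge
        q_m = p.sites[SITE_M].charge
        a_h = p.sites[SITE_H].polarizability
        a_o = p.sites[SITE_O].polarizability
        charges = np.tile([q_h, q_h, 0.0, q_m], n_waters)
        alphas = np.tile([a_h, a_h, a_o, 0.0], n_waters)
        return charges, alphas

    def energies(self, config: ClusterConfiguration, monomers: list[WaterMonomer] | None = None):
        """(e_intra, e_inter) for a pure-water configuration, kcal/mol."""
        if monomers is None:
            monomers = identify_waters(config)
        e_intra = sum(self._monomer_energy(m) for m in monomers)
        e_inter = self._pair_energy(config, monomers)
        return float(e_intra), float(e_inter)

    def evaluate(self, config: ClusterConfiguration) -> WaterModelResult:
        monomers = identify_waters(config)
        e_intra, e_inter = self.energies(config, monomers)
        charges, alphas = self.site_properties(len(monomers))
        return WaterModelResult(e_intra, e_inter, charges, alphas)

    # -- internals ----------------------------------------------------------
    def _monomer_energy(self, mono: WaterMonomer) -> float:
        dr1 = mono.r_oh1 - self.r0
        dr2 = mono.r_oh2 - self.r0
        dth = math.radians(mono.angle_hoh) - self.theta0
        return 0.5 * self.K_R * (dr1 * dr1 + dr2 * dr2) + 0.5 * self.K_THETA * dth * dth

    def _pair_energy(self, config: ClusterConfiguration, monomers) -> float:
        if len(monomers) < 2:
            return 0.0
        # electrostatics over the water-only site system
        from .potential import build_site_system, tang_toennies

        system = build_site_system(self.params, config, water_model=self, include_ion=False,
                                   monomers=monomers)
        e = system.electrostatic_energy()
        pos = config.positions
        for i in range(len(monomers)):
            for j in range(i + 1, len(monomers)):
                r = float(np.linalg.norm(pos[monomers[i].o_index] - pos[monomers[j].o_index]))
                e += self.A_OO * math.exp(-self.BETA_OO * r)
                e -= self.C6_OO * tang_toennies(6, self.BETA_OO, r) / r**6
        return e


_REGISTRY: dict[str, type] = {}


def register_water_model(name: str, factory) -> None:
    """Register a water-model factory ``factory(params) -> model``."""
    _REGISTRY[name.lower()] = factory


def get_water_model(params: IonWaterParameters):
    """Instantiate the water model selected by ``params.model``."""
    try:
        factory = _REGISTRY[params.model.lower()]
    except KeyError:
        raise ConfigurationError(
            f"no water model registered under {params.model!r}; "
            f"known: {sorted(_REGISTRY)}"
        ) from None
    return factory(params)


for _name in ("custom", "i-ttm2", "i-ttm3", "i-ttm4", "i-mbpol"):
    register_water_model(_name, SimpleRigidWater)
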