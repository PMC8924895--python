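"""Model parameters for the halide-ion/water potential.

An :class:`IonWaterParameters` object carries everything the energy kernels
need beyond the geometry: the Born-Mayer / dispersion pair terms for the
ion-O and ion-H pairs, the electrostatic site templates (charges, Gaussian
smearing widths, polarizabilities, Thole damping factors), the M-site
placement, and the name of the water model that supplies water-water terms.

Serialization is a flat JSON document versioned by the ``model`` field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

from .constants import (
    COULOMB_CONSTANT,
    HALIDE_CHARGE,
    HALIDE_POLARIZABILITY,
    HALIDES,
)
from .errors import ConfigurationError, DomainError

__all__ = [
    "PairShortRange",
    "ElectrostaticSite",
    "IonWaterParameters",
    "toy_parameters",
    "load_parameters",
    "save_parameters",
]

PAIR_ION_O = "ion-O"
PAIR_ION_H = "ion-H"


@dataclass
class PairShortRange:
    """Born-Mayer repulsion + damped dispersion for one ion-atom pair.

    The repulsion is ``a * exp(-beta * R)`` (kcal/mol, beta in 1/A stored
    positive) and the dispersion ``-c6 * f6(delta * R) / R^6`` with the
    sixth-order Tang-Toennies damping function f6. When ``delta`` is None the
    delta=beta coupling rule is in force and the damping steepness tracks the
    repulsion exponent.
    """

    a: float
    beta: float
    c6: float
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.a < 0:
            raise DomainError(f"A must be >= 0, got {self.a}")
        if self.beta <= 0:
            raise DomainError(f"beta must be > 0, got {self.beta}")
        if self.c6 < 0:
            raise DomainError(f"C6 must be >= 0, got {self.c6}")
        if self.delta is not None and self.delta <= 0:
            raise DomainError(f"delta must be > 0, got {self.delta}")

    @property
    def effective_delta(self) -> float:
        """Damping steepness: explicit delta, or beta under the delta=beta rule."""
        return self.beta if self.delta is None else self.delta


@dataclass
class ElectrostaticSite:
    """Template for one electrostatic site kind.

    charge in e; smearing_width is the Gaussian charge width in A (0 means a
    point charge); polarizability in A^3 (0 for non-polarizable sites);
    thole_damping is the dimensionless factor scaling the dipole smearing
    width ``thole_damping * alpha**(1/3)``.
    """

    site_kind: str
    charge: float
    smearing_width: float = 0.0
    polarizability: float = 0.0
    thole_damping: float = 1.0

    def __post_init__(self) -> None:
        if self.smearing_width < 0:
            raise DomainError("smearing_width must be >= 0")
        if self.polarizability < 0:
            raise DomainError("polarizability must be >= 0")
        if self.thole_damping <= 0:
            raise DomainError("thole_damping must be > 0")


# canonical site-template keys
SITE_H = "H-charge"
SITE_M = "M-site"
SITE_O = "O-pol"
SITE_ION = "ion"

KNOWN_MODELS = ("i-TTM2", "i-TTM3", "i-TTM4", "i-MBpol", "custom")


@dataclass
class IonWaterParameters:
    """Complete parameter set for one halide ion.

    ``m_site_fraction`` places the massless M charge site along the HOH
    bisector at ``m_site_fraction * m_site_reference_offset`` angstrom from
    the oxygen (toward the hydrogens). ``intra_thole_scale`` multiplies the
    dipole-dipole smearing width for site pairs inside one monomer (the
    increased intramolecular damping of TTM-style models).
    """

    ion: str
    pair_terms: dict = field(default_factory=dict)
    sites: dict = field(default_factory=dict)
    m_site_fraction: float = 1.0
    m_site_reference_offset: float = 0.147
    coulomb_constant: float = COULOMB_CONSTANT
    intra_thole_scale: float = 3.0
    model: str = "custom"

    def __post_init__(self) -> None:
        if self.ion not in HALIDES:
            raise DomainError(f"ion must be one of {sorted(HALIDES)}, got {self.ion!r}")
        for key in (PAIR_ION_O, PAIR_ION_H):
            if key not in self.pair_terms:
                raise ConfigurationError(f"missing pair term {key!r}")
        if not (0.0 < self.m_site_fraction <= 1.0):
            raise DomainError(f"m_site_fraction must be in (0, 1], got {self.m_site_fraction}")
        for key in (SITE_H, SITE_M, SITE_O, SITE_ION):
            if key not in self.sites:
                raise ConfigurationError(f"missing site template {key!r}")
        ion_site = self.sites[SITE_ION]
        if abs(ion_site.charge - HALIDE_CHARGE) > 1e-12:
            raise DomainError(f"ion charge must be {HALIDE_CHARGE} e, got {ion_site.charge}")
        q_h = self.sites[SITE_H].charge
        q_m = self.sites[SITE_M].charge
        if abs(q_m + 2.0 * q_h) > 1e-10:
            raise DomainError(
                f"water sites must be neutral per monomer: q_M={q_m} but -2*q_H={-2 * q_h}"
            )
        if self.model not in KNOWN_MODELS:
            raise DomainError(f"model must be one of {KNOWN_MODELS}, got {self.model!r}")

    # convenient accessors -------------------------------------------------
    @property
    def pair_o(self) -> PairShortRange:
        return self.pair_terms[PAIR_ION_O]

    @property
    def pair_h(self) -> PairShortRange:
        return self.pair_terms[PAIR_ION_H]

    @property
    def q_h(self) -> float:
        return self.sites[SITE_H].charge

    @property
    def m_site_offset(self) -> float:
        """Actual O-to-M distance along the bisector, angstrom."""
        return self.m_site_fraction * self.m_site_reference_offset

    def with_pair_terms(self, pair_o: PairShortRange, pair_h: PairShortRange) -> "IonWaterParameters":
        new = replace(self)
        new.pair_terms = dict(self.pair_terms)
        new.pair_terms[PAIR_ION_O] = pair_o
        new.pair_terms[PAIR_ION_H] = pair_h
        return new

    def content_hash(self) -> str:
        """Stable hash of the parameter content (used in dataset provenance)."""
        return hashlib.sha256(
            json.dumps(_to_dict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# JSON serialization


def _to_dict(params: IonWaterParameters) -> dict:
    return {
        "model": params.model,
        "ion": params.ion,
        "pair_terms": {k: asdict(v) for k, v in params.pair_terms.items()},
        "sites": {k: asdict(v) for k, v in params.sites.items()},
        "m_site_fraction": params.m_site_fraction,
        "m_site_reference_offset": params.m_site_reference_offset,
        "coulomb_constant": params.coulomb_constant,
        "intra_thole_scale": params.intra_thole_scale,
    }


def save_parameters(params: IonWaterParameters, path) -> None:
    with open(path, "w") as fh:
        json.dump(_to_dict(params), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_parameters(path) -> IonWaterParameters:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        pair_terms = {k: PairShortRange(**v) for k, v in doc["pair_terms"].items()}
        sites = {k: ElectrostaticSite(**v) for k, v in doc["sites"].items()}
        return IonWaterParameters(
            ion=doc["ion"],
            pair_terms=pair_terms,
            sites=sites,
            m_site_fraction=doc.get("m_site_fraction", 1.0),
            m_site_reference_offset=doc.get("m_site_reference_offset", 0.147),
            coulomb_constant=doc.get("coulomb_constant", COULOMB_CONSTANT),
            intra_thole_scale=doc.get("intra_thole_scale", 3.0),
            model=doc.get("model", "custom"),
        )
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing parameter field {exc}") from None
    except TypeError as exc:
        raise ConfigurationError(f"{path}: malformed parameter document ({exc})") from None


# ---------------------------------------------------------------------------
# Toy / synthetic parameter sets

# Born-Mayer and dispersion defaults per halide, chosen once to give
# physically sensible dimer minima (depth grows F > Cl > Br > I, minimum
# R(ion-O) increasing down the group). These are synthetic study conditions,
# not literature fits.
_TOY_SHORT_RANGE: dict[str, dict] = {
    "F": {"a_o": 4.0e4, "b_o": 3.6, "c6_o": 1.2e3, "a_h": 6.0e3, "b_h": 3.2, "c6_h": 4.0e2},
    "Cl": {"a_o": 6.0e4, "b_o": 3.2, "c6_o": 3.0e3, "a_h": 8.0e3, "b_h": 2.9, "c6_h": 8.0e2},
    "Br": {"a_o": 7.0e4, "b_o": 3.0, "c6_o": 4.2e3, "a_h": 9.0e3, "b_h": 2.8, "c6_h": 1.1e3},
    "I": {"a_o": 8.0e4, "b_o": 2.8, "c6_o": 6.0e3, "a_h": 1.0e4, "b_h": 2.6, "c6_h": 1.5e3},
}

# Water-site defaults: fixed charges in rigid-water mode (q_M = -2 q_H),
# Thole-style atomic polarizabilities for O and H, Gaussian widths in A.
_TOY_Q_H = 0.574
_TOY_ALPHA_O = 0.837
_TOY_ALPHA_H = 0.496
_TOY_WIDTH = 0.4


def toy_parameters(ion: str = "Cl", model: str = "custom") -> IonWaterParameters:
    """A self-contained synthetic parameter set for the given halide.

    Used as ground truth in fit-recovery fixtures and as a sensible starting
    point for user fits; the values are the package's own defaults.
    """
    if ion not in _TOY_SHORT_RANGE:
        raise DomainError(f"no toy parameters for ion {ion!r}")
    t = _TOY_SHORT_RANGE[ion]
    pair_terms = {
        PAIR_ION_O: PairShortRange(a=t["a_o"], beta=t["b_o"], c6=t["c6_o"]),
        PAIR_ION_H: PairShortRange(a=t["a_h"], beta=t["b_h"], c6=t["c6_h"]),
    }
    sites = {
        SITE_H: ElectrostaticSite(SITE_H, charge=_TOY_Q_H, smearing_width=_TOY_WIDTH,
                                  polarizability=_TOY_ALPHA_H),
        SITE_M: ElectrostaticSite(SITE_M, charge=-2.0 * _TOY_Q_H, smearing_width=_TOY_WIDTH),
        SITE_O: ElectrostaticSite(SITE_O, charge=0.0, polarizability=_TOY_ALPHA_O),
        SITE_ION: ElectrostaticSite(SITE_ION, charge=HALIDE_CHARGE, smearing_width=0.6,
                                    polarizability=HALIDE_POLARIZABILITY[ion]),
    }
    return IonWaterParameters(ion=ion, pair_terms=pair_terms, sites=sites, model=model)
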