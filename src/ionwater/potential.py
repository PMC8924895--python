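"""Energy kernels for the halide-ion/water interaction.

The ion-water intermolecular energy is a sum of four contributions::

    V_iw = V_rep(2B) + V_disp(2B) + V_elec(2B) + V_ind(nB)

* ``V_rep``: Born-Mayer repulsion A*exp(-beta*R) over ion-O and ion-H pairs.
* ``V_disp``: damped dispersion -C6*f6(delta*R)/R^6 with the sixth-order
  Tang-Toennies damping function; by default the damping steepness equals
  the Born-Mayer exponent (delta = beta rule).
* ``V_elec``: permanent charge-charge electrostatics between Gaussian-smeared
  charges on different monomers (H charges, the M site on the HOH bisector,
  and the -1e ion charge).
* ``V_ind``: many-body polarization. Each polarizable site (O, H, ion)
  carries an isotropic dipole responding self-consistently to the permanent
  field and to all other induced dipoles through Thole-damped dipole-dipole
  tensors. This term is nonadditive: it is solved over the full site set.

Charge smearing uses Gaussian distributions, which give closed-form erf
screening for charge-charge, charge-dipole and dipole-dipole interactions
and recover the point-charge limit exactly as the widths go to zero.
Gaussian widths combine as ``sqrt(w_i^2 + w_j^2)``; the dipole width of a
polarizable site is ``thole_damping * alpha**(1/3)`` and intramonomer
dipole-dipole pairs use an increased damping width (``intra_thole_scale``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf, gammainc

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    DomainError,
    ModelError,
    SolverError,
)
from .geometry import ClusterConfiguration, WaterMonomer, identify_waters
from .parameters import (
    SITE_H,
    SITE_ION,
    SITE_M,
    SITE_O,
    IonWaterParameters,
)

__all__ = [
    "EnergyBreakdown",
    "InducedDipoleState",
    "SiteSystem",
    "tang_toennies",
    "born_mayer_energy",
    "dispersion_energy",
    "permanent_electrostatics",
    "solve_induced_dipoles",
    "induction_energy",
    "ion_water_energy",
    "total_energy",
    "interaction_energy",
    "build_site_system",
]

_TWO_OVER_SQRT_PI = 2.0 / math.sqrt(math.pi)
_R_MIN = 1e-8  # below this separation a pair interaction is degenerate


# ---------------------------------------------------------------------------
# Scalar kernels


def tang_toennies(order: int, delta: float, R):
    """Tang-Toennies damping function f_n(delta*R).

    ``f_n(x) = 1 - exp(-x) * sum_{k=0}^{n} x^k / k!`` with ``x = delta*R``,
    evaluated through the regularized lower incomplete gamma function
    ``P(n+1, x)``, which is that series identically. Monotonically increasing
    in R, 0 at R=0, -> 1 as R -> infinity.
    """
    if int(order) != order or order < 0:
        raise DomainError(f"order must be a non-negative integer, got {order}")
    if delta <= 0:
        raise DomainError(f"delta must be > 0, got {delta}")
    x = np.asarray(delta * np.asarray(R, dtype=float))
    if np.any(x < 0):
        raise DomainError("R must be >= 0")
    out = gammainc(int(order) + 1, x)
    return float(out) if out.ndim == 0 else out


def _screen_charge(x):
    """Charge-charge screening: erf(x), the potential of a Gaussian charge."""
    return erf(x)


def _screen_l3(x):
    """lambda_3 screening for fields / the 1/R^3 part of dipole tensors."""
    return erf(x) - _TWO_OVER_SQRT_PI * x * np.exp(-x * x)


def _screen_l5(x):
    """lambda_5 screening for the 3*rr/R^5 part of dipole tensors."""
    return erf(x) - _TWO_OVER_SQRT_PI * x * (1.0 + 2.0 * x * x / 3.0) * np.exp(-x * x)


# ---------------------------------------------------------------------------
# Site system


@dataclass
class SiteSystem:
    """Flat arrays describing all electrostatic sites of a configuration.

    Site order: per water monomer [H1, H2, O, M], then the ion (if present).
    ``groups`` labels the monomer each site belongs to (the ion is its own
    group); intragroup pairs never interact through permanent electrostatics.
    """

    positions: np.ndarray  # (S, 3) A
    charges: np.ndarray  # (S,) e
    charge_widths: np.ndarray  # (S,) A, Gaussian width, 0 = point
    alphas: np.ndarray  # (S,) A^3
    dipole_widths: np.ndarray  # (S,) A, 0 for non-polarizable
    groups: np.ndarray  # (S,) int
    k: float  # Coulomb constant, kcal*A/(mol*e^2)
    intra_thole_scale: float = 3.0

    @property
    def n_sites(self) -> int:
        return len(self.charges)

    @property
    def pol_index(self) -> np.ndarray:
        return np.flatnonzero(self.alphas > 0)

    # -- permanent electrostatics ------------------------------------------
    def _pair_geometry(self):
        d = self.positions[:, None, :] - self.positions[None, :, :]
        r = np.linalg.norm(d, axis=-1)
        inter = self.groups[:, None] != self.groups[None, :]
        return d, r, inter

    def electrostatic_energy(self) -> float:
        """k * sum over intergroup site pairs of q_i q_j erf(R/gamma)/R."""
        if self.n_sites < 2:
            return 0.0
        _, r, inter = self._pair_geometry()
        iu = np.triu_indices(self.n_sites, k=1)
        sel = inter[iu]
        rr = r[iu][sel]
        qi = self.charges[iu[0]][sel]
        qj = self.charges[iu[1]][sel]
        live = (qi != 0) & (qj != 0)
        if np.any(rr[live] < _R_MIN):
            raise DegenerateGeometryError("coincident interacting sites")
        gam = np.sqrt(self.charge_widths[iu[0]][sel] ** 2 + self.charge_widths[iu[1]][sel] ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            screen = np.where(gam > 0, _screen_charge(np.where(rr > 0, rr, 1.0) / np.where(gam > 0, gam, 1.0)), 1.0)
            term = np.where(live, qi * qj * screen / np.where(rr > 0, rr, 1.0), 0.0)
        return float(self.k * term.sum())

    def permanent_fields(self) -> np.ndarray:
        """Fields at polarizable sites from charges in other groups.

        Returned WITHOUT the Coulomb constant (units e/A^2); multiply by
        ``k`` for kcal/(mol*e*A).
        """
        pol = self.pol_index
        fields = np.zeros((len(pol), 3))
        if len(pol) == 0 or self.n_sites == 0:
            return fields
        src = np.flatnonzero(self.charges != 0)
        if len(src) == 0:
            return fields
        d = self.positions[pol][:, None, :] - self.positions[src][None, :, :]  # target - source
        r = np.linalg.norm(d, axis=-1)
        inter = self.groups[pol][:, None] != self.groups[src][None, :]
        if np.any(r[inter] < _R_MIN):
            raise DegenerateGeometryError("polarizable site coincides with a charge")
        gam = np.sqrt(self.dipole_widths[pol][:, None] ** 2 + self.charge_widths[src][None, :] ** 2)
        rs = np.where(r > 0, r, 1.0)
        lam = np.where(gam > 0, _screen_l3(rs / np.where(gam > 0, gam, 1.0)), 1.0)
        w = np.where(inter, self.charges[src][None, :] * lam / rs**3, 0.0)
        return np.einsum("ts,tsx->tx", w, d)

    # -- induced dipoles ----------------------------------------------------
    def dipole_interaction_matrix(self) -> np.ndarray:
        """Thole-damped dipole-dipole tensor T as a (3P, 3P) block matrix."""
        pol = self.pol_index
        P = len(pol)
        T = np.zeros((3 * P, 3 * P))
        if P < 2:
            return T
        pos = self.positions[pol]
        wid = self.dipole_widths[pol]
        grp = self.groups[pol]
        eye = np.eye(3)
        for i in range(P):
            for j in range(i + 1, P):
                d = pos[i] - pos[j]
                r = float(np.linalg.norm(d))
                if r < _R_MIN:
                    raise DegenerateGeometryError("coincident polarizable sites")
                gam = math.sqrt(wid[i] ** 2 + wid[j] ** 2)
                if grp[i] == grp[j]:
                    gam *= self.intra_thole_scale
                if gam > 0:
                    x = r / gam
                    l3, l5 = float(_screen_l3(x)), float(_screen_l5(x))
                else:
                    l3 = l5 = 1.0
                rhat = d / r
                block = (3.0 * l5 * np.outer(rhat, rhat) - l3 * eye) / r**3
                T[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
                T[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        return T


@dataclass
class EnergyBreakdown:
    """Term-by-term decomposition of the ion-water interaction, kcal/mol."""

    rep: float
    disp: float
    elec: float
    ind: float

    @property
    def total(self) -> float:
        return self.rep + self.disp + self.elec + self.ind


@dataclass
class InducedDipoleState:
    """Converged induced dipoles (e*A per polarizable site)."""

    dipoles: np.ndarray  # (P, 3)
    residual: float  # max component change in the last iteration, e*A
    iterations: int
    converged: bool
    method: str = "iterative"


# ---------------------------------------------------------------------------
# Site-system construction


def _monomer_sites(params: IonWaterParameters, pos: np.ndarray, mono: WaterMonomer):
    """Positions of [H1, H2, O, M] for one monomer."""
    o = pos[mono.o_index]
    h1 = pos[mono.h1_index]
    h2 = pos[mono.h2_index]
    bis = 0.5 * (h1 + h2) - o
    nb = np.linalg.norm(bis)
    if nb < _R_MIN:
        raise DegenerateGeometryError(f"degenerate HOH bisector for monomer at O {mono.o_index}")
    m = o + params.m_site_offset * bis / nb
    return [h1, h2, o, m]


def water_site_arrays(
    params: IonWaterParameters,
    config: ClusterConfiguration,
    monomers: list[WaterMonomer] | None = None,
):
    """(positions, charge_widths, dipole_widths, groups) for the water sites.

    Charges and polarizabilities are supplied separately by the water model
    (plug-in contract); only the geometric and smearing data live here.
    """
    if monomers is None:
        monomers = identify_waters(config)
    pos = config.positions
    s_h = params.sites[SITE_H].smearing_width
    s_m = params.sites[SITE_M].smearing_width
    t_h = params.sites[SITE_H].thole_damping
    t_o = params.sites[SITE_O].thole_damping
    a_h = params.sites[SITE_H].polarizability
    a_o = params.sites[SITE_O].polarizability
    positions, cw, dw, groups = [], [], [], []
    for g, mono in enumerate(monomers):
        positions.extend(_monomer_sites(params, pos, mono))
        cw.extend([s_h, s_h, params.sites[SITE_O].smearing_width, s_m])
        dw.extend([t_h * a_h ** (1.0 / 3.0) if a_h > 0 else 0.0] * 2
                  + [t_o * a_o ** (1.0 / 3.0) if a_o > 0 else 0.0, 0.0])
        groups.extend([g, g, g, g])
    return (
        np.array(positions).reshape(-1, 3),
        np.array(cw),
        np.array(dw),
        np.array(groups, dtype=int),
    )


def build_site_system(
    params: IonWaterParameters,
    config: ClusterConfiguration,
    water_model=None,
    include_ion: bool = True,
    monomers: list[WaterMonomer] | None = None,
) -> SiteSystem:
    """Assemble the full electrostatic site system for a configuration.

    Water-site charges and polarizabilities come from the water model
    (default: the model registered under ``params.model``); the ion site
    comes from the parameter set. ``include_ion=False`` builds the water-only
    system used for interaction-energy differences.
    """
    if monomers is None:
        monomers = identify_waters(config) if config.n_waters else []
    if water_model is None:
        from .watermodels import get_water_model

        water_model = get_water_model(params)
    n_w = len(monomers)
    if n_w:
        wpos, wcw, wdw, wgroups = water_site_arrays(params, config, monomers)
        charges, alphas = water_model.site_properties(n_w)
    else:
        wpos = np.zeros((0, 3))
        wcw = wdw = charges = alphas = np.zeros(0)
        wgroups = np.zeros(0, dtype=int)
    if include_ion and config.has_ion:
        ion_t = params.sites[SITE_ION]
        wpos = np.vstack([wpos, config.ion.position[None, :]])
        charges = np.concatenate([charges, [ion_t.charge]])
        wcw = np.concatenate([wcw, [ion_t.smearing_width]])
        a_i = ion_t.polarizability
        wdw = np.concatenate(
            [wdw, [ion_t.thole_damping * a_i ** (1.0 / 3.0) if a_i > 0 else 0.0]]
        )
        alphas = np.concatenate([alphas, [a_i]])
        wgroups = np.concatenate([wgroups, [n_w]])
    return SiteSystem(
        positions=wpos,
        charges=np.asarray(charges, dtype=float),
        charge_widths=wcw,
        alphas=np.asarray(alphas, dtype=float),
        dipole_widths=wdw,
        groups=wgroups,
        k=params.coulomb_constant,
        intra_thole_scale=params.intra_thole_scale,
    )


# ---------------------------------------------------------------------------
# Pairwise short-range terms


def _ion_pair_distances(config: ClusterConfiguration):
    """Distances from the ion to every O and every H atom."""
    if not config.has_ion:
        raise DomainError("configuration has no ion")
    ion = config.ion.position
    pos = config.positions
    r_o = np.array(
        [np.linalg.norm(pos[i] - ion) for i, a in enumerate(config.atoms) if a.element == "O"]
    )
    r_h = np.array(
        [np.linalg.norm(pos[i] - ion) for i, a in enumerate(config.atoms) if a.element == "H"]
    )
    if (len(r_o) and r_o.min() < _R_MIN) or (len(r_h) and r_h.min() < _R_MIN):
        raise DegenerateGeometryError("ion coincides with a water atom")
    return r_o, r_h


def born_mayer_energy(params: IonWaterParameters, config: ClusterConfiguration) -> float:
    """Sum of A*exp(-beta*R) over ion-O and ion-H pairs, kcal/mol."""
    r_o, r_h = _ion_pair_distances(config)
    po, ph = params.pair_o, params.pair_h
    return float(po.a * np.exp(-po.beta * r_o).sum() + ph.a * np.exp(-ph.beta * r_h).sum())


def dispersion_energy(params: IonWaterParameters, config: ClusterConfiguration) -> float:
    """Damped dispersion -C6*f6(delta*R)/R^6 over ion-O and ion-H pairs."""
    r_o, r_h = _ion_pair_distances(config)
    out = 0.0
    for pair, r in ((params.pair_o, r_o), (params.pair_h, r_h)):
        if pair.c6 > 0 and len(r):
            f6 = tang_toennies(6, pair.effective_delta, r)
            out -= float(pair.c6 * np.sum(f6 / r**6))
    return out


# ---------------------------------------------------------------------------
# Electrostatics and induction


def permanent_electrostatics(
    params: IonWaterParameters,
    config: ClusterConfiguration,
    water_model=None,
    include_ion: bool = True,
):
    """Permanent smeared-charge electrostatics and fields at polarizable sites.

    Returns ``(energy, fields)``: the pairwise intermonomer charge-charge
    energy in kcal/mol, and the field each polarizable site feels from all
    permanent charges outside its own monomer, in kcal/(mol*e*A).
    """
    system = build_site_system(params, config, water_model, include_ion=include_ion)
    energy = system.electrostatic_energy()
    fields = params.coulomb_constant * system.permanent_fields()
    return energy, fields


def _solve_system_dipoles(
    system: SiteSystem,
    fields_nok: np.ndarray,
    method: str = "auto",
    tol: float = 1e-8,
    max_iterations: int = 200,
) -> InducedDipoleState:
    """Solve mu_i = alpha_i (E_i + sum_j T_ij mu_j) on a site system.

    ``fields_nok`` are the permanent fields WITHOUT the Coulomb constant.
    """
    pol = system.pol_index
    P = len(pol)
    if P == 0:
        return InducedDipoleState(np.zeros((0, 3)), 0.0, 0, True, method)
    alphas = system.alphas[pol]
    E = np.asarray(fields_nok, dtype=float).reshape(P, 3)
    if not np.any(E):
        return InducedDipoleState(np.zeros((P, 3)), 0.0, 0, True, method)
    T = system.dipole_interaction_matrix()

    def direct() -> np.ndarray:
        A = np.kron(np.diag(1.0 / alphas), np.eye(3)) - T
        try:
            np.linalg.cholesky(0.5 * (A + A.T))
        except np.linalg.LinAlgError:
            raise ModelError(
                "polarization catastrophe: dipole interaction matrix is not positive definite"
            ) from None
        return np.linalg.solve(A, E.ravel()).reshape(P, 3)

    if method == "direct":
        return InducedDipoleState(direct(), 0.0, 0, True, "direct")

    mu = (alphas[:, None] * E).ravel()
    e_flat = E.ravel()
    alpha3 = np.repeat(alphas, 3)
    omega = 0.65  # fixed-point mixing; plain iteration can overshoot for close sites
    residual = np.inf
    # stop a factor of 10 below tol: the per-step change underestimates the
    # distance to the fixed point by ~1/(1 - contraction rate)
    stop = 0.1 * tol
    for it in range(1, max_iterations + 1):
        mu_new = alpha3 * (e_flat + T @ mu)
        step = (1.0 - omega) * mu + omega * mu_new
        residual = float(np.max(np.abs(step - mu)))
        mu = step
        if residual <= stop:
            return InducedDipoleState(mu.reshape(P, 3), residual, it, True, "iterative")
    if method == "iterative":
        raise SolverError(
            f"induced dipoles did not converge in {max_iterations} iterations "
            f"(residual {residual:.3e} e*A)"
        )
    return InducedDipoleState(direct(), 0.0, max_iterations, True, "direct")


def solve_induced_dipoles(
    params: IonWaterParameters,
    config: ClusterConfiguration,
    permanent_fields: np.ndarray | None = None,
    water_model=None,
    method: str = "auto",
    tol: float = 1e-8,
    max_iterations: int = 200,
) -> InducedDipoleState:
    """Self-consistent induced dipoles for a full configuration.

    ``permanent_fields`` (kcal/(mol*e*A), as returned by
    :func:`permanent_electrostatics`) are recomputed when omitted.
    """
    system = build_site_system(params, config, water_model)
    if permanent_fields is None:
        fields_nok = system.permanent_fields()
    else:
        fields_nok = np.asarray(permanent_fields, dtype=float) / params.coulomb_constant
    return _solve_system_dipoles(system, fields_nok, method, tol, max_iterations)


def induction_energy(state: InducedDipoleState, permanent_fields: np.ndarray) -> float:
    """U_ind = -1/2 sum_i mu_i . E_perm,i, kcal/mol; never positive.

    ``permanent_fields`` must include the Coulomb constant (the units
    returned by :func:`permanent_electrostatics`).
    """
    if not state.converged:
        raise SolverError("refusing to evaluate induction energy from an unconverged state")
    if state.dipoles.size == 0:
        return 0.0
    return float(-0.5 * np.sum(state.dipoles * np.asarray(permanent_fields)))


# ---------------------------------------------------------------------------
# Assembled energies


def _induction_total(system: SiteSystem) -> float:
    # dipoles converged well below the 1e-9 kcal/mol energy-invariance
    # contract, so assembled energies are orientation-independent
    fields_nok = system.permanent_fields()
    state = _solve_system_dipoles(system, fields_nok, tol=1e-11)
    return float(-0.5 * system.k * np.sum(state.dipoles * fields_nok))


def ion_water_energy(
    params: IonWaterParameters,
    config: ClusterConfiguration,
    water_model=None,
) -> EnergyBreakdown:
    """Ion-water intermolecular interaction energy, term by term.

    ``elec`` and ``ind`` are the full-system values minus the water-only
    values at the same geometry, so for multi-water clusters the induction
    contribution is many-body (the ion both polarizes the waters and changes
    their mutual polarization), not a sum over ion-water dimers.
    """
    if not config.has_ion:
        raise DomainError("ion_water_energy requires an ion")
    monomers = identify_waters(config) if config.n_waters else []
    if not monomers:
        return EnergyBreakdown(0.0, 0.0, 0.0, 0.0)
    rep = born_mayer_energy(params, config)
    disp = dispersion_energy(params, config)
    full = build_site_system(params, config, water_model, monomers=monomers)
    waters = build_site_system(
        params, config, water_model, include_ion=False, monomers=monomers
    )
    elec = full.electrostatic_energy() - waters.electrostatic_energy()
    ind = _induction_total(full) - _induction_total(waters)
    return EnergyBreakdown(rep=rep, disp=disp, elec=elec, ind=ind)


def total_energy(
    params: IonWaterParameters,
    water_model,
    config: ClusterConfiguration,
) -> float:
    """Full cluster energy: V_W_intra + V_WW_inter + V_iW_inter, kcal/mol.

    Induced dipoles are solved over the full site set (ion + all waters).
    With no ion present this reduces exactly to the water model's energy
    (intra + intermolecular + water-only induction).
    """
    if water_model is None:
        raise ConfigurationError("total_energy requires a water model")
    if config.n_waters == 0:
        return 0.0  # an isolated classical ion has zero internal energy
    waters_config = config.without_ion() if config.has_ion else config
    monomers_w = identify_waters(waters_config)
    e_intra, e_ww = water_model.energies(waters_config, monomers_w)
    waters_sys = build_site_system(params, waters_config, water_model, monomers=monomers_w)
    e_w = e_intra + e_ww + _induction_total(waters_sys)
    if not config.has_ion:
        return float(e_w)
    iw = ion_water_energy(params, config, water_model)
    return float(e_w + iw.total)


def interaction_energy(
    params: IonWaterParameters,
    water_model,
    config: ClusterConfiguration,
) -> float:
    """Interaction energy dE = E(X-(H2O)n) - E((H2O)n) - E(X-), kcal/mol.

    The water-cluster energy is evaluated at the same geometry; the isolated
    classical ion has zero energy, so dE collapses to the ion-water
    intermolecular energy.
    """
    if not config.has_ion:
        raise DomainError("interaction_energy requires an ion")
    if water_model is None:
        from .watermodels import get_water_model

        water_model = get_water_model(params)
    e_cluster = total_energy(params, water_model, config)
    e_waters = total_energy(params, water_model, config.without_ion())
    return float(e_cluster - e_waters - 0.0)
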