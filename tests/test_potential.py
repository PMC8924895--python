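"""Energy kernels: closed-form oracles, solver agreement, invariances."""

import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ionwater.constants import COULOMB_CONSTANT as K
from ionwater.dataset import dimer_from_spherical, rigid_water_monomer
from ionwater.errors import (
    DegenerateGeometryError,
    DomainError,
    ModelError,
    SolverError,
)
from ionwater.geometry import Atom, ClusterConfiguration
from ionwater.potential import (
    InducedDipoleState,
    SiteSystem,
    _solve_system_dipoles,
    born_mayer_energy,
    dispersion_energy,
    induction_energy,
    interaction_energy,
    ion_water_energy,
    permanent_electrostatics,
    solve_induced_dipoles,
    tang_toennies,
    total_energy,
)
from ionwater.watermodels import get_water_model

from conftest import make_params, water_cluster


# ---------------------------------------------------------------------------
# Tang-Toennies damping


def tt_series_oracle(order: int, x: float) -> float:
    """f_n(x) = 1 - exp(-x) sum_{k<=n} x^k/k! at 50 decimal digits."""
    getcontext().prec = 50
    xd = Decimal(repr(x))
    total = Decimal(0)
    term = Decimal(1)
    for k in range(order + 1):
        if k > 0:
            term = term * xd / k
        total += term
    return float(Decimal(1) - (-xd).exp() * total)


@pytest.mark.parametrize("order", [0, 1, 3, 6])
@pytest.mark.parametrize("x", [0.1, 1.0, 2.0, 5.0, 10.0])
def test_tang_toennies_matches_extended_precision_series(order, x):
    got = tang_toennies(order, 1.0, x)
    want = tt_series_oracle(order, x)
    assert got == pytest.approx(want, rel=1e-8)


def test_tang_toennies_zero_at_r_zero_and_one_at_infinity():
    assert tang_toennies(6, 2.0, 0.0) == 0.0
    assert tang_toennies(6, 2.0, 1e4) == pytest.approx(1.0, abs=1e-12)


def test_tang_toennies_monotonic_in_r_and_order():
    r = np.linspace(0.1, 10, 200)
    f = tang_toennies(6, 1.5, r)
    assert np.all(np.diff(f) > 0)
    assert np.all((f >= 0) & (f <= 1))
    # higher order switches on later: smaller f at the same x
    for n in range(6):
        assert tang_toennies(n + 1, 1.0, 2.5) < tang_toennies(n, 1.0, 2.5)


def test_tang_toennies_negative_order_rejected():
    with pytest.raises(DomainError):
        tang_toennies(-1, 1.0, 1.0)


# ---------------------------------------------------------------------------
# Born-Mayer repulsion


def test_born_mayer_zero_amplitude_is_zero():
    params = make_params(a_o=0.0, a_h=0.0)
    cfg = dimer_from_spherical("Cl", 3.0, 90.0, 0.0)
    assert born_mayer_energy(params, cfg) == 0.0


def test_born_mayer_single_pair_closed_form():
    # ion straight above O (theta=0): R_ion-O = 2.0; silence the H pairs
    params = make_params(a_o=1000.0, b_o=3.0, a_h=0.0)
    cfg = dimer_from_spherical("Cl", 2.0, 0.0, 0.0)
    assert born_mayer_energy(params, cfg) == pytest.approx(1000.0 * math.exp(-6.0), rel=1e-12)


def test_born_mayer_doubling_r_multiplies_by_exp_factor():
    params = make_params(a_o=1000.0, b_o=3.0, a_h=0.0)
    e2 = born_mayer_energy(params, dimer_from_spherical("Cl", 2.0, 0.0, 0.0))
    e4 = born_mayer_energy(params, dimer_from_spherical("Cl", 4.0, 0.0, 0.0))
    assert e4 / e2 == pytest.approx(math.exp(-6.0), rel=1e-12)


# ---------------------------------------------------------------------------
# Dispersion


def test_dispersion_zero_c6_is_zero():
    params = make_params(c6_o=0.0, c6_h=0.0)
    cfg = dimer_from_spherical("Cl", 3.0, 90.0, 0.0)
    assert dispersion_energy(params, cfg) == 0.0


def test_dispersion_undamped_limit_single_pair():
    params = make_params(c6_o=100.0, b_o=3.0, c6_h=0.0)
    cfg = dimer_from_spherical("Cl", 10.0, 0.0, 0.0)
    assert dispersion_energy(params, cfg) == pytest.approx(-100.0 / 10.0**6, rel=1e-6)


def test_dispersion_ratio_approaches_undamped_tail():
    params = make_params(c6_o=100.0, b_o=3.0, c6_h=0.0)
    ratios = []
    for r in (5.0, 10.0, 20.0):
        e = dispersion_energy(params, dimer_from_spherical("Cl", r, 0.0, 0.0))
        ratios.append(e / (-100.0 / r**6))
    assert ratios[0] < ratios[1] < ratios[2] <= 1.0 + 1e-12
    assert ratios[2] == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Permanent electrostatics (site-system level for full charge control)


def _two_charge_system(q1, q2, r, w1=0.0, w2=0.0):
    return SiteSystem(
        positions=np.array([[0.0, 0, 0], [r, 0, 0]]),
        charges=np.array([q1, q2], dtype=float),
        charge_widths=np.array([w1, w2], dtype=float),
        alphas=np.zeros(2),
        dipole_widths=np.zeros(2),
        groups=np.array([0, 1]),
        k=K,
    )


def test_point_charge_pair_coulomb_closed_form():
    sys_ = _two_charge_system(1.0, -1.0, 10.0)
    assert sys_.electrostatic_energy() == pytest.approx(-K / 10.0, rel=1e-12)
    assert -K / 10.0 == pytest.approx(-33.20637157, abs=1e-6)


def test_smeared_pair_converges_to_point_limit():
    for r in (2.0, 5.0, 10.0):
        smeared = _two_charge_system(1.0, -1.0, r, w1=1e-3, w2=1e-3)
        point = _two_charge_system(1.0, -1.0, r)
        assert smeared.electrostatic_energy() == pytest.approx(
            point.electrostatic_energy(), rel=1e-6
        )


def test_smearing_reduces_interaction_at_short_range():
    smeared = _two_charge_system(1.0, -1.0, 1.0, w1=0.5, w2=0.5)
    point = _two_charge_system(1.0, -1.0, 1.0)
    assert abs(smeared.electrostatic_energy()) < abs(point.electrostatic_energy())


def test_field_from_point_charge_magnitude_and_direction():
    sys_ = SiteSystem(
        positions=np.array([[0.0, 0, 0], [3.0, 0, 0]]),
        charges=np.array([0.0, -1.0]),
        charge_widths=np.zeros(2),
        alphas=np.array([1.0, 0.0]),
        dipole_widths=np.zeros(2),
        groups=np.array([0, 1]),
        k=K,
    )
    field = K * sys_.permanent_fields()  # kcal/(mol e A)
    assert np.linalg.norm(field[0]) == pytest.approx(K / 9.0, rel=1e-12)
    assert field[0][0] > 0  # negative charge at +x pulls the probe toward +x


def test_zero_charges_give_zero_energy_and_fields():
    sys_ = _two_charge_system(0.0, 0.0, 3.0)
    sys_.alphas = np.array([1.0, 1.0])
    assert sys_.electrostatic_energy() == 0.0
    np.testing.assert_array_equal(sys_.permanent_fields(), np.zeros((2, 3)))


def test_coincident_interacting_sites_rejected():
    sys_ = _two_charge_system(1.0, -1.0, 0.0)
    with pytest.raises(DegenerateGeometryError):
        sys_.electrostatic_energy()


def test_no_intramonomer_electrostatics(params_cl):
    # a single water has charged sites but no intermonomer partner
    energy, fields = permanent_electrostatics(params_cl, rigid_water_monomer())
    assert energy == 0.0
    np.testing.assert_array_equal(fields, np.zeros_like(fields))


# ---------------------------------------------------------------------------
# Induced dipoles


def _pol_system(positions, charges, alphas, groups, widths=None):
    n = len(charges)
    return SiteSystem(
        positions=np.asarray(positions, dtype=float),
        charges=np.asarray(charges, dtype=float),
        charge_widths=np.zeros(n),
        alphas=np.asarray(alphas, dtype=float),
        dipole_widths=np.zeros(n) if widths is None else np.asarray(widths, float),
        groups=np.asarray(groups),
        k=K,
    )


def test_zero_field_gives_zero_dipoles():
    sys_ = _pol_system([[0, 0, 0], [3, 0, 0]], [0, 0], [1.0, 1.0], [0, 1])
    state = _solve_system_dipoles(sys_, sys_.permanent_fields())
    np.testing.assert_array_equal(state.dipoles, 0.0)
    assert state.converged


def test_single_site_dipole_is_alpha_times_field():
    sys_ = _pol_system([[0, 0, 0], [3, 0, 0]], [0, -1.0], [1.0, 0.0], [0, 1])
    f = sys_.permanent_fields()
    state = _solve_system_dipoles(sys_, f)
    np.testing.assert_allclose(state.dipoles, 1.0 * f, atol=1e-12)


def test_two_site_axial_system_matches_independent_linear_solve():
    # two polarizable sites on the x-axis, one source charge beyond them
    pos = np.array([[0.0, 0, 0], [2.0, 0, 0], [5.0, 0, 0]])
    alphas = np.array([1.2, 0.8, 0.0])
    sys_ = _pol_system(pos, [0, 0, -1.0], alphas, [0, 1, 2])
    state = _solve_system_dipoles(sys_, sys_.permanent_fields(), method="direct")

    # independent 6x6 assembly: mu = alpha (E0 + T mu), point-dipole tensors
    def t_tensor(ri, rj):
        d = ri - rj
        r = np.linalg.norm(d)
        rh = d / r
        return (3 * np.outer(rh, rh) - np.eye(3)) / r**3

    e0 = np.zeros(6)
    for i, p in enumerate(pos[:2]):
        d = p - pos[2]
        r = np.linalg.norm(d)
        e0[3 * i : 3 * i + 3] = (-1.0) * d / r**3
    big_t = np.zeros((6, 6))
    big_t[0:3, 3:6] = t_tensor(pos[0], pos[1])
    big_t[3:6, 0:3] = big_t[0:3, 3:6]
    a_mat = np.kron(np.diag(1.0 / alphas[:2]), np.eye(3)) - big_t
    mu_oracle = np.linalg.solve(a_mat, e0).reshape(2, 3)
    np.testing.assert_allclose(state.dipoles, mu_oracle, atol=1e-10)


@pytest.mark.parametrize("trial", range(20))
def test_iterative_and_direct_solutions_agree(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(2, 11))
    # well-separated sites avoid the polarization catastrophe by construction
    pos = rng.uniform(0, 8, (n, 3))
    while np.min(
        np.linalg.norm(pos[:, None] - pos[None, :], axis=-1) + 10 * np.eye(n)
    ) < 2.0:
        pos = rng.uniform(0, 8, (n, 3))
    charges = rng.uniform(-1, 1, n)
    alphas = rng.uniform(0.2, 1.5, n)
    widths = rng.uniform(0.1, 0.5, n)
    sys_ = _pol_system(pos, charges, alphas, np.arange(n), widths=widths)
    f = sys_.permanent_fields()
    it = _solve_system_dipoles(sys_, f, method="iterative")
    di = _solve_system_dipoles(sys_, f, method="direct")
    assert np.max(np.abs(it.dipoles - di.dipoles)) <= 1e-8
    u = induction_energy(
        InducedDipoleState(it.dipoles, it.residual, it.iterations, True), K * f
    )
    assert u <= 0.0


def test_induction_energy_single_site_closed_form():
    sys_ = _pol_system([[0, 0, 0], [3.0, 0, 0]], [0, -1.0], [1.0, 0.0], [0, 1])
    f = sys_.permanent_fields()
    state = _solve_system_dipoles(sys_, f)
    u = induction_energy(state, K * f)
    assert u == pytest.approx(-0.5 * K / 81.0, rel=1e-10)
    assert u == pytest.approx(-2.0498, abs=2e-4)


def test_induction_energy_linear_in_alpha():
    def u_of_alpha(alpha):
        sys_ = _pol_system([[0, 0, 0], [3.0, 0, 0]], [0, -1.0], [alpha, 0.0], [0, 1])
        f = sys_.permanent_fields()
        return induction_energy(_solve_system_dipoles(sys_, f), K * f)

    assert u_of_alpha(2.0) == pytest.approx(2.0 * u_of_alpha(1.0), rel=1e-12)


def test_unconverged_state_refused():
    state = InducedDipoleState(np.zeros((1, 3)), residual=1.0, iterations=200, converged=False)
    with pytest.raises(SolverError):
        induction_energy(state, np.zeros((1, 3)))


def test_polarization_catastrophe_detected():
    # two undamped polarizable sites far too close: alpha/r^3 > 1/2
    sys_ = _pol_system([[0, 0, 0], [0.8, 0, 0], [4, 0, 0]], [0, 0, -1.0],
                       [1.0, 1.0, 0.0], [0, 1, 2])
    with pytest.raises((ModelError, SolverError)):
        _solve_system_dipoles(sys_, sys_.permanent_fields(), method="direct")


def test_params_level_solver_roundtrip(params_cl, dimer):
    energy, fields = permanent_electrostatics(params_cl, dimer)
    state = solve_induced_dipoles(params_cl, dimer, permanent_fields=fields)
    assert state.converged
    u = induction_energy(state, fields)
    assert u < 0.0


# ---------------------------------------------------------------------------
# Assembled ion-water energy


def test_breakdown_total_is_sum_of_components(params_cl, dimer):
    bd = ion_water_energy(params_cl, dimer)
    assert bd.total == pytest.approx(bd.rep + bd.disp + bd.elec + bd.ind, abs=1e-10)
    rep = born_mayer_energy(params_cl, dimer)
    disp = dispersion_energy(params_cl, dimer)
    elec, fields = permanent_electrostatics(params_cl, dimer)
    state = solve_induced_dipoles(params_cl, dimer, permanent_fields=fields)
    ind = induction_energy(state, fields)
    assert bd.rep == pytest.approx(rep, abs=1e-12)
    assert bd.disp == pytest.approx(disp, abs=1e-12)
    assert bd.elec == pytest.approx(elec, abs=1e-10)
    assert bd.ind == pytest.approx(ind, abs=1e-8)


def test_energy_invariant_under_rigid_motion(params_cl, dimer):
    e0 = ion_water_energy(params_cl, dimer).total
    rot = Rotation.from_euler("zyx", [1.1, -0.7, 0.3]).as_matrix()
    moved = dimer.transformed(rotation=rot, translation=[10.0, -2.0, 4.0])
    assert ion_water_energy(params_cl, moved).total == pytest.approx(e0, abs=1e-9)


def test_energy_invariant_under_monomer_relabeling(params_cl):
    base = water_cluster(2, seed=11)
    atoms = [Atom(a.element, a.position.copy()) for a in base.atoms]
    atoms.append(Atom("Cl", [6.0, 1.0, 1.0]))
    cfg = ClusterConfiguration(atoms, ion_index=6)
    swapped_atoms = atoms[3:6] + atoms[0:3] + [atoms[6]]
    cfg_swapped = ClusterConfiguration(
        [Atom(a.element, a.position.copy()) for a in swapped_atoms], ion_index=6
    )
    e1 = ion_water_energy(params_cl, cfg).total
    e2 = ion_water_energy(params_cl, cfg_swapped).total
    assert e2 == pytest.approx(e1, abs=1e-9)


def test_far_ion_interaction_vanishes(params_cl):
    # perpendicular placement suppresses the leading ion-dipole tail
    cfg = dimer_from_spherical("Cl", 500.0, 90.0, 90.0)
    assert abs(ion_water_energy(params_cl, cfg).total) < 1e-5
    near = abs(ion_water_energy(params_cl, dimer_from_spherical("Cl", 3.0, 90.0, 90.0)).total)
    assert abs(ion_water_energy(params_cl, cfg).total) < 1e-6 * near


# ---------------------------------------------------------------------------
# Total and interaction energies


def test_total_energy_without_ion_reduces_to_water_model(params_cl):
    cfg = water_cluster(2, seed=3)
    wm = get_water_model(params_cl)
    total = total_energy(params_cl, wm, cfg)
    e_intra, e_inter = wm.energies(cfg)
    # remaining piece is the water-only induction, which must be <= 0
    ind = total - e_intra - e_inter
    assert ind <= 1e-12
    assert total == pytest.approx(e_intra + e_inter + ind, abs=1e-10)


def test_total_energy_dimer_is_monomer_plus_ion_water(params_cl, dimer):
    wm = get_water_model(params_cl)
    total = total_energy(params_cl, wm, dimer)
    iw = ion_water_energy(params_cl, dimer, wm).total
    e_intra, e_inter = wm.energies(dimer.without_ion())
    assert e_inter == 0.0  # single monomer
    assert total == pytest.approx(iw + e_intra, abs=1e-10)


def _supermolecular_nonadditivity(params):
    """E(ion+2w) - sum of pair energies + sum of monomer energies."""
    wm = get_water_model(params)
    w2 = water_cluster(2, seed=13)
    atoms = [Atom(a.element, a.position.copy()) for a in w2.atoms]
    atoms.append(Atom("Cl", [5.5, 2.0, 0.5]))
    full = ClusterConfiguration(atoms, ion_index=6)

    def sub(indices, ion=False):
        sel = [Atom(atoms[i].element, atoms[i].position.copy()) for i in indices]
        if ion:
            sel.append(Atom("Cl", atoms[6].position.copy()))
        return ClusterConfiguration(sel, ion_index=len(sel) - 1 if ion else None)

    e_full = total_energy(params, wm, full)
    e_pairs = (
        total_energy(params, wm, sub(range(0, 3), ion=True))
        + total_energy(params, wm, sub(range(3, 6), ion=True))
        + total_energy(params, wm, sub(range(0, 6)))
    )
    e_monos = (
        total_energy(params, wm, sub(range(0, 3)))
        + total_energy(params, wm, sub(range(3, 6)))
        + 0.0  # isolated classical ion
    )
    return e_full - e_pairs + e_monos


def test_three_body_nonadditivity_from_polarization():
    polarizable = make_params()
    assert abs(_supermolecular_nonadditivity(polarizable)) > 1e-4
    additive = make_params(alpha_o=0.0, alpha_h=0.0, alpha_ion=0.0)
    assert _supermolecular_nonadditivity(additive) == pytest.approx(0.0, abs=1e-9)


def test_interaction_energy_equals_ion_water_total(params_cl, dimer):
    wm = get_water_model(params_cl)
    de = interaction_energy(params_cl, wm, dimer)
    assert de == pytest.approx(ion_water_energy(params_cl, dimer, wm).total, abs=1e-9)


def test_interaction_energy_reduces_to_born_mayer_when_only_repulsion():
    params = make_params(q_h=0.0, c6_o=0.0, c6_h=0.0,
                         alpha_o=0.0, alpha_h=0.0, alpha_ion=0.0)
    cfg = dimer_from_spherical("Cl", 2.8, 45.0, 0.0)
    wm = get_water_model(params)
    assert interaction_energy(params, wm, cfg) == pytest.approx(
        born_mayer_energy(params, cfg), abs=1e-10
    )


def test_interaction_energy_pure_coulomb_matches_hand_sum():
    params = make_params(a_o=0.0, a_h=0.0, c6_o=0.0, c6_h=0.0, width=0.0,
                         ion_width=0.0, alpha_o=0.0, alpha_h=0.0, alpha_ion=0.0)
    cfg = dimer_from_spherical("Cl", 3.2, 135.0, 0.0)
    wm = get_water_model(params)
    de = interaction_energy(params, wm, cfg)
    # independent Coulomb arithmetic over the four water sites
    o, h1, h2 = (cfg.atoms[i].position for i in range(3))
    bis = 0.5 * (h1 + h2) - o
    m = o + params.m_site_offset * bis / np.linalg.norm(bis)
    ion = cfg.ion.position
    q_h = 0.574
    oracle = sum(
        K * q * (-1.0) / np.linalg.norm(site - ion)
        for q, site in [(q_h, h1), (q_h, h2), (-2 * q_h, m), (0.0, o)]
    )
    assert de == pytest.approx(oracle, abs=1e-10)
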