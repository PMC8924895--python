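"""Fitting engine: chi^2, SVD linear solves, simplex, active learning."""

import dataclasses

import numpy as np
import pytest

from ionwater.dataset import (
    GridSpec,
    TrainingPoint,
    TrainingSet,
    assign_energy_weights,
    build_spherical_grid,
    dimer_from_spherical,
    make_synthetic_reference,
)
from ionwater.errors import ConfigurationError, DomainError, FitError
from ionwater.fitting import (
    FitConfig,
    active_learning_fit,
    chi_squared,
    fit_linear_terms,
    simplex_fit,
    two_stage_fit,
    weighted_svd_lstsq,
)
from ionwater.parameters import PairShortRange, toy_parameters
from ionwater.potential import ion_water_energy

from conftest import make_params


SMALL_GRID = GridSpec(n_r=8, n_theta=6, n_phi=3)  # 144 points, fast


@pytest.fixture(scope="module")
def truth():
    return toy_parameters("Cl")


@pytest.fixture(scope="module")
def noiseless_set(truth):
    grid = build_spherical_grid(SMALL_GRID, "Cl")
    ts = make_synthetic_reference(truth, grid, noise_sd=0.0, seed=3)
    assign_energy_weights(ts)
    return ts


def perturbed_init(truth):
    return truth.with_pair_terms(
        PairShortRange(a=3.5e4, beta=2.9, c6=2400.0),
        PairShortRange(a=5.5e3, beta=2.6, c6=600.0),
    )


# ---------------------------------------------------------------------------
# chi^2


def test_chi_squared_zero_for_generating_parameters(truth, noiseless_set):
    assert chi_squared(truth, noiseless_set) == 0.0


def test_chi_squared_single_point_arithmetic(truth):
    cfg = dimer_from_spherical("Cl", 3.5, 90.0, 0.0)
    e_model = ion_water_energy(truth, cfg).total
    point = TrainingPoint(config=cfg, r=3.5, theta=90.0, phi=0.0,
                          e_ref=e_model - 3.0, weight=2.0)
    ts = TrainingSet(points=[point], ion="Cl")
    assert chi_squared(truth, ts) == pytest.approx(18.0, rel=1e-12)


def test_chi_squared_matches_loop_summation_oracle(truth, noiseless_set):
    rng = np.random.default_rng(8)
    ts = noiseless_set.subset(rng.choice(len(noiseless_set), 100, replace=False))
    for p in ts.points:  # perturb so residuals are non-trivial
        p.e_ref += rng.normal(0, 0.5)
    total = 0.0
    for p in ts.points:
        resid = ion_water_energy(truth, p.config).total - p.e_ref
        total += p.weight * resid * resid
    assert chi_squared(truth, ts) == pytest.approx(total, rel=1e-12)


def test_chi_squared_unset_weights_is_configuration_error(truth):
    cfg = dimer_from_spherical("Cl", 3.5, 90.0, 0.0)
    ts = TrainingSet(points=[TrainingPoint(config=cfg, r=3.5, theta=90.0, phi=0.0,
                                           e_ref=-1.0)], ion="Cl")
    with pytest.raises(ConfigurationError):
        chi_squared(truth, ts)


def test_chi_squared_invariant_to_point_order_and_linear_in_weights(truth, noiseless_set):
    rng = np.random.default_rng(12)
    ts = noiseless_set.subset(rng.permutation(len(noiseless_set)))
    for p in ts.points:
        p.e_ref += 0.3
    chi_fwd = chi_squared(truth, ts)
    ts_rev = ts.subset(np.arange(len(ts))[::-1])
    assert chi_squared(truth, ts_rev) == pytest.approx(chi_fwd, rel=1e-12)
    ts.set_weights(5.0 * ts.weights)
    assert chi_squared(truth, ts) == pytest.approx(5.0 * chi_fwd, rel=1e-12)


# ---------------------------------------------------------------------------
# Linear solves


def test_weighted_svd_recovers_exact_linear_combination():
    rng = np.random.default_rng(0)
    basis = rng.normal(size=(60, 4))
    coeffs = np.array([2.0, -1.5, 0.3, 4.0])
    y = basis @ coeffs
    w = rng.uniform(0.5, 2.0, 60)
    got = weighted_svd_lstsq(basis, y, w)
    np.testing.assert_allclose(got, coeffs, atol=1e-8)


def test_weighted_svd_agrees_with_normal_equations_oracle():
    rng = np.random.default_rng(1)
    basis = rng.normal(size=(80, 5))
    y = rng.normal(size=80)
    w = rng.uniform(0.1, 3.0, 80)
    got = weighted_svd_lstsq(basis, y, w)
    bw = basis * w[:, None]
    oracle = np.linalg.solve(basis.T @ bw, bw.T @ y / 1.0)  # (B^T W B) c = B^T W y
    np.testing.assert_allclose(got, oracle, atol=1e-8)


def test_duplicated_basis_column_gives_minimum_norm_solution():
    rng = np.random.default_rng(2)
    col = rng.normal(size=50)
    basis = np.column_stack([col, col])
    y = 3.0 * col
    got = weighted_svd_lstsq(basis, y, np.ones(50))
    # minimum-norm split: both coefficients equal
    np.testing.assert_allclose(got, [1.5, 1.5], atol=1e-8)


def test_rank_deficient_design_rejected():
    basis = np.zeros((10, 2))
    with pytest.raises(FitError):
        weighted_svd_lstsq(basis, np.ones(10), np.ones(10))


def test_fit_linear_terms_on_training_set(noiseless_set):
    # fabricate a linear target over two columns of point coordinates
    r = np.array([p.r for p in noiseless_set.points])
    basis = np.column_stack([np.exp(-r), 1.0 / r**6])
    ts = noiseless_set.subset(np.arange(len(noiseless_set)))
    target = basis @ np.array([100.0, -3000.0])
    for p, t in zip(ts.points, target):
        p.e_ref = float(t)
    got = fit_linear_terms(ts, basis)
    np.testing.assert_allclose(got, [100.0, -3000.0], rtol=1e-8)


# ---------------------------------------------------------------------------
# Simplex


def test_simplex_minimizes_quadratic_bowl():
    objective = lambda x: (x[0] - 1.0) ** 2 + 3.0 * (x[1] + 2.0) ** 2  # noqa: E731
    x, f = simplex_fit(objective, np.array([4.0, 4.0]), FitConfig(max_simplex_steps=800))
    np.testing.assert_allclose(x, [1.0, -2.0], atol=1e-6)
    assert f < 1e-10


def test_simplex_never_ascends_from_the_optimum():
    objective = lambda x: (x[0] - 1.0) ** 2  # noqa: E731
    x, f = simplex_fit(objective, np.array([1.0]), FitConfig(max_simplex_steps=50))
    assert f <= objective(np.array([1.0]))


def test_simplex_non_finite_objective_raises():
    def objective(x):
        return np.inf if x[0] > 2.0 else float(x[0] ** 2)

    with pytest.raises(FitError):
        simplex_fit(objective, np.array([3.0]), FitConfig())


def test_exponent_recovery_from_noiseless_data(truth, noiseless_set):
    # C6 frozen at truth; simplex must recover both Born-Mayer exponents
    init = truth.with_pair_terms(
        dataclasses.replace(truth.pair_o, a=4e4, beta=3.0),
        dataclasses.replace(truth.pair_h, a=6e3, beta=2.7),
    )
    cfg = FitConfig(max_al_iterations=1, max_simplex_steps=800,
                    mean_error_tol=1e-9, pointwise_error_tol=1e-9)
    res = active_learning_fit(noiseless_set, init, cfg, fit_c6=False)
    assert res.params.pair_o.beta == pytest.approx(truth.pair_o.beta, abs=1e-3)
    assert res.params.pair_h.beta == pytest.approx(truth.pair_h.beta, abs=1e-3)


# ---------------------------------------------------------------------------
# Active learning


def test_converged_input_returns_after_first_iteration(truth, noiseless_set):
    res = active_learning_fit(noiseless_set, truth, FitConfig(), fit_c6=False)
    assert res.converged
    assert res.iterations == 1
    assert len(res.weight_history) == 1
    np.testing.assert_array_equal(res.weight_history[0], noiseless_set.weights)


def _wall_fixture(truth, mismatch_amp=3.0):
    """Dense attractive sampling, sparse repulsive wall, model mismatch."""
    coords = [(float(r), th) for r in np.linspace(3.0, 8.0, 18)
              for th in (0.0, 60.0, 120.0, 180.0)]
    coords += [(2.2, 180.0), (2.5, 180.0), (2.8, 180.0)]
    points = []
    for r, th in coords:
        cfg = dimer_from_spherical("Cl", r, th, 0.0)
        e = ion_water_energy(truth, cfg).total
        e += mismatch_amp * np.exp(-1.5 * (r - 2.0))  # outside the model class
        points.append(TrainingPoint(config=cfg, r=r, theta=th, phi=0.0, e_ref=e))
    ts = TrainingSet(points=points, d_e=2.0, ion="Cl")
    assign_energy_weights(ts)
    return ts


def test_boost_schedule_is_the_stated_geometric_sequence(truth):
    ts = _wall_fixture(truth)
    cfg = FitConfig(max_al_iterations=4, max_simplex_steps=200,
                    mean_error_tol=1e-10, pointwise_error_tol=1e-10,
                    weight_boost_initial=1.0, weight_boost_decay=0.7)
    res = active_learning_fit(ts, perturbed_init(truth), cfg, fit_c6=False)
    assert res.iterations >= 2
    for t in range(res.iterations - 1):
        w_before = res.weight_history[t]
        w_after = res.weight_history[t + 1]
        ratios = w_after / w_before
        # two ratio levels: unboosted (c) and boosted (c * (1 + g0 * d^t))
        levels = np.unique(np.round(ratios, 9))
        assert len(levels) <= 2
        if len(levels) == 2:
            assert levels[1] / levels[0] == pytest.approx(1.0 + 1.0 * 0.7**t, rel=1e-6)


def test_active_learning_beats_single_pass_on_undersampled_wall(truth):
    budget_iters, budget_steps = 8, 300
    ts_al = _wall_fixture(truth)
    res_al = active_learning_fit(
        ts_al,
        perturbed_init(truth),
        FitConfig(max_al_iterations=budget_iters, max_simplex_steps=budget_steps,
                  mean_error_tol=1e-8, pointwise_error_tol=1e-8),
        fit_c6=False,
    )
    ts_sp = _wall_fixture(truth)
    res_sp = active_learning_fit(
        ts_sp,
        perturbed_init(truth),
        # same total simplex budget, threshold > 1 so no boost ever fires
        FitConfig(max_al_iterations=budget_iters,
                  max_simplex_steps=budget_iters * budget_steps,
                  mean_error_tol=1e-8, pointwise_error_tol=1e-8,
                  error_fraction_threshold=1.5),
        fit_c6=False,
    )
    assert (res_sp.diagnostics.n_boosted == 0).all()
    assert res_al.max_error < res_sp.max_error


def test_threshold_above_one_degenerates_to_single_weighted_fit(truth):
    ts = _wall_fixture(truth)
    cfg = FitConfig(max_al_iterations=5, max_simplex_steps=300,
                    mean_error_tol=1e-8, pointwise_error_tol=1e-8,
                    error_fraction_threshold=1.1)
    res = active_learning_fit(ts, perturbed_init(truth), cfg, fit_c6=False)
    assert (res.diagnostics.n_boosted == 0).all()


def test_rms_error_non_increasing_over_accepted_iterations(truth):
    ts = _wall_fixture(truth)
    cfg = FitConfig(max_al_iterations=8, max_simplex_steps=300,
                    mean_error_tol=1e-8, pointwise_error_tol=1e-8)
    res = active_learning_fit(ts, perturbed_init(truth), cfg, fit_c6=False)
    rms = res.diagnostics.rms.values
    assert np.all(np.diff(rms) <= 1e-12)


# ---------------------------------------------------------------------------
# Two-stage pipeline


def test_two_stage_recovers_parameters_and_freezes_c6(truth):
    grid = build_spherical_grid(GridSpec(), "Cl")  # the ~500-point default
    ts = make_synthetic_reference(truth, grid, noise_sd=0.0, seed=1)
    assign_energy_weights(ts)
    ts_lr = ts.subset(np.array([p.r >= 6.0 for p in ts.points]))
    cfg = FitConfig(max_al_iterations=3, max_simplex_steps=600,
                    mean_error_tol=1e-7, pointwise_error_tol=1e-7)
    res = two_stage_fit(ts_lr, ts, perturbed_init(truth), cfg, n_cycles=8)
    for got, want in (
        (res.params.pair_o.a, truth.pair_o.a),
        (res.params.pair_o.beta, truth.pair_o.beta),
        (res.params.pair_o.c6, truth.pair_o.c6),
        (res.params.pair_h.a, truth.pair_h.a),
        (res.params.pair_h.beta, truth.pair_h.beta),
        (res.params.pair_h.c6, truth.pair_h.c6),
    ):
        assert got == pytest.approx(want, rel=0.01)
    assert chi_squared(res.params, ts) < 1e-6


def test_stage_two_never_alters_c6(truth, noiseless_set):
    init = perturbed_init(truth)
    res = active_learning_fit(noiseless_set, init, FitConfig(max_al_iterations=2,
                                                             max_simplex_steps=150),
                              fit_c6=False)
    assert res.params.pair_o.c6 == init.pair_o.c6  # bitwise
    assert res.params.pair_h.c6 == init.pair_h.c6


def test_two_stage_empty_long_range_set_rejected(truth, noiseless_set):
    empty = noiseless_set.subset(np.array([], dtype=int))
    with pytest.raises(ConfigurationError):
        two_stage_fit(empty, noiseless_set, truth, FitConfig())


def test_fit_config_validation():
    with pytest.raises(DomainError):
        FitConfig(mean_error_tol=-1.0)
    with pytest.raises(DomainError):
        FitConfig(weight_boost_decay=1.5)
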