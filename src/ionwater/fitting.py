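"""Two-stage parameterization with active-learning reweighting.

The short-range parameters are separable: for fixed Born-Mayer exponents
(beta_ion-O, beta_ion-H) the model energy is linear in (A_ion-O, A_ion-H,
C6_ion-O, C6_ion-H), because the electrostatic and induction terms carry no
fitted parameters. Each objective evaluation therefore solves the linear
subproblem by weighted SVD least squares and the simplex (Nelder-Mead)
search runs only over the exponents. Under the delta=beta rule the
dispersion damping follows the exponents automatically.

The weighted figure of merit is

    chi^2 = sum_N w_N * (V_model(N) - E_ref(N))^2

The active-learning loop repeats {minimize chi^2; measure per-point |error|;
boost the weights of points whose error exceeds a fraction of the maximum
error} with a boost factor (1 + gamma0 * decay^t) that shrinks over the
iterations, then renormalizes weights to mean 1. It stops on a mean-error or
max-error tolerance, on the iteration cap, or when an iterate no longer
improves the RMS error (the iterate is then rejected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammainc

from .dataset import TrainingSet
from .errors import ConfigurationError, DomainError, FitError
from .parameters import IonWaterParameters, PairShortRange
from .potential import ion_water_energy

__all__ = [
    "FitConfig",
    "FitResult",
    "DimerDesign",
    "chi_squared",
    "weighted_svd_lstsq",
    "fit_linear_terms",
    "simplex_fit",
    "active_learning_fit",
    "two_stage_fit",
]


@dataclass
class FitConfig:
    """Knobs of the fitting engine. All tolerances in kcal/mol."""

    max_al_iterations: int = 30
    max_simplex_steps: int = 400
    mean_error_tol: float = 0.05
    pointwise_error_tol: float = 0.5
    error_fraction_threshold: float = 0.5  # boost points with |err| > frac * max|err|
    weight_boost_initial: float = 1.0  # gamma0
    weight_boost_decay: float = 0.7  # d; boost_t = 1 + gamma0 * d**t
    seed: int = 0
    svd_rcond: float = 1e-10

    def __post_init__(self) -> None:
        for name in ("mean_error_tol", "pointwise_error_tol"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.error_fraction_threshold <= 0:
            raise DomainError("error_fraction_threshold must be > 0")
        if self.weight_boost_initial <= 0:
            raise DomainError("weight_boost_initial must be > 0")
        if not (0 < self.weight_boost_decay <= 1):
            raise DomainError("weight_boost_decay must be in (0, 1]")


@dataclass
class FitResult:
    """Outcome of a fit: parameters, figures of merit, iteration history."""

    params: IonWaterParameters
    chi2: float
    rms_error: float
    max_error: float
    weight_history: list = field(default_factory=list)
    converged: bool = False
    criterion_met: str = ""
    iterations: int = 0
    diagnostics: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Design cache


class DimerDesign:
    """Precomputed per-point geometry and parameter-free energy baseline.

    For each training dimer: the ion-O distance, both ion-H distances, and
    the electrostatic + induction energy (fixed during short-range fitting
    because charges, widths and polarizabilities are inputs, not fit
    targets). Short-range model energies then evaluate vectorized.
    """

    def __init__(self, params: IonWaterParameters, training_set: TrainingSet):
        self.params = params
        n = len(training_set)
        self.r_o = np.empty(n)
        self.r_h = np.empty((n, 2))
        self.e_base = np.empty(n)
        for i, p in enumerate(training_set.points):
            cfg = p.config
            ion = cfg.ion.position
            pos = cfg.positions
            o_idx = [j for j, a in enumerate(cfg.atoms) if a.element == "O"]
            h_idx = [j for j, a in enumerate(cfg.atoms) if a.element == "H"]
            if len(o_idx) != 1 or len(h_idx) != 2:
                raise ConfigurationError("DimerDesign requires one-water dimer configurations")
            self.r_o[i] = np.linalg.norm(pos[o_idx[0]] - ion)
            self.r_h[i] = [np.linalg.norm(pos[j] - ion) for j in h_idx]
            bd = ion_water_energy(params, cfg)
            self.e_base[i] = bd.elec + bd.ind

    # -- vectorized model -------------------------------------------------
    @staticmethod
    def _f6(delta: float, r: np.ndarray) -> np.ndarray:
        return gammainc(7, delta * r)

    def basis_columns(self, beta_o: float, beta_h: float, include_c6: bool = True) -> np.ndarray:
        """Columns linear in (A_O, A_H[, C6_O, C6_H]) at fixed exponents."""
        cols = [
            np.exp(-beta_o * self.r_o),
            np.exp(-beta_h * self.r_h).sum(axis=1),
        ]
        if include_c6:
            cols.append(-self._f6(beta_o, self.r_o) / self.r_o**6)
            cols.append(-(self._f6(beta_h, self.r_h) / self.r_h**6).sum(axis=1))
        return np.column_stack(cols)

    def model_energies(self, pair_o: PairShortRange, pair_h: PairShortRange) -> np.ndarray:
        rep = pair_o.a * np.exp(-pair_o.beta * self.r_o) + pair_h.a * np.exp(
            -pair_h.beta * self.r_h
        ).sum(axis=1)
        disp = -pair_o.c6 * self._f6(pair_o.effective_delta, self.r_o) / self.r_o**6
        disp -= pair_h.c6 * (self._f6(pair_h.effective_delta, self.r_h) / self.r_h**6).sum(axis=1)
        return self.e_base + rep + disp


# ---------------------------------------------------------------------------
# chi^2 and linear algebra


def chi_squared(params: IonWaterParameters, training_set: TrainingSet) -> float:
    """Weighted sum of squared residuals sum_N w_N (V(N) - E_ref(N))^2.

    Direct evaluation through the full energy kernel (no design cache).
    """
    w = training_set.weights  # raises on unset weights
    e_ref = training_set.e_ref
    v = np.array([ion_water_energy(params, p.config).total for p in training_set.points])
    return float(np.sum(w * (v - e_ref) ** 2))


def weighted_svd_lstsq(
    basis: np.ndarray, y: np.ndarray, weights: np.ndarray, rcond: float = 1e-10
) -> np.ndarray:
    """Weighted least squares via SVD with relative singular-value truncation.

    Solves min_c || W^(1/2) (B c - y) ||^2; singular values below
    ``rcond * s_max`` are truncated (minimum-norm solution on the retained
    subspace). Raises :class:`FitError` if fewer than one singular value
    survives.
    """
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2:
        raise FitError("basis must be a 2-D matrix")
    if basis.shape[0] < basis.shape[1]:
        raise FitError(
            f"need at least {basis.shape[1]} points for {basis.shape[1]} coefficients, "
            f"got {basis.shape[0]}"
        )
    sw = np.sqrt(np.asarray(weights, dtype=float))
    u, s, vt = np.linalg.svd(sw[:, None] * basis, full_matrices=False)
    keep = s > rcond * s[0] if s[0] > 0 else np.zeros_like(s, dtype=bool)
    if not np.any(keep):
        raise FitError("rank-deficient design: no singular value above the cutoff")
    inv = np.zeros_like(s)
    inv[keep] = 1.0 / s[keep]
    return vt.T @ (inv * (u.T @ (sw * y)))


def fit_linear_terms(
    training_set: TrainingSet, basis: np.ndarray, rcond: float = 1e-10
) -> np.ndarray:
    """Weighted SVD solution of the linear-in-parameter energy terms.

    ``basis`` has one column per linear coefficient evaluated at each
    training point; the target is ``e_ref`` minus nothing (callers subtract
    any fixed baseline from e_ref themselves, or pass residual targets).
    """
    return weighted_svd_lstsq(basis, training_set.e_ref, training_set.weights, rcond)


# ---------------------------------------------------------------------------
# Simplex


def simplex_fit(objective, init: np.ndarray, config: FitConfig) -> tuple[np.ndarray, float]:
    """Nelder-Mead descent from ``init``; never returns an ascent.

    Restarts once from the best vertex when the search stagnates before the
    step budget is exhausted. Non-finite objective values raise
    :class:`FitError` naming the offending parameters.
    """
    init = np.asarray(init, dtype=float)
    f0 = objective(init)
    if not np.isfinite(f0):
        raise FitError(f"objective not finite at the initial point {init}")

    def guarded(x):
        val = objective(x)
        if not np.isfinite(val):
            raise FitError(f"objective returned a non-finite value at {x}")
        return val

    opts = dict(maxiter=config.max_simplex_steps, xatol=1e-10, fatol=1e-12)
    res = minimize(guarded, init, method="Nelder-Mead", options=opts)
    used = res.nit
    best_x, best_f = res.x, float(res.fun)
    if used < config.max_simplex_steps:  # restart once from the best vertex
        opts["maxiter"] = config.max_simplex_steps - used
        res2 = minimize(guarded, best_x, method="Nelder-Mead", options=opts)
        if res2.fun < best_f:
            best_x, best_f = res2.x, float(res2.fun)
    if best_f > f0:
        return init, f0
    return np.asarray(best_x), best_f


# ---------------------------------------------------------------------------
# Inner minimization: simplex over exponents, SVD over linear coefficients


def _minimize_short_range(
    design: DimerDesign,
    e_ref: np.ndarray,
    weights: np.ndarray,
    init_params: IonWaterParameters,
    config: FitConfig,
    fit_c6: bool,
) -> IonWaterParameters:
    """One weighted-chi^2 minimization; returns updated parameters."""
    y = e_ref - design.e_base
    frozen_c6 = (init_params.pair_o.c6, init_params.pair_h.c6)

    def linear_solve(beta_o: float, beta_h: float):
        target = y
        if not fit_c6:
            target = y + frozen_c6[0] * design._f6(beta_o, design.r_o) / design.r_o**6
            target = target + frozen_c6[1] * (
                design._f6(beta_h, design.r_h) / design.r_h**6
            ).sum(axis=1)
        basis = design.basis_columns(beta_o, beta_h, include_c6=fit_c6)
        coeffs = weighted_svd_lstsq(basis, target, weights, config.svd_rcond)
        coeffs = np.clip(coeffs, 0.0, None)  # A and C6 are non-negative by contract
        resid = basis @ coeffs - target
        return coeffs, float(np.sum(weights * resid**2))

    def objective(logbeta):
        beta_o, beta_h = np.exp(logbeta)
        _, chi2 = linear_solve(beta_o, beta_h)
        return chi2

    x0 = np.log([init_params.pair_o.beta, init_params.pair_h.beta])
    x_best, _ = simplex_fit(objective, x0, config)
    beta_o, beta_h = np.exp(x_best)
    coeffs, _ = linear_solve(beta_o, beta_h)
    if fit_c6:
        a_o, a_h, c6_o, c6_h = coeffs
    else:
        (a_o, a_h), (c6_o, c6_h) = coeffs, frozen_c6
    return init_params.with_pair_terms(
        PairShortRange(a=float(a_o), beta=float(beta_o), c6=float(c6_o)),
        PairShortRange(a=float(a_h), beta=float(beta_h), c6=float(c6_h)),
    )


# ---------------------------------------------------------------------------
# Active learning


def active_learning_fit(
    training_set: TrainingSet,
    init: IonWaterParameters,
    config: FitConfig | None = None,
    fit_c6: bool = True,
) -> FitResult:
    """Error-driven iterative reweighting around the weighted fit.

    Each iteration minimizes chi^2 (simplex over exponents, SVD over linear
    terms), measures unweighted per-point errors, and — if no convergence
    criterion holds — multiplies the weights of points with
    ``|err| > error_fraction_threshold * max|err|`` by ``1 + gamma0 *
    decay^t`` before renormalizing to mean 1. RMS error must not increase
    across accepted iterations; a worsening iterate is rejected and the loop
    halts.
    """
    config = config or FitConfig()
    weights = training_set.weights.copy()  # raises ConfigurationError-ish on unset
    e_ref = training_set.e_ref
    design = DimerDesign(init, training_set)

    history_rows = []
    weight_history: list[np.ndarray] = []
    best: FitResult | None = None
    params = init
    criterion = "max_iterations"
    converged = False
    for t in range(config.max_al_iterations):
        weight_history.append(weights.copy())
        params_t = _minimize_short_range(design, e_ref, weights, params, config, fit_c6)
        v = design.model_energies(params_t.pair_o, params_t.pair_h)
        err = np.abs(v - e_ref)
        chi2 = float(np.sum(weights * (v - e_ref) ** 2))
        rms = float(np.sqrt(np.mean(err**2)))
        mx = float(err.max())
        boosted = 0
        if best is not None and rms > best.rms_error:
            criterion = "no_improvement"
            weight_history.pop()  # rejected iterate does not count
            break
        best = FitResult(
            params=params_t, chi2=chi2, rms_error=rms, max_error=mx,
            weight_history=[], converged=False, criterion_met="", iterations=t + 1,
        )
        params = params_t
        if float(err.mean()) <= config.mean_error_tol:
            criterion, converged = "mean_error", True
        elif mx <= config.pointwise_error_tol:
            criterion, converged = "pointwise_error", True
        if converged or t == config.max_al_iterations - 1:
            history_rows.append(
                dict(iteration=t, chi2=chi2, rms=rms, max_error=mx, n_boosted=0)
            )
            break
        flag = err > config.error_fraction_threshold * mx
        if flag.all():
            warnings.warn("all training points flagged for boosting; proceeding", stacklevel=2)
        boosted = int(flag.sum())
        boost = 1.0 + config.weight_boost_initial * config.weight_boost_decay**t
        weights = weights.copy()
        weights[flag] *= boost
        weights /= weights.mean()
        history_rows.append(dict(iteration=t, chi2=chi2, rms=rms, max_error=mx, n_boosted=boosted))
    if best is None:  # pragma: no cover - loop always runs once
        raise FitError("active learning made no iterations")
    best.converged = converged
    best.criterion_met = criterion
    best.weight_history = weight_history
    best.iterations = len(weight_history)
    best.diagnostics = pd.DataFrame(history_rows)
    return best


# ---------------------------------------------------------------------------
# Two-stage pipeline


def _stage1_c6(
    design_lr: DimerDesign,
    set_longrange: TrainingSet,
    config: FitConfig,
    short_range: tuple[PairShortRange, PairShortRange] | None,
) -> np.ndarray:
    """Weighted SVD estimate of (C6_ion-O, C6_ion-H) on the long-range set.

    First pass: undamped -1/R^6 columns (damping ~ 1, repulsion neglected).
    Refinement passes subtract the currently fitted Born-Mayer repulsion and
    damp the columns at the current exponents, removing the small systematic
    bias those neglected terms leave at the near edge of the long-range set.
    """
    y = set_longrange.e_ref - design_lr.e_base
    if short_range is None:
        basis = np.column_stack(
            [-1.0 / design_lr.r_o**6, -(1.0 / design_lr.r_h**6).sum(axis=1)]
        )
    else:
        po, ph = short_range
        y = y - po.a * np.exp(-po.beta * design_lr.r_o)
        y = y - ph.a * np.exp(-ph.beta * design_lr.r_h).sum(axis=1)
        basis = np.column_stack(
            [
                -design_lr._f6(po.effective_delta, design_lr.r_o) / design_lr.r_o**6,
                -(design_lr._f6(ph.effective_delta, design_lr.r_h) / design_lr.r_h**6).sum(axis=1),
            ]
        )
    c6 = weighted_svd_lstsq(basis, y, set_longrange.weights, config.svd_rcond)
    return np.clip(c6, 0.0, None)


def two_stage_fit(
    set_longrange: TrainingSet,
    set_full: TrainingSet,
    init: IonWaterParameters,
    config: FitConfig | None = None,
    n_cycles: int = 2,
    refine_cutoff: float = 4.0,
) -> FitResult:
    """Asymptotics-first parameterization.

    Stage 1 fits the dispersion coefficients (C6_ion-O, C6_ion-H) on the
    long-range set, where damping is ~1 and the exponential repulsion is
    negligible, by weighted SVD linear regression on -1/R^6 columns. Stage 2
    freezes the C6 values and runs the active-learning loop for the
    Born-Mayer (A, beta) parameters on the full set, with the dispersion
    damping tied to beta (delta = beta rule).

    With ``n_cycles > 1`` the pair of stages is iterated to self-consistency.
    Refinement passes subtract the currently fitted repulsion and damp the
    dispersion columns at the fitted exponents, which lets them use the
    mid-range points of the full set (``R >= refine_cutoff``) where the
    dispersion signal is an order of magnitude above the long-range tail —
    the two 1/R^6 columns are nearly collinear on the far tail alone, so
    noisy references cannot separate the O and H coefficients there. Stage 2
    itself never alters the C6 values it receives.
    """
    config = config or FitConfig()
    if len(set_longrange) == 0:
        raise ConfigurationError("long-range training set is empty")
    if n_cycles < 1:
        raise DomainError("n_cycles must be >= 1")
    design_lr = DimerDesign(init, set_longrange)
    refine_set = set_full.subset(np.array([p.r >= refine_cutoff for p in set_full.points]))
    design_refine = DimerDesign(init, refine_set) if len(refine_set) else design_lr
    params = init
    short_range = None
    result: FitResult | None = None
    for _cycle in range(n_cycles):
        if short_range is None:
            c6 = _stage1_c6(design_lr, set_longrange, config, None)
        else:
            c6 = _stage1_c6(design_refine, refine_set, config, short_range)
        stage1 = params.with_pair_terms(
            replace(params.pair_o, c6=float(c6[0])), replace(params.pair_h, c6=float(c6[1]))
        )
        result = active_learning_fit(set_full, stage1, config, fit_c6=False)
        params = result.params
        short_range = (params.pair_o, params.pair_h)
    return result
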