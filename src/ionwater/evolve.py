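"""Self-adaptive evolutionary programming for cluster structure optimization.

Each individual is a pair of real vectors (chi, eta): the coordinate genes
and the per-gene strategy parameters controlling the mutation spread. A
parent mutates by

    chi'(j) = chi(j) + s_g * eta(j) * N_j(0, 1)
    eta'(j) = eta(j) * exp(tau' * N(0, 1) + tau'' * N_j(0, 1))

where N is one shared and N_j are per-gene standard normal draws, and
``s_g = delta0 * deltaj**g`` is a generation-decay step scale (delta0 = 0.15,
deltaj = 0.85 by default: every generation the displacement shrinks by the
deltaj factor; an alternative literal mode shrinks it by delta0 each
generation). Survivor selection is a stochastic q-opponent tournament over
the joint parent+child pool of 2M individuals: everyone plays q randomly
chosen opponents, the lower energy wins each encounter, and the M
individuals with the most wins (ties broken by lower energy) parent the next
generation. Convergence is declared when the best energy changes by less
than a threshold between consecutive generations (with a small patience so a
single flat step does not stop an active search).

Water monomers can evolve as rigid bodies (translation + rotation-vector
genes) so a rigid-water potential stays valid, or fully flexibly in
Cartesian mode. A Lennard-Jones cluster potential is included as a
validation fixture with known global minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    DomainError,
    EvaluationError,
)
from .geometry import Atom, ClusterConfiguration, identify_waters

__all__ = [
    "Individual",
    "EAConfig",
    "EAResult",
    "seed_from_water_cluster",
    "initialize_population",
    "mutate",
    "tournament_select",
    "optimize_cluster",
    "lennard_jones_energy",
]


@dataclass
class Individual:
    """(chi, eta) gene pair with cached fitness."""

    chi: np.ndarray  # coordinate genes
    eta: np.ndarray  # strategy parameters, > 0 (or 0 in degenerate test overrides)
    energy: float = math.nan

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.chi.shape != self.eta.shape:
            raise DomainError("chi and eta must have equal length")
        if np.any(self.eta < 0):
            raise DomainError("eta components must be >= 0")


@dataclass
class EAConfig:
    """Evolution-strategy knobs.

    ``tau_prime``/``tau_dprime`` default to the standard self-adaptive
    choices 1/sqrt(2n) and 1/sqrt(2 sqrt(n)) for gene length n.
    ``delta_init`` is the displacement factor for the initial population
    (uniform offsets in (0, delta_init) per gene). ``literal_decay`` selects
    the reading of the per-generation shrink: False multiplies the step scale
    by deltaj per generation (default), True by delta0.
    """

    population_m: int = 100
    tournament_q: int = 10
    tau_prime: float | None = None
    tau_dprime: float | None = None
    delta_init: float = 1.0  # A
    delta0: float = 0.15
    deltaj: float = 0.85
    energy_threshold: float = 0.01  # kcal/mol
    max_generations: int = 200
    patience: int = 3
    literal_decay: bool = False
    seed: int = 0
    # annealing-wave extension (n_cycles > 1): the step schedule restarts in
    # waves re-seeded from the incumbent best with shrinking perturbations
    n_cycles: int = 1
    cycle_patience: int = 4
    cycle_delta_decay: float = 0.6
    cycle_delta_floor: float = 0.02
    step_floor: float = 1e-4  # a wave ends when the step scale drops below this

    def __post_init__(self) -> None:
        if self.population_m < 2:
            raise DomainError("population_m must be >= 2")
        if not (1 <= self.tournament_q <= 2 * self.population_m - 1):
            raise ConfigurationError(
                f"tournament_q must be in [1, {2 * self.population_m - 1}]"
            )
        if not (0 < self.deltaj <= 1):
            raise DomainError("deltaj must be in (0, 1]")
        if self.energy_threshold <= 0:
            raise DomainError("energy_threshold must be > 0")

    def taus(self, n: int) -> tuple[float, float]:
        tp = self.tau_prime if self.tau_prime is not None else 1.0 / math.sqrt(2.0 * n)
        td = self.tau_dprime if self.tau_dprime is not None else 1.0 / math.sqrt(2.0 * math.sqrt(n))
        return tp, td

    def step_scale(self, generation: int) -> float:
        # literal mode reads "moves 85% less" as a x0.15 shrink per generation
        decay = self.delta0 if self.literal_decay else self.deltaj
        return self.delta0 * decay**generation


@dataclass
class EAResult:
    """Best individual found plus per-generation bookkeeping."""

    best: Individual
    best_config: ClusterConfiguration
    best_energy_per_generation: list[float] = field(default_factory=list)
    generations_run: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# Seeding


def seed_from_water_cluster(
    water_cluster: ClusterConfiguration, ion: str
) -> list[ClusterConfiguration]:
    """Ion-water seeds: replace one water with the ion, in all positions.

    Configuration k removes monomer k's three atoms and places the ion at
    that monomer's oxygen position, yielding exactly n_waters seeds.
    """
    if water_cluster.has_ion:
        raise DomainError("seed cluster must be pure water (no ion present)")
    monomers = identify_waters(water_cluster)
    if not monomers:
        raise DomainError("seed cluster has no water monomers")
    seeds = []
    for k, mono in enumerate(monomers):
        removed = set(mono.indices)
        atoms = [
            Atom(a.element, a.position.copy())
            for i, a in enumerate(water_cluster.atoms)
            if i not in removed
        ]
        atoms.append(Atom(ion, water_cluster.atoms[mono.o_index].position.copy()))
        seeds.append(
            ClusterConfiguration(
                atoms=atoms,
                ion_index=len(atoms) - 1,
                label=f"{water_cluster.label} ion@{k}".strip(),
            )
        )
    return seeds


# ---------------------------------------------------------------------------
# Gene encodings


class _CartesianGenes:
    """chi = flat Cartesian coordinates of all atoms."""

    def __init__(self, seed_config: ClusterConfiguration):
        self.template = seed_config
        self.n_genes = 3 * seed_config.n_atoms

    def encode(self, config: ClusterConfiguration) -> np.ndarray:
        return config.positions.ravel().copy()

    def decode(self, chi: np.ndarray) -> ClusterConfiguration:
        return self.template.with_positions(chi.reshape(-1, 3))


class _RigidWaterGenes:
    """Per-water rigid-body genes (translation + rotation vector) + ion xyz.

    Rotations act about each monomer's oxygen so O-H bond lengths and the
    HOH angle of the seed are preserved exactly.
    """

    def __init__(self, seed_config: ClusterConfiguration):
        self.template = seed_config
        self.monomers = identify_waters(seed_config)
        self.has_ion = seed_config.has_ion
        self.n_genes = 6 * len(self.monomers) + (3 if self.has_ion else 0)
        pos = seed_config.positions
        self._local = []  # H positions relative to O for each monomer
        for m in self.monomers:
            o = pos[m.o_index]
            self._local.append((pos[m.h1_index] - o, pos[m.h2_index] - o))
        self._o_ref = [pos[m.o_index].copy() for m in self.monomers]
        self._ion_ref = seed_config.ion.position.copy() if self.has_ion else None

    def encode(self, config: ClusterConfiguration) -> np.ndarray:
        # zero genes reproduce the seed; encoding arbitrary configs is not needed
        return np.zeros(self.n_genes)

    def decode(self, chi: np.ndarray) -> ClusterConfiguration:
        pos = self.template.positions
        off = 0
        for m, (h1l, h2l), o_ref in zip(self.monomers, self._local, self._o_ref):
            t = chi[off : off + 3]
            rvec = chi[off + 3 : off + 6]
            rot = Rotation.from_rotvec(rvec)
            o_new = o_ref + t
            pos[m.o_index] = o_new
            pos[m.h1_index] = o_new + rot.apply(h1l)
            pos[m.h2_index] = o_new + rot.apply(h2l)
            off += 6
        if self.has_ion:
            pos[self.template.ion_index] = self._ion_ref + chi[off : off + 3]
        return self.template.with_positions(pos)


def _make_genes(seed_config: ClusterConfiguration, mode: str):
    if mode == "auto":
        mode = "rigid" if seed_config.n_waters > 0 else "cartesian"
    if mode == "cartesian":
        return _CartesianGenes(seed_config)
    if mode == "rigid":
        return _RigidWaterGenes(seed_config)
    raise ConfigurationError(f"unknown gene mode {mode!r}")


# ---------------------------------------------------------------------------
# Core operators


def initialize_population(
    seed_config: ClusterConfiguration,
    config: EAConfig,
    rng: np.random.Generator,
    genes=None,
) -> list[Individual]:
    """M individuals around the seed: chi = seed genes + U(0, delta_init)
    per component, eta = 1. Deterministic for a fixed generator state."""
    genes = genes or _make_genes(seed_config, "auto")
    base = genes.encode(seed_config)
    population = []
    for _ in range(config.population_m):
        offset = rng.uniform(0.0, config.delta_init, size=genes.n_genes) if config.delta_init > 0 else 0.0
        population.append(Individual(chi=base + offset, eta=np.ones(genes.n_genes)))
    return population


def mutate(
    parent: Individual,
    generation: int,
    config: EAConfig,
    rng: np.random.Generator,
) -> Individual:
    """One offspring by the self-adaptive Gaussian mutation law.

    Draw order (fixed for reproducibility): per-gene N_j for chi, one shared
    N for eta, then per-gene N_j for eta.
    """
    n = len(parent.chi)
    s_g = config.step_scale(generation)
    n_chi = rng.standard_normal(n)
    chi = parent.chi + s_g * parent.eta * n_chi
    tp, td = config.taus(n)
    shared = rng.standard_normal()
    n_eta = rng.standard_normal(n)
    eta = parent.eta * np.exp(tp * shared + td * n_eta)
    return Individual(chi=chi, eta=eta)


def tournament_select(
    pool: list[Individual], config: EAConfig, rng: np.random.Generator
) -> list[Individual]:
    """Top-M survivors by q-opponent tournament wins over the 2M pool.

    Each individual meets q distinct random opponents; the lower (or equal)
    energy wins the encounter. Survivors are the M individuals with the most
    wins, ties broken by lower energy then pool order, so the best individual
    always survives (elitism).
    """
    m2 = len(pool)
    if m2 != 2 * config.population_m:
        raise ConfigurationError(f"pool size {m2} != 2M = {2 * config.population_m}")
    q = config.tournament_q
    if not (1 <= q <= m2 - 1):
        raise ConfigurationError(f"tournament_q {q} out of range [1, {m2 - 1}]")
    energies = np.array([ind.energy for ind in pool])
    wins = np.empty(m2, dtype=int)
    for i in range(m2):
        opponents = rng.choice(m2 - 1, size=q, replace=False)
        opponents[opponents >= i] += 1  # exclude self
        wins[i] = int(np.sum(energies[i] <= energies[opponents]))
    order = sorted(range(m2), key=lambda i: (-wins[i], energies[i], i))
    return [pool[i] for i in order[: config.population_m]]


# ---------------------------------------------------------------------------
# Main loop


def _wave_length(config: EAConfig) -> int:
    """Generations until the step scale decays below ``step_floor``."""
    decay = config.deltaj if not config.literal_decay else config.delta0
    if decay >= 1.0:
        return config.max_generations
    n = math.ceil(math.log(config.step_floor / config.delta0) / math.log(decay))
    return max(1, min(config.max_generations, n))


def optimize_cluster(
    potential,
    seed_config: ClusterConfiguration,
    config: EAConfig | None = None,
    mode: str = "auto",
) -> EAResult:
    """Locate a minimum-energy configuration of ``potential`` by EP.

    ``potential`` is an energy callback taking a ClusterConfiguration and
    returning kcal/mol. ``mode`` selects the gene encoding: "rigid" (water
    monomers as rigid bodies; default when waters are present), "cartesian"
    (all coordinates free), or "auto".

    With ``n_cycles == 1`` this is the plain generational loop: mutate all
    parents, join parents and children, tournament-select, and stop when the
    best energy changes by less than ``energy_threshold`` for ``patience``
    consecutive generations. With ``n_cycles > 1`` the same loop runs in
    annealing waves: each wave replays the decaying step schedule from a
    population re-seeded around the incumbent best (elite carried over) with
    a perturbation amplitude that shrinks while no wave improves the best
    energy by the threshold; the run converges after ``cycle_patience``
    non-improving waves.
    """
    config = config or EAConfig()
    genes = _make_genes(seed_config, mode)
    rng = np.random.default_rng(config.seed)

    def evaluate(ind: Individual, tag: str) -> None:
        e = float(potential(genes.decode(ind.chi)))
        if not math.isfinite(e):
            raise EvaluationError(f"potential returned non-finite energy for {tag}")
        ind.energy = e

    def make_population(base: np.ndarray, delta: float, elite: Individual | None):
        pop = []
        for _ in range(config.population_m):
            offset = rng.uniform(0.0, delta, size=genes.n_genes) if delta > 0 else 0.0
            pop.append(Individual(chi=base + offset, eta=np.ones(genes.n_genes)))
        if elite is not None:
            pop[0] = Individual(chi=elite.chi.copy(), eta=np.ones(genes.n_genes),
                                energy=elite.energy)
        for i, ind in enumerate(pop):
            if math.isnan(ind.energy):
                evaluate(ind, f"initial individual {i}")
        return pop

    best_series: list[float] = []
    best: Individual | None = None
    converged = False
    generations = 0
    seed_genes = genes.encode(seed_config)
    wave_len = _wave_length(config)
    flat_waves = 0
    single = config.n_cycles == 1
    n_waves = 1 if single else config.n_cycles
    for wave in range(n_waves):
        delta = (
            config.delta_init
            if single
            else max(config.delta_init * config.cycle_delta_decay**flat_waves,
                     config.cycle_delta_floor)
        )
        parents = make_population(
            seed_genes if best is None else best.chi, delta, best
        )
        wave_start_best = min(parents, key=lambda ind: ind.energy)
        if best is None or wave_start_best.energy < best.energy:
            best = Individual(wave_start_best.chi.copy(), wave_start_best.eta.copy(),
                              wave_start_best.energy)
        prev_best = best.energy
        if not best_series:
            best_series.append(best.energy)
        flat_gens = 0
        gen_cap = config.max_generations if single else wave_len
        for g in range(gen_cap):
            children = [mutate(p, g, config, rng) for p in parents]
            for i, c in enumerate(children):
                evaluate(c, f"generation {g} child {i}")
            parents = tournament_select(parents + children, config, rng)
            generations += 1
            gen_best = min(parents, key=lambda ind: ind.energy)
            if gen_best.energy < best.energy:
                best = Individual(gen_best.chi.copy(), gen_best.eta.copy(), gen_best.energy)
            best_series.append(best.energy)
            if abs(best_series[-2] - best_series[-1]) < config.energy_threshold:
                flat_gens += 1
                if single and flat_gens >= config.patience:
                    converged = True
                    break
            else:
                flat_gens = 0
        if single:
            break
        if prev_best - best.energy < config.energy_threshold:
            flat_waves += 1
            if flat_waves >= config.cycle_patience:
                converged = True
                break
        else:
            flat_waves = 0
    return EAResult(
        best=best,
        best_config=genes.decode(best.chi),
        best_energy_per_generation=best_series,
        generations_run=generations,
        converged=converged,
    )


def global_minimum_search(
    potential,
    seed_configs: list[ClusterConfiguration],
    config: EAConfig | None = None,
    mode: str = "auto",
    polish: bool = True,
) -> EAResult:
    """Multistart EP: one annealed run per seed configuration, keep the best.

    Mirrors the seeding protocol in which every substitution/initial
    structure starts its own optimization. Per-run seeds derive
    deterministically from ``config.seed``. With ``polish`` a final
    small-perturbation run refines the overall best.
    """
    config = config or EAConfig()
    if not seed_configs:
        raise DomainError("need at least one seed configuration")
    from dataclasses import replace as _replace

    base_cfg = _replace(config, n_cycles=max(config.n_cycles, 2))
    best_result: EAResult | None = None
    seeds = np.random.SeedSequence(config.seed).generate_state(len(seed_configs) + 1)
    for k, seed_config in enumerate(seed_configs):
        run_cfg = _replace(base_cfg, seed=int(seeds[k] % (2**31)))
        res = optimize_cluster(potential, seed_config, run_cfg, mode)
        if best_result is None or res.best.energy < best_result.best.energy:
            best_result = res
    if polish:
        polish_cfg = _replace(
            base_cfg,
            seed=int(seeds[-1] % (2**31)),
            delta_init=config.cycle_delta_floor,
            n_cycles=3,
            cycle_patience=2,
        )
        res = optimize_cluster(potential, best_result.best_config, polish_cfg, mode)
        if res.best.energy < best_result.best.energy:
            best_result = res
    return best_result


# ---------------------------------------------------------------------------
# Validation fixture


def lennard_jones_energy(
    config: ClusterConfiguration, epsilon: float = 1.0, sigma: float = 1.0
) -> float:
    """Pairwise 4*eps*((sigma/r)^12 - (sigma/r)^6) over all atom pairs."""
    pos = config.positions
    n = len(pos)
    if n < 2:
        raise DomainError("Lennard-Jones cluster needs at least two particles")
    d = pos[:, None, :] - pos[None, :, :]
    r = np.linalg.norm(d, axis=-1)
    iu = np.triu_indices(n, k=1)
    rr = r[iu]
    if np.any(rr < 1e-10):
        raise DegenerateGeometryError("coincident particles")
    s6 = (sigma / rr) ** 6
    return float(np.sum(4.0 * epsilon * (s6 * s6 - s6)))
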