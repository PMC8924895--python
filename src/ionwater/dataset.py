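"""Dimer training sets: spherical grids, energy weights, synthetic references.

Training configurations are ion + one rigid water dimers placed on a grid
that is equidistant in R (ion-oxygen distance), theta (polar angle) and phi
(azimuthal angle). The water-fixed frame puts O at the origin with the C2v
axis along z (H atoms in the xz-plane, HOH bisector toward -z); theta is
measured from +z and phi from +x. Water's mirror symmetry in the xz-plane
makes phi in [0, 180] deg non-redundant, and theta spans [0, 180] deg.

Reference energies favor low-energy regions through the weights

    w_N(E) = (1 / (E - E_min + D_E))^2

which are maximal at the training-set minimum E_min and decay with E; D_E
sets the width of the favorably weighted energy band.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import WATER_HOH, WATER_ROH
from .errors import (
    ConfigurationError,
    DataError,
    DegenerateGeometryError,
    DomainError,
    FormatError,
)
from .geometry import Atom, ClusterConfiguration
from .parameters import IonWaterParameters

__all__ = [
    "GridSpec",
    "TrainingPoint",
    "TrainingSet",
    "rigid_water_monomer",
    "dimer_from_spherical",
    "spherical_from_config",
    "build_spherical_grid",
    "energy_weights",
    "assign_energy_weights",
    "make_synthetic_reference",
    "write_training_set",
    "read_training_set",
]

FRAME_TAG = "O-origin,C2v-z,H-in-xz,bisector-minus-z"


@dataclass
class GridSpec:
    """Equidistant (R, theta, phi) grid specification."""

    r_min: float = 2.0  # A
    r_max: float = 8.0  # A
    n_r: int = 10
    n_theta: int = 10
    n_phi: int = 5
    frame: str = FRAME_TAG

    def __post_init__(self) -> None:
        if self.r_min <= 0:
            raise DomainError("r_min must be > 0")
        if self.r_max < self.r_min:
            raise DomainError("r_max must be >= r_min")
        if min(self.n_r, self.n_theta, self.n_phi) < 1:
            raise DomainError("grid counts must be >= 1")

    @property
    def n_points(self) -> int:
        return self.n_r * self.n_theta * self.n_phi


@dataclass
class TrainingPoint:
    """One dimer configuration with its grid coordinates and reference data."""

    config: ClusterConfiguration
    r: float  # A
    theta: float  # degrees
    phi: float  # degrees
    e_ref: float | None = None
    weight: float | None = None


@dataclass
class TrainingSet:
    """Dimer training configurations with reference energies and weights."""

    points: list[TrainingPoint]
    d_e: float = 2.0  # kcal/mol, width of the favorably weighted band
    provenance: str = ""
    ion: str = ""
    r_oh: float = WATER_ROH
    angle_hoh: float = WATER_HOH

    def __post_init__(self) -> None:
        if self.d_e <= 0:
            raise DomainError("d_e must be > 0")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def e_min(self) -> float:
        """Minimum reference energy over the set, kcal/mol."""
        energies = [p.e_ref for p in self.points if p.e_ref is not None]
        if not energies:
            raise DataError("training set has no reference energies")
        return float(min(energies))

    @property
    def e_ref(self) -> np.ndarray:
        if any(p.e_ref is None for p in self.points):
            raise DataError("training set has unset reference energies")
        return np.array([p.e_ref for p in self.points], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        if any(p.weight is None for p in self.points):
            raise ConfigurationError("training set has unset weights")
        return np.array([p.weight for p in self.points], dtype=float)

    def set_weights(self, weights) -> None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(self.points),):
            raise DataError(f"expected {len(self.points)} weights, got {weights.shape}")
        if np.any(weights < 0):
            raise DataError("weights must be >= 0")
        for p, w in zip(self.points, weights):
            p.weight = float(w)

    def subset(self, mask) -> "TrainingSet":
        """A new set over the selected points.

        Point records are copied (the geometries are shared), so weight or
        energy edits on the subset never touch the parent set.
        """
        from dataclasses import replace as _replace

        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return TrainingSet(
            points=[_replace(self.points[i]) for i in idx],
            d_e=self.d_e,
            provenance=self.provenance,
            ion=self.ion,
            r_oh=self.r_oh,
            angle_hoh=self.angle_hoh,
        )


# ---------------------------------------------------------------------------
# Frame geometry


def rigid_water_monomer(r_oh: float = WATER_ROH, angle_hoh: float = WATER_HOH) -> ClusterConfiguration:
    """One water in the canonical frame: O at origin, H in xz, bisector -> -z."""
    half = math.radians(angle_hoh) / 2.0
    h_x = r_oh * math.sin(half)
    h_z = -r_oh * math.cos(half)
    atoms = [
        Atom("O", np.zeros(3)),
        Atom("H", np.array([h_x, 0.0, h_z])),
        Atom("H", np.array([-h_x, 0.0, h_z])),
    ]
    return ClusterConfiguration(atoms=atoms, label="rigid water")


def dimer_from_spherical(
    ion: str,
    r: float,
    theta: float,
    phi: float,
    water: ClusterConfiguration | None = None,
) -> ClusterConfiguration:
    """Ion + rigid water dimer with the ion at spherical (r, theta, phi)."""
    if water is None:
        water = rigid_water_monomer()
    th, ph = math.radians(theta), math.radians(phi)
    ion_pos = np.array(
        [r * math.sin(th) * math.cos(ph), r * math.sin(th) * math.sin(ph), r * math.cos(th)]
    )
    atoms = [Atom(a.element, a.position.copy()) for a in water.atoms]
    atoms.append(Atom(ion, ion_pos))
    return ClusterConfiguration(
        atoms=atoms,
        ion_index=len(atoms) - 1,
        label=f"{ion}-(H2O) R={r:.4f} theta={theta:.2f} phi={phi:.2f}",
    )


def spherical_from_config(config: ClusterConfiguration) -> tuple[float, float, float]:
    """Recover (R, theta, phi) of the ion in the water-fixed frame.

    Assumes the water already sits in the canonical frame (as grid-generated
    configurations do). phi is folded into [0, 180] deg by the xz mirror
    symmetry; at theta = 0 or 180 deg phi is conventionally 0.
    """
    if not config.has_ion:
        raise DomainError("no ion in configuration")
    x, y, z = config.ion.position
    r = float(math.sqrt(x * x + y * y + z * z))
    if r < 1e-12:
        raise DegenerateGeometryError("ion at the oxygen position")
    theta = math.degrees(math.acos(max(-1.0, min(1.0, z / r))))
    rho = math.hypot(x, y)
    phi = 0.0 if rho < 1e-10 else math.degrees(math.atan2(abs(y), x))
    return r, theta, phi


def _axis_values(lo: float, hi: float, n: int) -> np.ndarray:
    """n values equidistant on [lo, hi]; the midpoint when n == 1."""
    if n == 1:
        return np.array([lo])
    return np.linspace(lo, hi, n)


def build_spherical_grid(
    spec: GridSpec,
    ion: str,
    water_geometry: ClusterConfiguration | None = None,
    overlap_tol: float = 0.5,
) -> list[TrainingPoint]:
    """All n_r * n_theta * n_phi dimer configurations of the grid, in
    lexicographic (R, theta, phi) order. Weights and references are unset.

    Raises :class:`DegenerateGeometryError` when r_min brings the ion within
    ``overlap_tol`` angstrom of a water atom, listing the offending points.
    """
    if water_geometry is None:
        water_geometry = rigid_water_monomer()
    r_values = _axis_values(spec.r_min, spec.r_max, spec.n_r)
    th_values = _axis_values(0.0, 180.0, spec.n_theta)
    ph_values = _axis_values(0.0, 180.0, spec.n_phi)
    points: list[TrainingPoint] = []
    offending: list[str] = []
    wpos = water_geometry.positions
    for r in r_values:
        for th in th_values:
            for ph in ph_values:
                config = dimer_from_spherical(ion, float(r), float(th), float(ph), water_geometry)
                dmin = float(np.min(np.linalg.norm(wpos - config.ion.position, axis=1)))
                if dmin < overlap_tol:
                    offending.append(f"(R={r:.3f}, theta={th:.1f}, phi={ph:.1f}): {dmin:.3f} A")
                points.append(TrainingPoint(config=config, r=float(r), theta=float(th), phi=float(ph)))
    if offending:
        raise DegenerateGeometryError(
            "ion overlaps water atoms at grid points: " + "; ".join(offending[:5])
            + ("..." if len(offending) > 5 else "")
        )
    return points


# ---------------------------------------------------------------------------
# Weights


def energy_weights(training_set: TrainingSet, e_min: float | None = None) -> np.ndarray:
    """w(E) = (1 / (E - E_min + D_E))^2 per point; maximal at E = E_min.

    ``e_min`` defaults to the set's own minimum; passing the minimum of a
    parent set keeps subset weights on the parent scale. An energy below the
    declared minimum makes the set inconsistent.
    """
    e = training_set.e_ref
    if e_min is None:
        e_min = training_set.e_min
    if np.any(e < e_min - 1e-12):
        raise DataError("reference energy below the declared minimum; inconsistent set")
    return (1.0 / (e - e_min + training_set.d_e)) ** 2


def assign_energy_weights(training_set: TrainingSet) -> np.ndarray:
    """Compute the energy weights and store them on the points."""
    w = energy_weights(training_set)
    training_set.set_weights(w)
    return w


# ---------------------------------------------------------------------------
# Synthetic reference data


def make_synthetic_reference(
    true_params: IonWaterParameters,
    grid: list[TrainingPoint],
    noise_sd: float = 0.0,
    seed: int = 0,
    d_e: float = 2.0,
) -> TrainingSet:
    """Reference energies from a known ground-truth potential plus noise.

    Stands in for ab initio dimer interaction energies in fit-recovery
    fixtures: ``e_ref = V_model(true_params) + N(0, noise_sd)``,
    deterministic for a given seed. Weights are left unset.
    """
    from .potential import ion_water_energy

    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(grid)) if noise_sd > 0 else np.zeros(len(grid))
    points = []
    for p, eps in zip(grid, noise):
        e = ion_water_energy(true_params, p.config).total + float(eps)
        points.append(TrainingPoint(config=p.config, r=p.r, theta=p.theta, phi=p.phi, e_ref=e))
    provenance = json.dumps(
        {
            "generator": "make_synthetic_reference",
            "params_hash": true_params.content_hash(),
            "seed": int(seed),
            "noise_sd": float(noise_sd),
        },
        sort_keys=True,
    )
    return TrainingSet(points=points, d_e=d_e, provenance=provenance, ion=true_params.ion)


# ---------------------------------------------------------------------------
# I/O: TSV + JSON sidecar


def _sidecar_path(path) -> str:
    return str(path) + ".json"


def write_training_set(training_set: TrainingSet, path) -> None:
    """TSV with columns R, theta, phi, e_ref, weight + JSON sidecar."""
    df = pd.DataFrame(
        {
            "R": [p.r for p in training_set.points],
            "theta": [p.theta for p in training_set.points],
            "phi": [p.phi for p in training_set.points],
            "e_ref": [p.e_ref if p.e_ref is not None else np.nan for p in training_set.points],
            "weight": [p.weight if p.weight is not None else np.nan for p in training_set.points],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    meta = {
        "frame": FRAME_TAG,
        "d_e": training_set.d_e,
        "provenance": training_set.provenance,
        "ion": training_set.ion,
        "r_oh": training_set.r_oh,
        "angle_hoh": training_set.angle_hoh,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_training_set(path, ion: str | None = None) -> TrainingSet:
    """Read a TSV training set; dimer configurations are rebuilt from
    (R, theta, phi) using the frame recorded in the JSON sidecar."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty training-set file") from None
    required = {"R", "theta", "phi", "e_ref", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("R", "theta", "phi"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(f"{path}: non-numeric {col!r} cell in row {bad[0] + 2}")
        df[col] = coerced
    for col in ("e_ref", "weight"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    meta = {"d_e": 2.0, "provenance": "", "ion": ion or "", "r_oh": WATER_ROH, "angle_hoh": WATER_HOH}
    try:
        with open(_sidecar_path(path)) as fh:
            meta.update(json.load(fh))
    except FileNotFoundError:
        pass
    if ion:
        meta["ion"] = ion
    if not meta["ion"]:
        raise FormatError(f"{path}: ion not given and absent from the sidecar")
    water = rigid_water_monomer(meta["r_oh"], meta["angle_hoh"])
    points = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        vals = [row.R, row.theta, row.phi]
        if any(not np.isfinite(v) for v in vals):
            raise FormatError(f"{path}: non-numeric coordinate in row {row_no}")
        config = dimer_from_spherical(meta["ion"], row.R, row.theta, row.phi, water)
        points.append(
            TrainingPoint(
                config=config,
                r=float(row.R),
                theta=float(row.theta),
                phi=float(row.phi),
                e_ref=None if pd.isna(row.e_ref) else float(row.e_ref),
                weight=None if pd.isna(row.weight) else float(row.weight),
            )
        )
    return TrainingSet(
        points=points,
        d_e=float(meta["d_e"]),
        provenance=str(meta["provenance"]),
        ion=str(meta["ion"]),
        r_oh=float(meta["r_oh"]),
        angle_hoh=float(meta["angle_hoh"]),
    )
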