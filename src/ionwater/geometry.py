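"""Cluster geometries: XYZ I/O, water-monomer detection, structural analyses.

A :class:`ClusterConfiguration` is an ordered list of atoms with at most one
halide ion. All energy kernels and the optimizer operate on this type.
Structural analyses cover the surface-plane distance decomposition used to
characterize whether the ion sits on the cluster surface, and the
ion-displacement scan paths used to probe non-equilibrium configurations.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASSES, DEFAULT_OH_CUTOFF, HALIDES
from .errors import (
    DegenerateGeometryError,
    DomainError,
    FormatError,
    TopologyError,
)

__all__ = [
    "Atom",
    "ClusterConfiguration",
    "WaterMonomer",
    "PlaneAnalysis",
    "read_xyz",
    "read_xyz_frames",
    "write_xyz",
    "write_xyz_frames",
    "identify_waters",
    "center_of_mass",
    "surface_plane_analysis",
    "ion_scan_path",
]

_ENERGY_TAG = re.compile(r"\bE=([-+0-9.eEdD]+)\b")


@dataclass
class Atom:
    """One atom: chemical symbol and Cartesian position in angstrom."""

    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.element not in ATOMIC_MASSES:
            raise DomainError(f"unknown element {self.element!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise DomainError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise DomainError("position components must be finite")
        self.position = pos

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES[self.element]


@dataclass
class ClusterConfiguration:
    """Ordered atoms with an optional ion tag.

    Parameters
    ----------
    atoms
        Atom list in file order.
    ion_index
        Index of the halide ion, or None for a pure-water (or generic) cluster.
    label
        Free-text identifier, used as the structure id in benchmark tables.
    energy_tag
        Optional energy carried from the XYZ comment line, kcal/mol.
    """

    atoms: list[Atom]
    ion_index: int | None = None
    label: str = ""
    energy_tag: float | None = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if self.ion_index is not None:
            if not (0 <= self.ion_index < n):
                raise DomainError(f"ion_index {self.ion_index} out of range for {n} atoms")
            if self.atoms[self.ion_index].element not in HALIDES:
                raise DomainError(
                    f"atom {self.ion_index} ({self.atoms[self.ion_index].element}) is not a halide"
                )
        halides = [i for i, a in enumerate(self.atoms) if a.element in HALIDES]
        tagged = set(halides) - ({self.ion_index} if self.ion_index is not None else set())
        if tagged:
            raise DomainError(
                f"halide atoms {sorted(tagged)} present but not tagged as the ion; "
                "a configuration holds at most one ion"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_waters(self) -> int:
        return sum(1 for a in self.atoms if a.element == "O")

    @property
    def has_ion(self) -> bool:
        return self.ion_index is not None

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def ion(self) -> Atom:
        if self.ion_index is None:
            raise DomainError("configuration has no ion")
        return self.atoms[self.ion_index]

    def water_indices(self) -> list[int]:
        """Indices of all non-ion atoms, in order."""
        return [i for i in range(self.n_atoms) if i != self.ion_index]

    def copy(self) -> "ClusterConfiguration":
        return ClusterConfiguration(
            atoms=[Atom(a.element, a.position.copy()) for a in self.atoms],
            ion_index=self.ion_index,
            label=self.label,
            energy_tag=self.energy_tag,
        )

    def with_positions(self, positions: np.ndarray) -> "ClusterConfiguration":
        positions = np.asarray(positions, dtype=float).reshape(self.n_atoms, 3)
        return ClusterConfiguration(
            atoms=[Atom(a.element, p.copy()) for a, p in zip(self.atoms, positions)],
            ion_index=self.ion_index,
            label=self.label,
            energy_tag=None,
        )

    def without_ion(self) -> "ClusterConfiguration":
        """The same geometry with the ion removed (water-only sub-cluster)."""
        atoms = [Atom(a.element, a.position.copy()) for i, a in enumerate(self.atoms) if i != self.ion_index]
        return ClusterConfiguration(atoms=atoms, ion_index=None, label=self.label)

    def transformed(self, rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0)) -> "ClusterConfiguration":
        """Apply a rigid rotation (3x3 matrix) followed by a translation."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, dtype=float).T
        pos = pos + np.asarray(translation, dtype=float)
        return self.with_positions(pos)


@dataclass
class WaterMonomer:
    """Bookkeeping for one O + 2H triplet detected in a configuration."""

    o_index: int
    h1_index: int
    h2_index: int
    r_oh1: float
    r_oh2: float
    angle_hoh: float

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.o_index, self.h1_index, self.h2_index)


@dataclass
class PlaneAnalysis:
    """Signed distances of oxygens and ion from the surface-analysis plane.

    The plane passes through the cluster center of mass, perpendicular to the
    COM-to-ion line; positive distances point toward the ion, so an ion
    sitting outside the oxygen shell has ``r_ion > max(r_oxygen)``.
    """

    plane_point: np.ndarray
    plane_normal: np.ndarray
    oxygen_indices: list[int]
    r_oxygen: np.ndarray
    ion_index: int
    r_ion: float

    def to_table(self) -> pd.DataFrame:
        """Tabular export; atom indices are reported 1-based."""
        rows = [
            {"site_type": "O", "atom_index": i + 1, "r": r}
            for i, r in zip(self.oxygen_indices, self.r_oxygen)
        ]
        rows.append({"site_type": "ion", "atom_index": self.ion_index + 1, "r": self.r_ion})
        return pd.DataFrame(rows, columns=["site_type", "atom_index", "r"])

    def write_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @property
    def ion_on_surface(self) -> bool:
        """True when the ion lies beyond every oxygen along the COM-ion axis."""
        return bool(self.r_ion > float(np.max(self.r_oxygen)))


# ---------------------------------------------------------------------------
# XYZ I/O


def _detect_ion(atoms: list[Atom], line_offset: int = 0) -> int | None:
    halides = [i for i, a in enumerate(atoms) if a.element in HALIDES]
    if len(halides) > 1:
        raise FormatError(
            f"multiple halide atoms at records {', '.join(str(i + 1) for i in halides)}; "
            "a cluster holds at most one ion"
        )
    return halides[0] if halides else None


def _parse_frame(lines: list[str], start: int) -> tuple[ClusterConfiguration, int]:
    """Parse one XYZ frame beginning at ``lines[start]``; returns (config, next_line)."""
    ln = start
    try:
        count = int(lines[ln].split()[0])
    except (IndexError, ValueError):
        raise FormatError(f"line {ln + 1}: malformed atom-count line {lines[ln]!r}") from None
    if count < 1:
        raise FormatError(f"line {ln + 1}: atom count must be positive, got {count}")
    if ln + 1 >= len(lines):
        raise FormatError(f"line {ln + 2}: missing comment line")
    comment = lines[ln + 1].rstrip("\n")
    energy_tag = None
    m = _ENERGY_TAG.search(comment)
    if m:
        try:
            energy_tag = float(m.group(1).replace("D", "E").replace("d", "e"))
        except ValueError:
            raise FormatError(f"line {ln + 2}: unparsable energy tag {m.group(0)!r}") from None
    atoms: list[Atom] = []
    for k in range(count):
        idx = ln + 2 + k
        if idx >= len(lines) or not lines[idx].strip():
            raise FormatError(
                f"line {idx + 1}: expected {count} atom records, found {k}"
            )
        parts = lines[idx].split()
        if len(parts) < 4:
            raise FormatError(f"line {idx + 1}: expected 'element x y z', got {lines[idx]!r}")
        element = parts[0]
        if element not in ATOMIC_MASSES:
            raise FormatError(f"line {idx + 1}: unknown element {element!r}")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise FormatError(f"line {idx + 1}: coordinate parse failure in {lines[idx]!r}") from None
        atoms.append(Atom(element, np.array(xyz)))
    config = ClusterConfiguration(
        atoms=atoms,
        ion_index=_detect_ion(atoms),
        label=comment.strip(),
        energy_tag=energy_tag,
    )
    return config, ln + 2 + count


def read_xyz(path) -> ClusterConfiguration:
    """Read a single-frame XYZ file.

    The comment line is kept as the label; a token ``E=<float>`` in it is
    parsed into ``energy_tag`` (kcal/mol). The ion is auto-detected as the
    unique halide element, if any.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty file")
    config, _ = _parse_frame(lines, 0)
    return config


def read_xyz_frames(path) -> list[ClusterConfiguration]:
    """Read a multi-frame XYZ file (concatenated frames)."""
    with open(path) as fh:
        lines = fh.readlines()
    frames: list[ClusterConfiguration] = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        config, ln = _parse_frame(lines, ln)
        frames.append(config)
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return frames


def _format_frame(config: ClusterConfiguration, comment: str | None) -> str:
    if comment is None:
        comment = config.label or ""
        if config.energy_tag is not None and "E=" not in comment:
            comment = (comment + f" E={config.energy_tag:.10g}").strip()
    out = [f"{config.n_atoms}", comment]
    for a in config.atoms:
        x, y, z = a.position
        out.append(f"{a.element:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    return "\n".join(out) + "\n"


def write_xyz(config: ClusterConfiguration, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_format_frame(config, comment))


def write_xyz_frames(configs: list[ClusterConfiguration], path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(_format_frame(c, None))


# ---------------------------------------------------------------------------
# Monomer detection


def identify_waters(
    config: ClusterConfiguration, oh_cutoff: float = DEFAULT_OH_CUTOFF
) -> list[WaterMonomer]:
    """Partition non-ion atoms into O + 2H water monomers.

    Each hydrogen is assigned to its nearest oxygen within ``oh_cutoff``; the
    assignment must be a perfect matching with exactly two hydrogens per
    oxygen. Ambiguous hydrogens (two oxygens within the cutoff at nearly the
    same distance) raise :class:`TopologyError`.
    """
    o_idx = [i for i in config.water_indices() if config.atoms[i].element == "O"]
    h_idx = [i for i in config.water_indices() if config.atoms[i].element == "H"]
    other = [
        i for i in config.water_indices() if config.atoms[i].element not in ("O", "H")
    ]
    if other:
        raise TopologyError(f"non-water, non-ion atoms at indices {other}")
    if len(h_idx) != 2 * len(o_idx):
        raise TopologyError(
            f"{len(o_idx)} oxygens require {2 * len(o_idx)} hydrogens, found {len(h_idx)}"
        )
    pos = config.positions
    assigned: dict[int, list[int]] = {i: [] for i in o_idx}
    for h in h_idx:
        dists = sorted((float(np.linalg.norm(pos[h] - pos[o])), o) for o in o_idx)
        within = [(d, o) for d, o in dists if d <= oh_cutoff]
        if not within:
            raise TopologyError(f"hydrogen {h} has no oxygen within {oh_cutoff} A")
        if len(within) > 1 and within[1][0] - within[0][0] < 0.2:
            raise TopologyError(
                f"hydrogen {h} is ambiguously close to oxygens {within[0][1]} and {within[1][1]}"
            )
        assigned[within[0][1]].append(h)
    monomers: list[WaterMonomer] = []
    for o in o_idx:
        hs = sorted(assigned[o])
        if len(hs) != 2:
            raise TopologyError(f"oxygen {o} has {len(hs)} hydrogens within cutoff, needs 2")
        v1 = pos[hs[0]] - pos[o]
        v2 = pos[hs[1]] - pos[o]
        r1, r2 = float(np.linalg.norm(v1)), float(np.linalg.norm(v2))
        cosang = float(np.clip(np.dot(v1, v2) / (r1 * r2), -1.0, 1.0))
        monomers.append(
            WaterMonomer(
                o_index=o,
                h1_index=hs[0],
                h2_index=hs[1],
                r_oh1=r1,
                r_oh2=r2,
                angle_hoh=math.degrees(math.acos(cosang)),
            )
        )
    return monomers


# ---------------------------------------------------------------------------
# Structural analyses


def center_of_mass(config: ClusterConfiguration, include_ion: bool = True) -> np.ndarray:
    """Mass-weighted mean position (standard atomic weights), angstrom."""
    if config.n_atoms == 0:
        raise DomainError("empty configuration has no center of mass")
    if include_ion or not config.has_ion:
        masses, pos = config.masses, config.positions
    else:
        idx = config.water_indices()
        if not idx:
            raise DomainError("no water atoms to average over")
        masses = config.masses[idx]
        pos = config.positions[idx]
    return np.asarray(masses @ pos / masses.sum())


def surface_plane_analysis(
    config: ClusterConfiguration, include_ion_in_com: bool = True
) -> PlaneAnalysis:
    """Signed distances of each oxygen and the ion from the COM plane.

    The plane is perpendicular to the line joining the cluster center of mass
    and the ion, and contains the center of mass; distances are measured along
    the COM-to-ion unit vector (positive toward the ion).
    """
    if not config.has_ion:
        raise DomainError("surface-plane analysis requires an ion")
    com = center_of_mass(config, include_ion=include_ion_in_com)
    axis = config.ion.position - com
    norm = float(np.linalg.norm(axis))
    if norm < 1e-8:
        raise DegenerateGeometryError("ion coincides with the center of mass; plane normal undefined")
    normal = axis / norm
    o_idx = [i for i, a in enumerate(config.atoms) if a.element == "O"]
    pos = config.positions
    r_o = np.array([float(np.dot(pos[i] - com, normal)) for i in o_idx])
    return PlaneAnalysis(
        plane_point=com,
        plane_normal=normal,
        oxygen_indices=o_idx,
        r_oxygen=r_o,
        ion_index=config.ion_index,
        r_ion=float(np.dot(config.ion.position - com, normal)),
    )


DEFAULT_SCAN_STEPS = (0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0, 1.1, 1.25, 1.5)


def ion_scan_path(
    config: ClusterConfiguration,
    steps=DEFAULT_SCAN_STEPS,
    include_ion_in_com: bool = True,
) -> list[ClusterConfiguration]:
    """Displace the ion along the COM-to-minimum line, waters held fixed.

    Step ``s`` places the ion at ``COM + s * (ion_position - COM)``: s=0 is
    the cluster center of mass, s=1 the original (minimum-energy) position,
    s>1 extrapolates outward into the dissociative region.
    """
    if not config.has_ion:
        raise DomainError("ion scan requires an ion")
    steps = list(steps)
    if not steps:
        raise DomainError("empty steps list")
    com = center_of_mass(config, include_ion=include_ion_in_com)
    ion_pos = config.ion.position.copy()
    out = []
    for s in steps:
        c = config.copy()
        # s=1 reproduces the input bit-exactly (no round-trip through the COM)
        new_pos = ion_pos.copy() if s == 1.0 else com + float(s) * (ion_pos - com)
        c.atoms[c.ion_index].position = new_pos
        c.label = (config.label + f" scan_step={s:g}").strip()
        c.energy_tag = None
        out.append(c)
    return out
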