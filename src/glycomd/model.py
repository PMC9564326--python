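"""Core structural data model: atoms, topologies, frames, trajectories,
force-field parameter tables and the analysis configuration.

Atom indices are 0-based everywhere in memory; file I/O converts to the
formats' native 1-based serials. Coordinates are Angstrom, times ns.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import constants as C
from .errors import (
    MissingParameterError,
    ParameterError,
    SelectionError,
    TopologyMismatchError,
)

#: Residue names treated as water by default.
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "SPC"})
#: Residue names treated as monoatomic ions by default.
DEFAULT_ION_RESNAMES = frozenset(
    {"CA", "CAL", "NA", "NA+", "CL", "CL-", "MG", "K", "ZN", "MN", "FE"}
)


@dataclass(frozen=True)
class Atom:
    """A single atom record."""

    serial: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain: str = "A"
    is_water: bool = False
    is_ion: bool = False


class Topology:
    """Ordered atom list plus named index groups and (optional) bonds.

    Groups are named ``numpy`` integer index arrays (e.g. ``"receptor"``,
    ``"ligand"``, ``"ring_atoms"``). The ``"receptor"`` and ``"ligand"``
    groups, when both present, must be disjoint.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        groups: Optional[Mapping[str, Iterable[int]]] = None,
        bonds: Optional[Iterable[Tuple[int, int]]] = None,
    ):
        self.atoms: List[Atom] = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a topology")
        self.groups: Dict[str, np.ndarray] = {}
        for name, idx in (groups or {}).items():
            self.set_group(name, idx)
        self.bonds: List[Tuple[int, int]] = [
            (min(i, j), max(i, j)) for i, j in (bonds or [])
        ]
        for i, j in self.bonds:
            if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"bond ({i},{j}) references missing atom")
        self._check_disjoint()

    # -- basic accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def set_group(self, name: str, indices: Iterable[int]) -> None:
        idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= len(self.atoms)):
            raise SelectionError(f"group {name!r} references missing atom indices")
        self.groups[name] = idx
        self._check_disjoint()

    def group(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise SelectionError(f"unknown group {name!r}")
        idx = self.groups[name]
        if idx.size == 0:
            raise SelectionError(f"group {name!r} is empty")
        return idx

    def _check_disjoint(self) -> None:
        if "receptor" in self.groups and "ligand" in self.groups:
            overlap = np.intersect1d(self.groups["receptor"], self.groups["ligand"])
            if overlap.size:
                raise SelectionError(
                    "'receptor' and 'ligand' groups overlap at indices "
                    f"{overlap.tolist()}"
                )

    # -- lookups ---------------------------------------------------------
    def index_of(self, residue_id: int, atom_name: str) -> int:
        """0-based index of the atom with this (residue_id, name) key."""
        for i, a in enumerate(self.atoms):
            if a.residue_id == residue_id and a.name == atom_name:
                return i
        raise SelectionError(f"no atom {atom_name!r} in residue {residue_id}")

    def residue_indices(self, residue_id: int) -> np.ndarray:
        idx = [i for i, a in enumerate(self.atoms) if a.residue_id == residue_id]
        if not idx:
            raise SelectionError(f"no residue with id {residue_id}")
        return np.asarray(idx, dtype=int)

    def residue_ids(self) -> List[int]:
        """Distinct residue ids in order of first appearance."""
        seen: Dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def water_oxygen_indices(self) -> np.ndarray:
        return np.asarray(
            [
                i
                for i, a in enumerate(self.atoms)
                if a.is_water and a.element == "O"
            ],
            dtype=int,
        )

    def bonded_hydrogens(self, index: int) -> List[int]:
        out = []
        for i, j in self.bonds:
            other = j if i == index else i if j == index else None
            if other is not None and self.atoms[other].element == "H":
                out.append(other)
        return out

    def subset(self, keep: Sequence[int]) -> Tuple["Topology", np.ndarray]:
        """New topology containing only ``keep`` (in order); also returns the
        old->new index map (-1 for dropped atoms)."""
        keep = list(keep)
        old2new = np.full(self.n_atoms, -1, dtype=int)
        for new, old in enumerate(keep):
            old2new[old] = new
        atoms = [self.atoms[i] for i in keep]
        groups = {
            name: [old2new[i] for i in idx if old2new[i] >= 0]
            for name, idx in self.groups.items()
        }
        bonds = [
            (old2new[i], old2new[j])
            for i, j in self.bonds
            if old2new[i] >= 0 and old2new[j] >= 0
        ]
        return Topology(atoms, groups, bonds), old2new


@dataclass
class Frame:
    """One snapshot: (n_atoms, 3) coordinates in Angstrom at a time in ns."""

    coordinates: np.ndarray
    time: float = 0.0
    box: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if self.time < 0:
            raise ValueError("frame time must be >= 0")


class Trajectory:
    """Time-ordered frames sharing one topology; ``run_id`` labels which of
    the independent simulation replicas the trajectory came from."""

    def __init__(self, topology: Topology, frames: Sequence[Frame], run_id: int = 0):
        self.topology = topology
        self.frames: List[Frame] = list(frames)
        self.run_id = int(run_id)
        for f in self.frames:
            if f.coordinates.shape[0] != topology.n_atoms:
                raise TopologyMismatchError(
                    f"frame has {f.coordinates.shape[0]} atoms, topology has "
                    f"{topology.n_atoms}"
                )
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.frames])

    def coordinates(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class AtomParams:
    """Per-atom nonbonded parameters."""

    charge: float          # e
    rmin_half: float       # Angstrom (LJ r_min/2)
    epsilon: float         # kcal/mol (LJ well depth)
    mass: float            # amu
    gb_radius: float       # Angstrom (intrinsic Born radius)
    gb_screen: float = 0.8  # dimensionless descreening scale


class ForceFieldParams:
    """Nonbonded parameter table keyed by (residue_name, atom_name), plus the
    global dielectric/solvation constants of the energy model.

    Atoms are matched first on the exact (residue, name) key, then on a
    wildcard ("*", name) entry.
    """

    def __init__(
        self,
        atom_table: Mapping[Tuple[str, str], AtomParams],
        eps_int: float = C.DEFAULT_EPS_INT,
        eps_solv: float = C.DEFAULT_EPS_SOLV,
        temperature: float = C.DEFAULT_TEMPERATURE,
        probe_radius: float = C.DEFAULT_PROBE_RADIUS,
        surface_tension: float = C.DEFAULT_SURFACE_TENSION,
        coulomb: float = C.COULOMB_KCAL,
        gb_alpha: float = C.GB_OBC_ALPHA,
        gb_beta: float = C.GB_OBC_BETA,
        gb_gamma: float = C.GB_OBC_GAMMA,
        gb_offset: float = C.GB_RADIUS_OFFSET,
    ):
        if eps_int < 1:
            raise ParameterError("eps_int must be >= 1")
        if eps_solv <= eps_int:
            raise ParameterError("eps_solv must exceed eps_int")
        self.atom_table: Dict[Tuple[str, str], AtomParams] = dict(atom_table)
        for key, p in self.atom_table.items():
            if p.mass <= 0:
                raise ParameterError(f"non-positive mass for {key}")
            if p.gb_radius <= 0:
                raise ParameterError(f"non-positive GB radius for {key}")
        self.eps_int = float(eps_int)
        self.eps_solv = float(eps_solv)
        self.temperature = float(temperature)
        self.probe_radius = float(probe_radius)
        self.surface_tension = float(surface_tension)
        self.coulomb = float(coulomb)
        self.gb_alpha = float(gb_alpha)
        self.gb_beta = float(gb_beta)
        self.gb_gamma = float(gb_gamma)
        self.gb_offset = float(gb_offset)

    def lookup(self, atom: Atom) -> Optional[AtomParams]:
        return self.atom_table.get(
            (atom.residue_name, atom.name), self.atom_table.get(("*", atom.name))
        )

    def arrays_for(self, topology: Topology, indices: Optional[Sequence[int]] = None):
        """Aligned parameter arrays (charge, rmin_half, epsilon, mass, radius,
        screen) for the given atoms; raises naming *all* unparameterised atoms."""
        if indices is None:
            indices = range(topology.n_atoms)
        indices = list(indices)
        missing = []
        rows = []
        for i in indices:
            a = topology.atoms[i]
            p = self.lookup(a)
            if p is None:
                missing.append(f"{a.residue_name}{a.residue_id}:{a.name}")
            else:
                rows.append(p)
        if missing:
            raise MissingParameterError(
                "no force-field parameters for atoms: " + ", ".join(missing)
            )
        return {
            "charge": np.array([p.charge for p in rows]),
            "rmin_half": np.array([p.rmin_half for p in rows]),
            "epsilon": np.array([p.epsilon for p in rows]),
            "mass": np.array([p.mass for p in rows]),
            "gb_radius": np.array([p.gb_radius for p in rows]),
            "gb_screen": np.array([p.gb_screen for p in rows]),
        }

    def with_updates(self, **kwargs) -> "ForceFieldParams":
        state = dict(
            atom_table=self.atom_table,
            eps_int=self.eps_int,
            eps_solv=self.eps_solv,
            temperature=self.temperature,
            probe_radius=self.probe_radius,
            surface_tension=self.surface_tension,
            coulomb=self.coulomb,
            gb_alpha=self.gb_alpha,
            gb_beta=self.gb_beta,
            gb_gamma=self.gb_gamma,
            gb_offset=self.gb_offset,
        )
        state.update(kwargs)
        return ForceFieldParams(**state)


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    ``distance_cutoff`` is the donor-acceptor heavy-atom distance (A),
    ``angle_cutoff`` the D-H...A angle (degrees); ``distance_only`` drops the
    angle test (used for Ca2+ coordination and hydrogen-free topologies).
    """

    distance_cutoff: float = 3.5
    angle_cutoff: float = 135.0
    stable_threshold: float = 0.5
    distance_only: bool = False

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ParameterError("distance cutoff must be > 0")
        if not (90.0 < self.angle_cutoff <= 180.0):
            raise ParameterError("angle cutoff must lie in (90, 180]")


@dataclass
class AnalysisConfig:
    """Tunable knobs of the full analysis pipeline with their defaults."""

    n_snapshots: int = 5000
    pose_stride_ns: float = 0.1
    rmsd_cutoff: float = 1.5
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    ion_distance_cutoff: float = 3.0
    voxel_cell: float = 0.5
    density_floor: float = 0.25
    entropy_windows: int = 10
    escape_threshold: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name in ("pose_stride_ns", "rmsd_cutoff", "voxel_cell", "escape_threshold"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.n_snapshots <= 0 or self.entropy_windows < 3:
            raise ParameterError("n_snapshots must be > 0, entropy_windows >= 3")


def frames_like(trajectory: Trajectory, coords: np.ndarray) -> Trajectory:
    """New trajectory with the same topology/times but replaced coordinates."""
    frames = [
        replace(f, coordinates=c) for f, c in zip(trajectory.frames, coords)
    ]
    return Trajectory(trajectory.topology, frames, trajectory.run_id)
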