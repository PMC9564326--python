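"""File I/O: PDB structures, multi-model PDB and DCD trajectories, and the
YAML force-field parameter / analysis configuration tables.

PDB ATOM/HETATM records are handled with the fixed-column format directly so
that parse failures can name the offending line and so water/ion flagging is
under the caller's control; binary DCD files go through MDAnalysis.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import (
    EmptyInputError,
    PDBParseError,
    TopologyMismatchError,
)
from .model import (
    AnalysisConfig,
    Atom,
    AtomParams,
    DEFAULT_ION_RESNAMES,
    DEFAULT_WATER_RESNAMES,
    ForceFieldParams,
    Frame,
    HBondCriteria,
    Topology,
    Trajectory,
)

__all__ = [
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "read_trajectory",
    "write_dcd",
    "load_ff_params",
    "save_ff_params",
    "load_analysis_config",
]


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in {
        "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CA",
    } and name.strip().upper() == stripped[:2].upper():
        # two-letter element only when the whole name is the element symbol
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> Tuple[Atom, np.ndarray]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip() or line[17:21].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    element = element.capitalize() if len(element) > 1 else element.upper()
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        residue_id=resid,
        residue_name=resname,
        chain=chain,
    )
    return atom, np.array([x, y, z])


def read_pdb_models(
    path,
    chain: Optional[str] = None,
    water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
    ion_resnames: Iterable[str] = DEFAULT_ION_RESNAMES,
) -> Tuple[Topology, List[Frame]]:
    """Read all MODELs of a PDB file.

    Waters and monoatomic ions are flagged by residue-name whitelist
    (configurable; PDB dialects vary). Returns the topology of the first
    model and one Frame per model. ``chain`` restricts to a single chain id.
    """
    water_resnames = {r.upper() for r in water_resnames}
    ion_resnames = {r.upper() for r in ion_resnames}
    models: List[List[np.ndarray]] = []
    atoms: List[Atom] = []
    current: List[np.ndarray] = []
    in_model = False
    first_model_done = False
    n_expected = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current:
                    models.append(current)
                current = []
                in_model = True
                first_model_done = bool(atoms)
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                first_model_done = True
            elif rec in ("ATOM", "HETATM"):
                atom, xyz = _parse_atom_line(line, lineno)
                if chain is not None and atom.chain != chain:
                    continue
                if not first_model_done:
                    resname = atom.residue_name.upper()
                    atom = Atom(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element,
                        residue_id=atom.residue_id,
                        residue_name=atom.residue_name,
                        chain=atom.chain,
                        is_water=resname in water_resnames,
                        is_ion=resname in ion_resnames,
                    )
                    atoms.append(atom)
                current.append(xyz)
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not atoms or not models:
        raise EmptyInputError(f"no ATOM/HETATM records found in {path}")
    frames = []
    n_expected = len(atoms)
    for k, coords in enumerate(models):
        if len(coords) != n_expected:
            raise TopologyMismatchError(
                f"model {k + 1} of {path} has {len(coords)} atoms, expected "
                f"{n_expected}"
            )
        frames.append(Frame(np.asarray(coords), time=float(k)))
    return Topology(atoms), frames


def read_pdb(path, chain: Optional[str] = None, infer_groups: bool = True,
             **kw) -> Tuple[Topology, Frame]:
    """Read a PDB structure; multi-model files yield the first model.

    With ``infer_groups`` the standard analysis groups (receptor, ligand,
    receptor_ca, ring_atoms, sugar moieties) are derived from residue names.
    """
    topo, frames = read_pdb_models(path, chain=chain, **kw)
    if infer_groups:
        infer_default_groups(topo)
    return topo, frames[0]


_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HID HIE HIP ILE LEU LYS MET PHE "
    "PRO SER THR TRP TYR VAL".split()
)
_RING_NAMES = frozenset({"O5", "C1", "C2", "C3", "C4", "C5"})


def infer_default_groups(topology: Topology) -> Topology:
    """Populate the standard group names from residue classification:
    protein residues -> receptor (C-alphas -> receptor_ca), sugar/sulfate
    residues -> ligand with per-moiety groups, pyranose ring atoms ->
    ring_atoms. Existing groups are kept."""
    from .conformation import FUC_NAMES, GAL_NAMES, GLCNAC_NAMES, NEU5AC_NAMES

    moiety = {}
    for names, label in ((NEU5AC_NAMES, "Neu5Ac"), (GAL_NAMES, "Gal"),
                         (GLCNAC_NAMES, "GlcNAc"), (FUC_NAMES, "Fuc")):
        for n in names:
            moiety[n] = label
    groups: Dict[str, List[int]] = {
        "receptor": [], "ligand": [], "receptor_ca": [], "ring_atoms": [],
    }
    for i, a in enumerate(topology.atoms):
        if a.is_water or a.is_ion:
            continue
        res = a.residue_name.upper()
        if res in _AMINO_ACIDS:
            groups["receptor"].append(i)
            if a.name == "CA":
                groups["receptor_ca"].append(i)
        elif res in moiety or res == "SO3":
            groups["ligand"].append(i)
            label = moiety.get(res, "SO3")
            groups.setdefault(label, []).append(i)
            if a.name in _RING_NAMES:
                groups["ring_atoms"].append(i)
    for name, idx in groups.items():
        if idx and name not in topology.groups:
            topology.set_group(name, idx)
    return topology


def write_pdb(path, topology: Topology, frames) -> None:
    """Write one Frame or a sequence of Frames as a (multi-model) PDB file."""
    if isinstance(frames, Frame):
        frames = [frames]
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for k, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {k:4d}\n")
            for i, atom in enumerate(topology.atoms):
                x, y, z = frame.coordinates[i]
                record = "HETATM" if (atom.is_water or atom.is_ion) else "ATOM  "
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"{record}{atom.serial:5d} {name:<4.4s} "
                    f"{atom.residue_name:<4.4s}{atom.chain:1.1s}"
                    f"{atom.residue_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2.2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(
    path,
    topology: Topology,
    dt_ns: float = 0.1,
    run_id: int = 0,
    chain: Optional[str] = None,
) -> Trajectory:
    """Read a multi-model PDB or binary DCD trajectory onto ``topology``.

    Times are taken as frame_index * ``dt_ns`` (trajectory formats rarely
    carry wall-clock times in units we can trust).
    """
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        coords = _read_dcd_coords(path)
    else:
        _, frames = read_pdb_models(path, chain=chain)
        coords = np.stack([f.coordinates for f in frames])
    if coords.shape[1] != topology.n_atoms:
        raise TopologyMismatchError(
            f"{path} frames have {coords.shape[1]} atoms, topology has "
            f"{topology.n_atoms}"
        )
    frames = [Frame(c, time=k * dt_ns) for k, c in enumerate(coords)]
    return Trajectory(topology, frames, run_id=run_id)


def _read_dcd_coords(path) -> np.ndarray:
    from MDAnalysis.coordinates.DCD import DCDReader

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = DCDReader(str(path))
        coords = np.stack([ts.positions.copy() for ts in reader]).astype(float)
        reader.close()
    return coords


def write_dcd(path, trajectory: Trajectory) -> None:
    """Write a trajectory's coordinates as a DCD file (test fixtures and
    interchange with standard MD tooling)."""
    import MDAnalysis
    from MDAnalysis.coordinates.DCD import DCDWriter

    n = trajectory.topology.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = MDAnalysis.Universe.empty(n, trajectory=True)
        with DCDWriter(str(path), n_atoms=n) as w:
            for frame in trajectory.frames:
                u.atoms.positions = np.asarray(frame.coordinates, dtype=np.float32)
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Parameter tables and configuration
# ---------------------------------------------------------------------------

_GLOBAL_KEYS = (
    "eps_int",
    "eps_solv",
    "temperature",
    "probe_radius",
    "surface_tension",
    "coulomb",
    "gb_alpha",
    "gb_beta",
    "gb_gamma",
    "gb_offset",
)


def load_ff_params(path) -> ForceFieldParams:
    """Load a YAML force-field parameter table.

    Layout::

        globals: {eps_int: 3.0, eps_solv: 78.5, temperature: 300.0}
        atoms:
          - {residue: GAL, name: C1, charge: 0.3, rmin_half: 1.9,
             epsilon: 0.1094, mass: 12.011, gb_radius: 1.7, gb_screen: 0.72}

    Unstated globals fall back to the package defaults (eps_int 3.0,
    eps_solv 78.5, T 300 K, probe 1.4 A).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not doc or "atoms" not in doc:
        raise EmptyInputError(f"no 'atoms' table in parameter file {path}")
    table = {}
    for row in doc["atoms"]:
        missing = [k for k in ("residue", "name", "charge", "rmin_half",
                               "epsilon", "mass", "gb_radius") if k not in row]
        if missing:
            raise _missing_param_error(row, missing)
        key = (str(row["residue"]), str(row["name"]))
        table[key] = AtomParams(
            charge=float(row["charge"]),
            rmin_half=float(row["rmin_half"]),
            epsilon=float(row["epsilon"]),
            mass=float(row["mass"]),
            gb_radius=float(row["gb_radius"]),
            gb_screen=float(row.get("gb_screen", 0.8)),
        )
    globals_ = {k: float(v) for k, v in (doc.get("globals") or {}).items()
                if k in _GLOBAL_KEYS}
    return ForceFieldParams(table, **globals_)


def _missing_param_error(row, missing):
    from .errors import MissingParameterError

    ident = f"{row.get('residue', '?')}:{row.get('name', '?')}"
    return MissingParameterError(
        f"atom {ident} is missing parameter field(s): {', '.join(missing)}"
    )


def save_ff_params(path, params: ForceFieldParams) -> None:
    doc = {
        "globals": {k: getattr(params, k) for k in _GLOBAL_KEYS},
        "atoms": [
            {
                "residue": res,
                "name": name,
                "charge": p.charge,
                "rmin_half": p.rmin_half,
                "epsilon": p.epsilon,
                "mass": p.mass,
                "gb_radius": p.gb_radius,
                "gb_screen": p.gb_screen,
            }
            for (res, name), p in params.atom_table.items()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_analysis_config(path) -> AnalysisConfig:
    """Load AnalysisConfig from YAML; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    hb = doc.pop("hbond", None)
    cfg = AnalysisConfig(**doc) if doc else AnalysisConfig()
    if hb:
        cfg.hbond = HBondCriteria(**hb)
    return cfg
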