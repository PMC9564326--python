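"""Synthetic topologies and trajectories with known ground truth.

Three generators cover the statistical structures the analysis stages rely
on:

* a harmonic bath - independent Gaussian fluctuations per coordinate, whose
  mass-weighted covariance (hence quasiharmonic entropy) is known in closed
  form;
* Gaussian torsion ensembles with a prescribed mean and covariance, the
  exact oracle for Karplus-Kushick entropies;
* a toy receptor-glycan complex emulating the behaviours of real bound,
  multi-pose and unbound simulations: a tetrasaccharide-like ligand
  (Neu5Ac-Gal-GlcNAc core with a branch fucose and a 6'-sulfate), a small
  receptor with a planted salt bridge and hydrogen-bond donors, a Ca2+ ion
  and an optional Ca2+ - water - sulfate bridge geometry.

Coordinate noise is Gaussian (not Boltzmann-from-force-field): closed-form
covariances give exact oracles. Pose switching is block-wise (contiguous
dwells), mimicking MD autocorrelation rather than i.i.d. frame labels.
All generators are deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import GeometryError, SpecError
from .model import (
    AnalysisConfig,
    Atom,
    AtomParams,
    ForceFieldParams,
    Frame,
    Topology,
    Trajectory,
)

__all__ = [
    "HarmonicBathSpec",
    "TorsionEnsembleSpec",
    "ToyComplexSpec",
    "BridgeSpec",
    "HBondPlant",
    "gen_harmonic_trajectory",
    "gen_torsion_ensemble",
    "gen_toy_complex",
    "gen_toy_runs",
    "toy_force_field",
]

_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "S": 32.06, "Ca": 40.078}
_ELEMENT_RMIN = {"H": 0.6, "C": 1.908, "N": 1.824, "O": 1.661,
                 "S": 2.0, "Ca": 1.7}
_ELEMENT_EPS = {"H": 0.0157, "C": 0.1094, "N": 0.17, "O": 0.21,
                "S": 0.25, "Ca": 0.45}
_ELEMENT_GBR = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.5, "S": 1.8, "Ca": 1.7}


# ---------------------------------------------------------------------------
# Harmonic bath
# ---------------------------------------------------------------------------


@dataclass
class HarmonicBathSpec:
    """Independent Gaussian fluctuations: atom i, coordinate a ~
    N(mean, sigma_ia^2); the mass-weighted covariance is diagonal with
    entries m_i sigma_ia^2."""

    masses: Sequence[float]          # amu, one per atom
    sigmas: Sequence[float]          # A; scalar-per-atom or (n_atoms, 3)
    n_frames: int = 1000
    seed: int = 0
    dt_ns: float = 0.01
    spacing: float = 8.0             # A between atom rest positions

    def sigma_matrix(self) -> np.ndarray:
        s = np.asarray(self.sigmas, dtype=float)
        n = len(self.masses)
        if s.ndim == 1:
            s = np.repeat(s[:, None], 3, axis=1)
        if s.shape != (n, 3):
            raise SpecError("sigmas must be per-atom scalars or (n_atoms, 3)")
        if np.any(s <= 0):
            raise SpecError("fluctuation SDs must be > 0")
        return s


def gen_harmonic_trajectory(spec: HarmonicBathSpec) -> Trajectory:
    """Trajectory whose coordinates are independent Gaussians about fixed
    rest positions; reproducible under the spec seed."""
    sig = spec.sigma_matrix()
    n = len(spec.masses)
    if any(m <= 0 for m in spec.masses):
        raise SpecError("masses must be > 0")
    rng = np.random.default_rng(spec.seed)
    means = np.zeros((n, 3))
    means[:, 0] = np.arange(n) * spec.spacing
    atoms = [
        Atom(serial=i + 1, name="C", element="C", residue_id=i + 1,
             residue_name="BTH")
        for i in range(n)
    ]
    topo = Topology(atoms, groups={"all": list(range(n))})
    noise = rng.standard_normal((spec.n_frames, n, 3)) * sig
    frames = [
        Frame(means + noise[k], time=k * spec.dt_ns)
        for k in range(spec.n_frames)
    ]
    return Trajectory(topo, frames)


# ---------------------------------------------------------------------------
# Torsion ensembles
# ---------------------------------------------------------------------------


@dataclass
class TorsionEnsembleSpec:
    """Multivariate Gaussian torsion ensemble (degrees), wrapped to
    (-180, 180]."""

    mean: Sequence[float]
    cov: Sequence[Sequence[float]]   # degrees^2
    n_samples: int = 10000
    seed: int = 0


def gen_torsion_ensemble(spec: TorsionEnsembleSpec) -> np.ndarray:
    """(n_samples, n_torsions) array of wrapped torsion samples."""
    mean = np.asarray(spec.mean, dtype=float)
    cov = np.atleast_2d(np.asarray(spec.cov, dtype=float))
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise SpecError("torsion covariance must be symmetric positive-definite")
    rng = np.random.default_rng(spec.seed)
    samples = rng.multivariate_normal(mean, cov, size=spec.n_samples,
                                      method="cholesky")
    return (samples + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# Toy receptor-glycan complex
# ---------------------------------------------------------------------------


@dataclass
class BridgeSpec:
    """Plant a Ca2+ - water - sulfate-oxygen bridge at stated distances."""

    ca_water_dist: float = 2.0
    water_so3_dist: float = 3.0
    jitter_sd: float = 0.03


@dataclass
class HBondPlant:
    """Plant a receptor-donor -> ligand-acceptor hydrogen bond satisfied in
    a known fraction of frames."""

    acceptor: Tuple[int, str]        # (ligand residue id, atom name)
    distance: float = 2.8
    fraction: float = 1.0


@dataclass
class ToyComplexSpec:
    """Layout and dynamics of the synthetic receptor-glycan complex."""

    mode: str = "stable"             # stable | multi-pose | diffusing
    n_frames: int = 200
    dt_ns: float = 0.1
    seed: int = 0
    noise_sd: float = 0.2            # A, ligand thermal jitter
    receptor_noise_sd: float = 0.05
    pose_offsets: Sequence[Sequence[float]] = (
        (0.0, 0.0, 0.0), (3.5, 0.0, 1.5), (-2.0, 3.0, -1.0),
    )
    dwell_fractions: Sequence[float] = (0.5, 0.3, 0.2)
    escape_distance: float = 14.0    # A travelled by the final diffusing frame
    hbond_plants: Optional[Sequence[HBondPlant]] = None
    bridge: Optional[BridgeSpec] = None
    n_bulk_waters: int = 4
    with_sulfate: bool = True

    def __post_init__(self):
        if self.mode not in ("stable", "multi-pose", "diffusing"):
            raise SpecError(f"unknown mode {self.mode!r}")
        if self.noise_sd <= 0 or self.n_frames < 2:
            raise SpecError("noise_sd must be > 0 and n_frames >= 2")
        if self.mode == "multi-pose":
            f = np.asarray(self.dwell_fractions, dtype=float)
            if len(f) != len(self.pose_offsets) or abs(f.sum() - 1) > 1e-9:
                raise SpecError("dwell fractions must match poses and sum to 1")


# residue ids used by the builder
RES_SIA, RES_GAL, RES_NAG, RES_FUC, RES_SO3 = 1, 2, 3, 4, 5
_RES_SER, _RES_ARG, _RES_GLU = 11, 12, 13


def _hexagon(center, radius=1.45, tilt=0.25):
    """Six ring positions (O5,C1..C5 order) with alternating z-displacement
    so the ring has a definite chair pucker."""
    ang = np.arange(6) * np.pi / 3.0
    pts = np.column_stack([
        center[0] + radius * np.cos(ang),
        center[1] + radius * np.sin(ang),
        center[2] + tilt * (-1.0) ** np.arange(6),
    ])
    return pts


def _build_layout(spec: ToyComplexSpec):
    """Base (frame-0) coordinates, atoms, bonds and groups."""
    atoms: List[Atom] = []
    coords: List[np.ndarray] = []
    bonds: List[Tuple[int, int]] = []
    groups: Dict[str, List[int]] = {
        "receptor": [], "ligand": [], "ring_atoms": [], "receptor_ca": [],
        "Neu5Ac": [], "Gal": [], "GlcNAc": [], "Fuc": [], "SO3": [],
        "glycosidic": [],
    }
    serial = [0]

    def add(name, element, resid, resname, xyz, water=False, ion=False):
        serial[0] += 1
        atoms.append(Atom(serial=serial[0], name=name, element=element,
                          residue_id=resid, residue_name=resname,
                          is_water=water, is_ion=ion))
        coords.append(np.asarray(xyz, dtype=float))
        return len(atoms) - 1

    ring_names = ["O5", "C1", "C2", "C3", "C4", "C5"]
    sugar_layout = [
        (RES_NAG, "NAG", np.array([0.0, 0.0, 0.0]), "GlcNAc"),
        (RES_GAL, "GAL", np.array([4.2, 0.0, 0.0]), "Gal"),
        (RES_SIA, "SIA", np.array([8.4, 0.0, 0.0]), "Neu5Ac"),
        (RES_FUC, "FUC", np.array([0.0, 4.2, 0.0]), "Fuc"),
    ]
    ring_index: Dict[Tuple[int, str], int] = {}
    for resid, resname, center, gname in sugar_layout:
        pts = _hexagon(center)
        first = None
        for name, xyz in zip(ring_names, pts):
            k = add(name, name[0], resid, resname, xyz)
            ring_index[(resid, name)] = k
            groups["ligand"].append(k)
            groups["ring_atoms"].append(k)
            groups[gname].append(k)
            if first is None:
                first = k
        # ring bonds O5-C1-...-C5-O5
        for a in range(6):
            bonds.append((first + a, first + (a + 1) % 6))

    centers = {resid: center for resid, _, center, _ in sugar_layout}

    def add_exocyclic(resid, resname, gname, name, anchor, z_off=0.4, dist=1.4):
        """Exocyclic oxygen pointing radially outward from the ring center
        (with a z tilt), so it cannot clash with neighbouring ring atoms."""
        base = coords[ring_index[(resid, anchor)]]
        radial = base - centers[resid]
        radial[2] = 0.0
        direction = radial / np.linalg.norm(radial) + np.array([0.0, 0.0, z_off])
        direction /= np.linalg.norm(direction)
        k = add(name, "O", resid, resname, base + dist * direction)
        bonds.append((ring_index[(resid, anchor)], k))
        groups["ligand"].append(k)
        groups[gname].append(k)
        return k

    # exocyclic oxygens used by linkages, H-bond targets and the sulfate
    o4_nag = add_exocyclic(RES_NAG, "NAG", "GlcNAc", "O4", "C4", z_off=0.4)
    o3_nag = add_exocyclic(RES_NAG, "NAG", "GlcNAc", "O3", "C3", z_off=-0.4)
    o3_gal = add_exocyclic(RES_GAL, "GAL", "Gal", "O3", "C3", z_off=-0.4)
    o4_gal = add_exocyclic(RES_GAL, "GAL", "Gal", "O4", "C4", z_off=0.4)
    o6_gal = add_exocyclic(RES_GAL, "GAL", "Gal", "O6", "C5", z_off=0.6)
    o2_fuc = add_exocyclic(RES_FUC, "FUC", "Fuc", "O2", "C2", z_off=0.4)

    # glycosidic bonds: Gal(1-4)GlcNAc, Neu5Ac(2-3)Gal, Fuc(1-3)GlcNAc
    bonds.append((ring_index[(RES_GAL, "C1")], o4_nag))
    bonds.append((ring_index[(RES_SIA, "C2")], o3_gal))
    bonds.append((ring_index[(RES_FUC, "C1")], o3_nag))
    groups["glycosidic"].extend([o4_nag, o3_gal, o3_nag])

    # sulfate on Gal O6, extending radially away from both rings
    so3_oxygens = []
    if spec.with_sulfate:
        o6 = coords[o6_gal]
        out = o6 - coords[ring_index[(RES_GAL, "C5")]]
        out = out / np.linalg.norm(out)
        s = add("S", "S", RES_SO3, "SO3", o6 + 1.6 * out)
        bonds.append((o6_gal, s))
        groups["ligand"].append(s)
        groups["SO3"].append(s)
        for i, d in enumerate(
            [np.array([1.2, -0.8, 0.0]), np.array([-1.2, -0.8, 0.0]),
             np.array([0.0, -0.8, 1.2])]
        ):
            o = add(f"O{i + 1}S", "O", RES_SO3, "SO3", coords[s] + d)
            bonds.append((s, o))
            groups["ligand"].append(o)
            groups["SO3"].append(o)
            so3_oxygens.append(o)

    # --- receptor ------------------------------------------------------
    def add_residue(resid, resname, anchor_xyz, away):
        """Five-atom residue (N, CA, C, O, CB) marching away from the
        binding site, plus a returned CB index for side-chain extension."""
        away = np.asarray(away, dtype=float)
        away = away / np.linalg.norm(away)
        cb = add("CB", "C", resid, resname, anchor_xyz)
        ca = add("CA", "C", resid, resname, anchor_xyz + 1.5 * away)
        n = add("N", "N", resid, resname, coords[ca] + np.array([1.2, 0.6, 0.0]))
        c = add("C", "C", resid, resname, coords[ca] + np.array([-1.2, 0.7, 0.2]))
        o = add("O", "O", resid, resname, coords[c] + np.array([-0.4, 1.1, 0.0]))
        for idx in (cb, ca, n, c, o):
            groups["receptor"].append(idx)
        groups["receptor_ca"].append(ca)
        bonds.extend([(n, ca), (ca, c), (c, o), (ca, cb)])
        return cb

    # SER donor: OG-HG hydrogen-bonding toward Gal O4
    acc0 = coords[o4_gal]
    ser_dir = np.array([-0.51, -0.86, 0.0])
    ser_dir = ser_dir / np.linalg.norm(ser_dir)
    og_pos = acc0 + 2.8 * ser_dir
    ser_cb = add_residue(_RES_SER, "SER", og_pos + 1.4 * ser_dir, ser_dir)
    og = add("OG", "O", _RES_SER, "SER", og_pos)
    hg = add("HG", "H", _RES_SER, "SER", og_pos - 1.0 * ser_dir)
    bonds.extend([(ser_cb, og), (og, hg)])
    groups["receptor"].extend([og, hg])

    # ARG guanidinium carbon: salt bridge to the sulfate (or to Gal O6)
    target = coords[so3_oxygens[0]] if so3_oxygens else coords[o6_gal]
    arg_dir = np.array([0.5, -1.0, 0.5]) / np.linalg.norm([0.5, -1.0, 0.5])
    cz_pos = target + 3.2 * arg_dir
    arg_cb = add_residue(_RES_ARG, "ARG", cz_pos + 1.5 * arg_dir, arg_dir)
    cz = add("CZ", "C", _RES_ARG, "ARG", cz_pos)
    nh1 = add("NH1", "N", _RES_ARG, "ARG", cz_pos + np.array([1.1, -0.6, 0.0]))
    bonds.extend([(arg_cb, cz), (cz, nh1)])
    groups["receptor"].extend([cz, nh1])

    # GLU: inert third residue flanking the GlcNAc, placed to keep the
    # C-alpha fit triangle well-conditioned
    glu_cb = add_residue(_RES_GLU, "GLU", np.array([-5.0, -1.0, -2.0]),
                         [-0.5, -1.0, -0.3])
    oe1 = add("OE1", "O", _RES_GLU, "GLU", coords[glu_cb] + np.array([0.8, -1.1, 0.0]))
    bonds.append((glu_cb, oe1))
    groups["receptor"].append(oe1)

    # --- ion, bridge water, bulk waters --------------------------------
    ion = None
    bridge_water_o = None
    if spec.bridge is not None:
        target = coords[so3_oxygens[-1]] if so3_oxygens else coords[o6_gal]
        d = np.array([0.0, -0.5, 1.0])
        d = d / np.linalg.norm(d)
        w_pos = target + spec.bridge.water_so3_dist * d
        ca_pos = w_pos + spec.bridge.ca_water_dist * d
        ion = add("CA", "Ca", 50, "CA", ca_pos, ion=True)
        groups["Ca2+"] = [ion]
        bridge_water_o = add("O", "O", 60, "HOH", w_pos, water=True)
        h1 = add("H1", "H", 60, "HOH", w_pos + np.array([0.76, 0.59, 0.0]),
                 water=True)
        h2 = add("H2", "H", 60, "HOH", w_pos + np.array([-0.76, 0.59, 0.0]),
                 water=True)
        bonds.extend([(bridge_water_o, h1), (bridge_water_o, h2)])
    else:
        ion = add("CA", "Ca", 50, "CA", np.array([-2.5, 6.5, 1.0]), ion=True)
        groups["Ca2+"] = [ion]

    rng = np.random.default_rng(spec.seed + 777)
    for w in range(spec.n_bulk_waters):
        pos = np.array([14.0, 10.0, 8.0]) + rng.uniform(-1, 1, 3) + w * np.array(
            [5.0, 3.0, -2.0]
        )
        o = add("O", "O", 61 + w, "HOH", pos, water=True)
        add("H1", "H", 61 + w, "HOH", pos + np.array([0.76, 0.59, 0.0]), water=True)
        add("H2", "H", 61 + w, "HOH", pos + np.array([-0.76, 0.59, 0.0]), water=True)

    base = np.asarray(coords)
    dmat = np.linalg.norm(base[:, None] - base[None, :], axis=-1)
    np.fill_diagonal(dmat, np.inf)
    if dmat.min() < 0.5:
        i, j = np.unravel_index(np.argmin(dmat), dmat.shape)
        raise GeometryError(
            f"layout places atoms {i} and {j} within {dmat.min():.2f} A"
        )
    topo = Topology(atoms, groups={k: v for k, v in groups.items() if v}, bonds=bonds)
    extras = {
        "bridge_water_o": bridge_water_o,
        "ion": ion,
        "so3_oxygens": so3_oxygens,
        "hbond_og": og,
        "hbond_hg": hg,
        "donor_dir": ser_dir,
        "acceptors": {"O4_GAL": o4_gal, "O3_NAG": o3_nag, "O2_FUC": o2_fuc},
    }
    return topo, base, extras


def _dwell_blocks(n_frames: int, fractions: Sequence[float]) -> np.ndarray:
    """Contiguous pose labels with block lengths proportional to the dwell
    fractions (largest-remainder rounding so lengths sum to n_frames)."""
    f = np.asarray(fractions, dtype=float)
    raw = f * n_frames
    lengths = np.floor(raw).astype(int)
    rem = n_frames - lengths.sum()
    order = np.argsort(-(raw - lengths))
    lengths[order[:rem]] += 1
    return np.repeat(np.arange(len(f)), lengths)


def gen_toy_complex(spec: ToyComplexSpec, run_id: int = 0) -> Tuple[
        Trajectory, ForceFieldParams, Dict]:
    """Generate one run of the toy complex.

    Returns (trajectory, force-field params, extras) where extras carries
    planted ground truth: pose labels, H-bond on/off masks, the bridge site
    position and key atom indices.
    """
    topo, base, extras = _build_layout(spec)
    rng = np.random.default_rng((spec.seed, run_id))
    lig = topo.groups["ligand"]
    rec = topo.groups["receptor"]
    n = topo.n_atoms
    lig_center = base[lig].mean(axis=0)

    pose_labels = None
    if spec.mode == "multi-pose":
        pose_labels = _dwell_blocks(spec.n_frames, spec.dwell_fractions)
        offsets = np.asarray(spec.pose_offsets, dtype=float)

    hb_masks = {}
    if spec.hbond_plants:
        for plant in spec.hbond_plants:
            n_on = int(round(plant.fraction * spec.n_frames))
            on = np.zeros(spec.n_frames, dtype=bool)
            on[rng.choice(spec.n_frames, size=n_on, replace=False)] = True
            hb_masks[plant.acceptor] = (plant, on)

    frames = []
    for k in range(spec.n_frames):
        c = base.copy()
        c[lig] += rng.standard_normal((len(lig), 3)) * spec.noise_sd
        c[rec] += rng.standard_normal((len(rec), 3)) * spec.receptor_noise_sd
        wat = [i for i, a in enumerate(topo.atoms) if a.is_water]
        c[wat] += rng.standard_normal((len(wat), 3)) * (
            spec.bridge.jitter_sd if spec.bridge else 0.05
        )
        if spec.mode == "multi-pose":
            c[lig] += offsets[pose_labels[k]]
        elif spec.mode == "diffusing":
            t = k / (spec.n_frames - 1)
            c[lig] += np.array([0.0, 0.0, spec.escape_distance]) * t
        # planted H-bonds: reposition the SER hydroxyl relative to the
        # (possibly moved) acceptor, on-frames at the planted distance
        for (resid, aname), (plant, on) in hb_masks.items():
            acc = c[topo.index_of(resid, aname)]
            d = extras["donor_dir"]
            dist = plant.distance if on[k] else plant.distance + 2.5
            og_i, hg_i = extras["hbond_og"], extras["hbond_hg"]
            c[og_i] = acc + dist * d
            c[hg_i] = acc + (dist - 1.0) * d
        frames.append(Frame(c, time=k * spec.dt_ns))

    params = toy_force_field(topo)
    extras.update({"pose_labels": pose_labels, "hb_masks": hb_masks,
                   "base": base})
    if extras["bridge_water_o"] is not None:
        extras["bridge_site"] = base[extras["bridge_water_o"]]
    return Trajectory(topo, frames, run_id=run_id), params, extras


def gen_toy_runs(spec: ToyComplexSpec, n_runs: int = 3):
    """Independent replicate runs (run_id 0..n_runs-1) sharing one layout."""
    trajs = []
    params = extras = None
    for r in range(n_runs):
        t, params, extras = gen_toy_complex(spec, run_id=r)
        trajs.append(t)
    return trajs, params, extras


def toy_force_field(topology: Topology) -> ForceFieldParams:
    """Element-typed parameter table for the toy complex.

    Planted charges: ARG CZ +1 against SO3 oxygens (-0.5 each, S +0.5) form
    the salt bridge probed by the alanine scan; everything else is neutral.
    """
    table: Dict[Tuple[str, str], AtomParams] = {}
    for a in topology.atoms:
        el = a.element if a.element in _ELEMENT_MASS else "C"
        charge = 0.0
        if a.residue_name == "ARG" and a.name == "CZ":
            charge = 1.0
        elif a.residue_name == "SO3":
            charge = 0.5 if a.name == "S" else -0.5
        elif a.residue_name == "CA" and a.is_ion:
            charge = 2.0
        elif a.is_water:
            charge = -0.834 if el == "O" else 0.417
        table[(a.residue_name, a.name)] = AtomParams(
            charge=charge,
            rmin_half=_ELEMENT_RMIN[el],
            epsilon=_ELEMENT_EPS[el],
            mass=_ELEMENT_MASS[el],
            gb_radius=_ELEMENT_GBR[el],
            gb_screen=0.8,
        )
    # alanine templates so alanine-truncated mutants stay parameterised
    for name in ("N", "CA", "C", "O", "CB"):
        el = name[0] if name[0] in _ELEMENT_MASS else "C"
        table.setdefault(("ALA", name), AtomParams(
            charge=0.0, rmin_half=_ELEMENT_RMIN[el], epsilon=_ELEMENT_EPS[el],
            mass=_ELEMENT_MASS[el], gb_radius=_ELEMENT_GBR[el], gb_screen=0.8,
        ))
    return ForceFieldParams(table)


def save_complex_bundle(outdir, trajs, params, topology=None) -> Dict[str, str]:
    """Write a generated complex as multi-model PDB + per-run DCD + params
    YAML so the file-based pipeline can consume it unchanged."""
    from .io import save_ff_params, write_dcd, write_pdb

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if topology is None:
        topology = trajs[0].topology
    paths = {}
    top_path = outdir / "complex.pdb"
    write_pdb(top_path, topology, trajs[0].frames[0])
    paths["topology"] = str(top_path)
    for traj in trajs:
        p = outdir / f"run{traj.run_id}.dcd"
        write_dcd(p, traj)
        paths[f"run{traj.run_id}"] = str(p)
    pp = outdir / "params.yaml"
    save_ff_params(pp, params)
    paths["params"] = str(pp)
    return paths
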