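"""Glycosidic torsions, linkage assignment, CHI strain-energy scoring and
Cremer-Pople ring puckering.

Torsion conventions for a glycosidic linkage donor(1-x)acceptor:

* phi = C2-C1-Ox-Cx, psi = C1-Ox-Cx-C(x-1)
* for a sialic-acid (Neu5Ac) donor: phi = C3-C2-Ox-Cx, psi = C2-Ox-Cx-C(x-1)

CHI (carbohydrate intrinsic) energies score how far a linkage's torsions
have strayed from their relaxed one-dimensional energy curves. Two special
rules apply to the sialylated Lewis ligands analysed here: the
Neu5Ac(a2-3)Gal linkage is excluded from CHI totals, and the Fuc(a1-3)GlcNAc
linkage is scored on the mirror image of the curves, (phi, psi) ->
(-phi, -psi) - the enantiomeric relation between alpha-L-fucose and the
beta-D template sugars the curves were derived for.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import GeometryError, ParameterError, SelectionError
from .model import Frame, Topology, Trajectory

__all__ = [
    "GlycosidicLinkage",
    "ChiCurve",
    "ChiCurveRegistry",
    "PuckerState",
    "torsion_angle",
    "assign_glycosidic_linkages",
    "chi_energy",
    "total_chi_series",
    "ring_pucker",
]

# residue-name synonym sets (PDB/GLYCAM dialects), configurable per call
NEU5AC_NAMES = frozenset({"SIA", "SLB", "NEU", "NAN", "NEU5AC"})
FUC_NAMES = frozenset({"FUC", "FUA", "0FA"})
GAL_NAMES = frozenset({"GAL", "GLA", "0LB", "GL6"})
GLCNAC_NAMES = frozenset({"NAG", "NDG", "4YB", "GLCNAC"})


def torsion_angle(frame: Frame, quadruple: Sequence[int]) -> float:
    """Signed dihedral (degrees, right-handed, in (-180, 180]) over four
    atom indices."""
    if len(set(quadruple)) != 4:
        raise SelectionError("torsion requires 4 distinct atoms")
    p = frame.coordinates[list(quadruple)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear atom triple; dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = -float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


@dataclass
class GlycosidicLinkage:
    """One inter-residue glycosidic bond and its torsion atom quadruples."""

    donor_residue: int
    acceptor_residue: int
    donor_name: str
    acceptor_name: str
    label: str                      # e.g. "Fuc1-3GlcNAc"
    phi_quad: Tuple[int, int, int, int]
    psi_quad: Tuple[int, int, int, int]
    excluded_from_chi: bool = False
    mirror: bool = False


def _find(topology: Topology, resid: int, name: str, context: str) -> int:
    try:
        return topology.index_of(resid, name)
    except SelectionError:
        raise SelectionError(
            f"cannot build {context}: residue {resid} has no atom {name!r}"
        )


def assign_glycosidic_linkages(
    topology: Topology,
    frame: Optional[Frame] = None,
    bond_cutoff: float = 1.8,
    neu5ac_names: Iterable[str] = NEU5AC_NAMES,
    fuc_names: Iterable[str] = FUC_NAMES,
    gal_names: Iterable[str] = GAL_NAMES,
    glcnac_names: Iterable[str] = GLCNAC_NAMES,
) -> List[GlycosidicLinkage]:
    """Identify glycosidic linkages and emit their phi/psi quadruples.

    Linkages are located from topology bonds when present, otherwise from
    anomeric-carbon-to-Ox distances in ``frame`` (< ``bond_cutoff`` A). The
    Neu5Ac donor rule, the Neu5Ac(a2-3)Gal CHI exclusion and the
    Fuc(a1-3)GlcNAc mirror flag are applied from the residue names.
    """
    neu5ac = {n.upper() for n in neu5ac_names}
    fuc = {n.upper() for n in fuc_names}
    gal = {n.upper() for n in gal_names}
    glcnac = {n.upper() for n in glcnac_names}

    resname = {}
    for a in topology.atoms:
        resname.setdefault(a.residue_id, a.residue_name.upper())
    sugar_res = [
        r for r, n in resname.items()
        if n in neu5ac | fuc | gal | glcnac or _has_ring_atoms(topology, r)
    ]

    pairs = set()  # (donor_anomeric_index, acceptor_Ox_index)
    if topology.bonds:
        for i, j in topology.bonds:
            ai, aj = topology.atoms[i], topology.atoms[j]
            if ai.residue_id == aj.residue_id:
                continue
            for c_idx, o_idx in ((i, j), (j, i)):
                c, o = topology.atoms[c_idx], topology.atoms[o_idx]
                if c.element == "C" and o.element == "O" and _is_anomeric(c, resname, neu5ac):
                    pairs.add((c_idx, o_idx))
    elif frame is not None:
        for r in sugar_res:
            anomeric = "C2" if resname[r] in neu5ac else "C1"
            try:
                c_idx = topology.index_of(r, anomeric)
            except SelectionError:
                continue
            for o_idx, a in enumerate(topology.atoms):
                if (
                    a.residue_id != r
                    and a.element == "O"
                    and a.name.startswith("O")
                    and a.residue_id in sugar_res
                ):
                    d = np.linalg.norm(
                        frame.coordinates[c_idx] - frame.coordinates[o_idx]
                    )
                    if d < bond_cutoff:
                        pairs.add((c_idx, o_idx))
    else:
        raise SelectionError(
            "topology has no bonds; supply a frame for distance-based linkage detection"
        )

    linkages = []
    for c_idx, o_idx in sorted(pairs):
        c, o = topology.atoms[c_idx], topology.atoms[o_idx]
        donor, acceptor = c.residue_id, o.residue_id
        dname, aname = resname[donor], resname[acceptor]
        is_neu = dname in neu5ac
        x = _ox_number(o.name, acceptor)
        ctx = f"linkage {dname}{donor}-{aname}{acceptor}"
        cx = _find(topology, acceptor, f"C{x}", ctx)
        cx1 = _find(topology, acceptor, f"C{x - 1}" if x > 1 else "C2", ctx)
        if is_neu:
            phi = (_find(topology, donor, "C3", ctx), _find(topology, donor, "C2", ctx),
                   o_idx, cx)
            psi = (_find(topology, donor, "C2", ctx), o_idx, cx, cx1)
            link_pos = f"2-{x}"
        else:
            phi = (_find(topology, donor, "C2", ctx), _find(topology, donor, "C1", ctx),
                   o_idx, cx)
            psi = (_find(topology, donor, "C1", ctx), o_idx, cx, cx1)
            link_pos = f"1-{x}"
        label = f"{_pretty(dname, neu5ac, fuc, gal, glcnac)}{link_pos}" \
                f"{_pretty(aname, neu5ac, fuc, gal, glcnac)}"
        linkages.append(
            GlycosidicLinkage(
                donor_residue=donor,
                acceptor_residue=acceptor,
                donor_name=dname,
                acceptor_name=aname,
                label=label,
                phi_quad=phi,
                psi_quad=psi,
                excluded_from_chi=(is_neu and aname in gal and x == 3),
                mirror=(dname in fuc and aname in glcnac and x == 3),
            )
        )
    return linkages


def _has_ring_atoms(topology: Topology, resid: int) -> bool:
    names = {a.name for a in topology.atoms if a.residue_id == resid}
    return {"C1", "C2", "C3", "C4", "C5", "O5"} <= names or \
        {"C2", "C3", "C4", "C5", "C6", "O6"} <= names


def _is_anomeric(atom, resname, neu5ac) -> bool:
    want = "C2" if resname[atom.residue_id] in neu5ac else "C1"
    return atom.name == want


def _ox_number(name: str, resid: int) -> int:
    digits = "".join(ch for ch in name if ch.isdigit())
    if not digits:
        raise SelectionError(
            f"glycosidic oxygen {name!r} in residue {resid} has no position number"
        )
    return int(digits)


def _pretty(resname, neu5ac, fuc, gal, glcnac) -> str:
    if resname in neu5ac:
        return "Neu5Ac"
    if resname in fuc:
        return "Fuc"
    if resname in gal:
        return "Gal"
    if resname in glcnac:
        return "GlcNAc"
    return resname.capitalize()


# ---------------------------------------------------------------------------
# CHI curves
# ---------------------------------------------------------------------------


@dataclass
class ChiCurve:
    """One-dimensional periodic strain curve on a (-180, 180] degree grid.

    Curves are relative energies: the grid minimum is shifted to zero on
    construction. Evaluation uses periodic linear interpolation (exact at
    nodes, no overshoot).
    """

    angles: np.ndarray
    energies: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        if a.shape != e.shape or a.ndim != 1 or a.size < 2:
            raise ParameterError("curve needs matching 1-D angle/energy grids")
        order = np.argsort(a)
        self.angles = a[order]
        self.energies = e[order] - e.min()
        if self.angles[0] < -180.0 or self.angles[-1] > 180.0:
            raise ParameterError("grid angles must lie in [-180, 180]")

    def __call__(self, angle) -> np.ndarray:
        ang = np.asarray(angle, dtype=float)
        wrapped = ((ang - self.angles[0]) % 360.0) + self.angles[0]
        # periodic closure: append first node at +360
        xs = np.concatenate([self.angles, [self.angles[0] + 360.0]])
        ys = np.concatenate([self.energies, [self.energies[0]]])
        return np.interp(wrapped, xs, ys)


class ChiCurveRegistry:
    """Maps (linkage_class, torsion_name) -> ChiCurve.

    ``linkage_class`` is the linkage label without residue instance numbers
    (e.g. ``"Gal1-4GlcNAc"``); ``torsion_name`` is ``"phi"`` or ``"psi"``.
    Curves can be loaded from a directory of CSV files named
    ``<linkage_class>__<torsion>.csv`` with columns angle,energy.
    """

    def __init__(self, curves: Optional[Dict[Tuple[str, str], ChiCurve]] = None):
        self.curves = dict(curves or {})

    def add(self, linkage_class: str, torsion: str, curve: ChiCurve) -> None:
        self.curves[(linkage_class, torsion)] = curve

    def get(self, linkage_class: str, torsion: str) -> ChiCurve:
        try:
            return self.curves[(linkage_class, torsion)]
        except KeyError:
            raise ParameterError(
                f"no CHI curve registered for {linkage_class!r}/{torsion}"
            )

    @classmethod
    def from_dir(cls, path) -> "ChiCurveRegistry":
        reg = cls()
        for f in sorted(Path(path).glob("*.csv")):
            stem = f.stem
            if "__" not in stem:
                continue
            linkage_class, torsion = stem.rsplit("__", 1)
            data = np.loadtxt(f, delimiter=",", skiprows=1, ndmin=2)
            reg.add(linkage_class, torsion, ChiCurve(data[:, 0], data[:, 1]))
        return reg


def chi_energy(
    linkage: GlycosidicLinkage,
    phi: float,
    psi: float,
    registry: ChiCurveRegistry,
) -> float:
    """CHI strain energy (kcal/mol) of one linkage at torsions (phi, psi).

    Excluded linkages return exactly 0. Mirror linkages are evaluated at
    (-phi, -psi)."""
    if linkage.excluded_from_chi:
        return 0.0
    if linkage.mirror:
        phi, psi = -phi, -psi
    e_phi = float(registry.get(linkage.label, "phi")(phi))
    e_psi = float(registry.get(linkage.label, "psi")(psi))
    return e_phi + e_psi


def total_chi_series(
    traj: Trajectory,
    linkages: Sequence[GlycosidicLinkage],
    registry: ChiCurveRegistry,
) -> np.ndarray:
    """Per-frame total CHI energy summed over all non-excluded linkages."""
    if not linkages:
        raise SelectionError("no linkages supplied")
    out = np.zeros(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        total = 0.0
        for link in linkages:
            if link.excluded_from_chi:
                continue
            phi = torsion_angle(frame, link.phi_quad)
            psi = torsion_angle(frame, link.psi_quad)
            total += chi_energy(link, phi, psi, registry)
        out[k] = total
    return out


# ---------------------------------------------------------------------------
# Ring puckering
# ---------------------------------------------------------------------------


@dataclass
class PuckerState:
    """Cremer-Pople puckering coordinates of a six-membered ring plus the
    chair label: 4C1 (theta <= 45 deg), 1C4 (theta >= 135 deg), else
    'other'."""

    Q: float          # total puckering amplitude, Angstrom
    theta: float      # degrees, [0, 180]
    phi_ring: float   # degrees, [0, 360)
    label: str


def ring_pucker(frame: Frame, ring_indices: Sequence[int]) -> PuckerState:
    """Cremer-Pople analysis of a pyranose ring ordered O5,C1..C5."""
    if len(ring_indices) != 6:
        raise SelectionError("pyranose pucker needs exactly 6 ring atoms")
    R = frame.coordinates[list(ring_indices)].astype(float)
    center = R.mean(axis=0)
    R = R - center
    N = 6
    j = np.arange(N)
    Rp = (R * np.sin(2 * np.pi * j / N)[:, None]).sum(axis=0)
    Rpp = (R * np.cos(2 * np.pi * j / N)[:, None]).sum(axis=0)
    n = np.cross(Rp, Rpp)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        return PuckerState(Q=0.0, theta=90.0, phi_ring=0.0, label="other")
    n = n / norm
    z = R @ n
    q2c = np.sqrt(2.0 / N) * (z * np.cos(4 * np.pi * j / N)).sum()
    q2s = -np.sqrt(2.0 / N) * (z * np.sin(4 * np.pi * j / N)).sum()
    q3 = np.sqrt(1.0 / N) * (z * (-1.0) ** j).sum()
    q2 = np.hypot(q2c, q2s)
    Q = float(np.sqrt(q2 ** 2 + q3 ** 2))
    if Q < 0.1:
        warnings.warn("near-planar ring (Q < 0.1 A); pucker label unreliable")
        theta = 90.0 if Q == 0 else float(np.degrees(np.arccos(np.clip(q3 / Q, -1, 1))))
        return PuckerState(Q=Q, theta=theta, phi_ring=0.0, label="other")
    theta = float(np.degrees(np.arccos(np.clip(q3 / Q, -1, 1))))
    phi_ring = float(np.degrees(np.arctan2(q2s, q2c)) % 360.0)
    if theta <= 45.0:
        label = "4C1"
    elif theta >= 135.0:
        label = "1C4"
    else:
        label = "other"
    return PuckerState(Q=Q, theta=theta, phi_ring=phi_ring, label=label)
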