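"""Intermolecular interactions: hydrogen-bond detection and occupancy,
ion-coordination contacts, voxel water-density maps and water-mediated
ion-ligand bridge detection.

Hydrogen bonds use a geometric definition (donor-acceptor heavy-atom
distance plus donor-H...acceptor angle). "Stable" pairs are those whose
pooled occupancy over all runs clears a configurable threshold. Ca2+
coordination is scored distance-only (ion coordination has no hydrogen
geometry).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParameterError, SelectionError
from .model import Frame, HBondCriteria, Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "detect_hbonds",
    "hbond_occupancy",
    "DensityGrid",
    "water_density_map",
    "WaterBridgeReport",
    "detect_water_bridge",
]

_POLAR_ELEMENTS = {"N", "O", "F"}


def _polar_heavy(topology: Topology, indices: np.ndarray) -> np.ndarray:
    return np.asarray(
        [i for i in indices if topology.atoms[i].element in _POLAR_ELEMENTS],
        dtype=int,
    )


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    criteria: HBondCriteria,
    group_a: str,
    group_b: str,
) -> List[Tuple[int, int]]:
    """All (donor_index, acceptor_index) pairs between the two groups
    satisfying the criteria in this frame.

    Donors are polar heavy atoms with at least one bonded hydrogen; the
    angle test uses the best (largest) D-H...A angle over the donor's
    hydrogens. In ``distance_only`` mode every polar-polar cross pair within
    the distance cutoff counts (hydrogen-free topologies, ion coordination).
    """
    ia = topology.group(group_a)
    ib = topology.group(group_b)
    if np.intersect1d(ia, ib).size:
        raise SelectionError(f"groups {group_a!r} and {group_b!r} overlap")
    coords = frame.coordinates
    pa = _polar_heavy(topology, ia)
    pb = _polar_heavy(topology, ib)
    pairs = []
    for donors, acceptors in ((pa, pb), (pb, pa)):
        for d in donors:
            hyds = topology.bonded_hydrogens(int(d))
            if not hyds and not criteria.distance_only:
                continue
            dv = coords[acceptors] - coords[d]
            dist = np.linalg.norm(dv, axis=1)
            for a, r in zip(acceptors, dist):
                if r > criteria.distance_cutoff or r < 1e-6:
                    continue
                if criteria.distance_only:
                    pairs.append((int(d), int(a)))
                    continue
                best = 0.0
                for h in hyds:
                    v1 = coords[d] - coords[h]
                    v2 = coords[a] - coords[h]
                    cosang = (v1 @ v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12
                    )
                    best = max(best, np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if best >= criteria.angle_cutoff:
                    pairs.append((int(d), int(a)))
    return sorted(set(pairs))


def _pair_label(topology: Topology, idx: int) -> str:
    a = topology.atoms[idx]
    return f"{a.residue_name}{a.residue_id}:{a.name}"


def hbond_occupancy(
    trajs: Sequence[Trajectory],
    criteria: HBondCriteria,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-pair occupancy fractions, per run and pooled (frame-weighted),
    with the stable flag applied to the pooled value.

    Returns a DataFrame with columns donor, acceptor, occ_run_<id>...,
    occupancy, stable.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise EmptyInputError("no trajectories supplied")
    topo = trajs[0].topology
    counts: Dict[Tuple[int, int], Dict[int, int]] = {}
    frames_per_run: Dict[int, int] = {}
    for traj in trajs:
        frames_per_run[traj.run_id] = traj.n_frames
        for frame in traj.frames:
            for pair in detect_hbonds(frame, topo, criteria, group_a, group_b):
                counts.setdefault(pair, {}).setdefault(traj.run_id, 0)
                counts[pair][traj.run_id] += 1
    run_ids = sorted(frames_per_run)
    total_frames = sum(frames_per_run.values())
    rows = []
    for (d, a), per_run in sorted(counts.items()):
        row = {
            "donor": _pair_label(topo, d),
            "acceptor": _pair_label(topo, a),
            "donor_index": d,
            "acceptor_index": a,
        }
        pooled = 0
        for rid in run_ids:
            c = per_run.get(rid, 0)
            row[f"occ_run_{rid}"] = c / frames_per_run[rid]
            pooled += c
        row["occupancy"] = pooled / total_frames
        row["stable"] = row["occupancy"] >= criteria.stable_threshold
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Water density
# ---------------------------------------------------------------------------


@dataclass
class DensityGrid:
    """Mean water-oxygen occupancy per cubic voxel, averaged over frames."""

    origin: np.ndarray
    cell: float
    density: np.ndarray  # 3-D array of mean counts per voxel
    n_frames: int

    def voxel_center(self, ijk) -> np.ndarray:
        return self.origin + (np.asarray(ijk) + 0.5) * self.cell


def water_density_map(
    trajs: Sequence[Trajectory],
    region_min: np.ndarray,
    region_max: np.ndarray,
    cell: float = 0.5,
    density_floor: float = 0.25,
) -> Tuple[DensityGrid, List[Tuple[Tuple[int, int, int], float]]]:
    """Voxelised mean water-oxygen density over the axis-aligned box
    [region_min, region_max] at ``cell`` (A) resolution, plus local maxima.

    A local maximum is a voxel strictly exceeding all 26 neighbours with
    mean density >= ``density_floor``. Maxima are returned sorted by
    density, highest first. Returns an all-zero grid (with a warning entry)
    if the topology has no waters.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if cell <= 0:
        raise ParameterError("cell size must be > 0")
    lo = np.asarray(region_min, dtype=float)
    hi = np.asarray(region_max, dtype=float)
    if np.any(hi <= lo):
        raise ParameterError("region_max must exceed region_min on every axis")
    shape = np.maximum(np.ceil((hi - lo) / cell).astype(int), 1)
    counts = np.zeros(shape)
    n_frames = 0
    wox = trajs[0].topology.water_oxygen_indices()
    for traj in trajs:
        for frame in traj.frames:
            n_frames += 1
            if wox.size == 0:
                continue
            pos = frame.coordinates[wox]
            inside = np.all((pos >= lo) & (pos < hi), axis=1)
            if not inside.any():
                continue
            ijk = ((pos[inside] - lo) / cell).astype(int)
            np.add.at(counts, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), 1.0)
    density = counts / max(n_frames, 1)
    grid = DensityGrid(origin=lo, cell=cell, density=density, n_frames=n_frames)
    maxima = _local_maxima(density, density_floor)
    return grid, maxima


def _local_maxima(density: np.ndarray, floor: float):
    out = []
    nx, ny, nz = density.shape
    cand = np.argwhere(density >= floor)
    for i, j, k in cand:
        v = density[i, j, k]
        neighborhood = density[
            max(i - 1, 0): i + 2, max(j - 1, 0): j + 2, max(k - 1, 0): k + 2
        ]
        if v >= neighborhood.max() and (neighborhood == v).sum() == 1:
            out.append(((int(i), int(j), int(k)), float(v)))
    out.sort(key=lambda t: -t[1])
    return out


def write_dx(path, grid: DensityGrid) -> None:
    """Write the density grid in OpenDX-style volumetric text format."""
    nx, ny, nz = grid.density.shape
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        ox, oy, oz = grid.origin
        fh.write(f"origin {ox:.4f} {oy:.4f} {oz:.4f}\n")
        fh.write(f"delta {grid.cell:.4f} 0 0\ndelta 0 {grid.cell:.4f} 0\n"
                 f"delta 0 0 {grid.cell:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.density.ravel()
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[start:start + 3]) + "\n")


# ---------------------------------------------------------------------------
# Water-mediated bridges
# ---------------------------------------------------------------------------


@dataclass
class WaterBridgeReport:
    """Result of probing one high-occupancy water site for an
    ion-water-target bridge."""

    site: np.ndarray
    ion_water_mean: float
    ion_water_sd: float
    water_target_mean: float
    water_target_sd: float
    per_run_present: Dict[int, bool]
    occupancy: float  # fraction of frames with a water in the site

    @property
    def present_in_all_runs(self) -> bool:
        return bool(self.per_run_present) and all(self.per_run_present.values())


def detect_water_bridge(
    trajs: Sequence[Trajectory],
    ion_index: int,
    target_indices: Sequence[int],
    site: np.ndarray,
    ion_water_window: Tuple[float, float] = (1.8, 2.4),
    water_target_window: Tuple[float, float] = (2.2, 3.8),
    cell: float = 0.5,
) -> WaterBridgeReport:
    """Probe a water site (typically a density-map maximum) for a persistent
    ion-water-target bridge.

    Per frame, the water oxygen nearest the site and within one cell of it
    is taken to occupy the site; its distances to the ion and to the nearest
    target atom are recorded. A run exhibits the bridge when the means of
    both distances fall inside the given windows. Returns a no-bridge report
    (occupancy 0) when no water ever occupies the site.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    site = np.asarray(site, dtype=float)
    target_indices = np.asarray(list(target_indices), dtype=int)
    wox = trajs[0].topology.water_oxygen_indices()
    per_run_iw: Dict[int, List[float]] = {}
    per_run_wt: Dict[int, List[float]] = {}
    occupied = 0
    total = 0
    for traj in trajs:
        iw = per_run_iw.setdefault(traj.run_id, [])
        wt = per_run_wt.setdefault(traj.run_id, [])
        for frame in traj.frames:
            total += 1
            if wox.size == 0:
                continue
            pos = frame.coordinates[wox]
            d_site = np.linalg.norm(pos - site, axis=1)
            k = int(np.argmin(d_site))
            if d_site[k] > cell:
                continue
            occupied += 1
            w = pos[k]
            iw.append(float(np.linalg.norm(w - frame.coordinates[ion_index])))
            wt.append(
                float(
                    np.linalg.norm(
                        frame.coordinates[target_indices] - w, axis=1
                    ).min()
                )
            )
    all_iw = [v for vs in per_run_iw.values() for v in vs]
    all_wt = [v for vs in per_run_wt.values() for v in vs]
    present = {}
    for rid in per_run_iw:
        iw, wt = per_run_iw[rid], per_run_wt[rid]
        if not iw:
            present[rid] = False
            continue
        present[rid] = (
            ion_water_window[0] <= float(np.mean(iw)) <= ion_water_window[1]
            and water_target_window[0] <= float(np.mean(wt)) <= water_target_window[1]
        )
    return WaterBridgeReport(
        site=site,
        ion_water_mean=float(np.mean(all_iw)) if all_iw else np.nan,
        ion_water_sd=float(np.std(all_iw, ddof=1)) if len(all_iw) > 1 else 0.0,
        water_target_mean=float(np.mean(all_wt)) if all_wt else np.nan,
        water_target_sd=float(np.std(all_wt, ddof=1)) if len(all_wt) > 1 else 0.0,
        per_run_present=present,
        occupancy=occupied / max(total, 1),
    )
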