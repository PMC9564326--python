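"""Rigid-body superposition, positional RMSD series, pairwise (2D) RMSD
matrices, pose clustering and representative-structure extraction.

The positional-RMSD convention used throughout: each frame is least-squares
fitted to the reference on a *fit* selection (typically receptor C-alpha
atoms) and the RMSD is then measured over a *measure* selection (typically
the ligand ring atoms) **without refitting**, so the series reports where
the ligand sits in the binding site rather than its internal shape.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .errors import EmptyInputError, GeometryError, ParameterError
from .model import Frame, Topology, Trajectory

__all__ = [
    "SuperpositionResult",
    "RMSDSeries",
    "PoseAssignment",
    "kabsch_superpose",
    "ligand_rmsd_series",
    "pairwise_rmsd_matrix",
    "cluster_poses",
    "representative_frame",
]


@dataclass
class SuperpositionResult:
    """Optimal proper rotation R and translation t mapping mobile onto
    reference: x' = R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSDSeries:
    times: np.ndarray
    values: np.ndarray
    reference: str = ""
    fit_selection: str = ""
    measure_selection: str = ""
    run_id: int = 0


@dataclass
class PoseAssignment:
    """Cluster labels for the sampled frames; poses numbered 1.. by
    descending population."""

    labels: np.ndarray            # pose id per sample, 1-based
    populations: np.ndarray       # fraction per pose, ordered by pose id
    medoids: np.ndarray           # sample index of each pose's medoid
    sample_meta: Optional[List[Tuple[int, float, int]]] = None  # (run, time, frame)

    @property
    def n_poses(self) -> int:
        return len(self.populations)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> SuperpositionResult:
    """Weighted least-squares rigid fit (Kabsch algorithm).

    Returns the proper rotation (det = +1) and translation minimising the
    weighted RMSD of ``mobile`` onto ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("point sets must both be (n, 3) with equal n")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 points for a rigid fit")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    X = mobile - mc
    Y = reference - rc
    # collinearity check: centered reference must span a plane
    if np.linalg.matrix_rank(Y * np.sqrt(w)[:, None], tol=1e-8) < 2:
        raise GeometryError("points are collinear; rotation is underdetermined")
    H = (w[:, None] * X).T @ Y
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    diff = X @ R.T - Y
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _positional_rmsd(
    coords: np.ndarray,
    ref: np.ndarray,
    fit_idx: np.ndarray,
    measure_idx: np.ndarray,
) -> float:
    sup = kabsch_superpose(coords[fit_idx], ref[fit_idx])
    moved = sup.apply(coords[measure_idx])
    return float(np.sqrt(((moved - ref[measure_idx]) ** 2).sum(axis=1).mean()))


def ligand_rmsd_series(
    traj: Trajectory,
    fit_selection: str,
    measure_selection: str,
    reference: Frame,
    reference_label: str = "reference",
) -> RMSDSeries:
    """Positional RMSD of ``measure_selection`` after per-frame fit of
    ``fit_selection`` onto the reference frame (no refit on the measured
    atoms)."""
    topo = traj.topology
    fit_idx = topo.group(fit_selection)
    meas_idx = topo.group(measure_selection)
    ref = reference.coordinates
    values = np.array(
        [
            _positional_rmsd(f.coordinates, ref, fit_idx, meas_idx)
            for f in traj.frames
        ]
    )
    return RMSDSeries(
        times=traj.times,
        values=values,
        reference=reference_label,
        fit_selection=fit_selection,
        measure_selection=measure_selection,
        run_id=traj.run_id,
    )


def _sample_frames(trajs: Sequence[Trajectory], stride_ns: float):
    """Evenly sample every ``stride_ns`` from each run, pooled."""
    samples = []
    for traj in trajs:
        next_t = traj.frames[0].time
        for k, f in enumerate(traj.frames):
            if f.time >= next_t - 1e-9:
                samples.append((traj.run_id, f.time, k, f.coordinates))
                next_t += stride_ns
    return samples


def pairwise_rmsd_matrix(
    trajs,
    selection: str,
    stride_ns: float = 0.1,
    fit_selection: Optional[str] = None,
):
    """Symmetric all-vs-all RMSD matrix over samples drawn every
    ``stride_ns`` from the pooled runs.

    Entry (i, j) superposes sample j on sample i and measures the RMSD over
    ``selection``. By default the fit uses the same selection (internal-shape
    RMSD); passing ``fit_selection`` (e.g. receptor C-alpha) fits on those
    atoms instead and measures ``selection`` without refitting, giving the
    positional (binding-site-frame) pose map.

    Returns (matrix, sample_meta) where sample_meta is a list of
    (run_id, time, frame_index) tuples.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if stride_ns <= 0:
        raise ParameterError("stride must be > 0")
    topo = trajs[0].topology
    idx = topo.group(selection)
    fit_idx = topo.group(fit_selection) if fit_selection else idx
    samples = _sample_frames(trajs, stride_ns)
    m = len(samples)
    if m < 2:
        raise EmptyInputError("stride yields fewer than 2 samples")
    meas = np.stack([s[3][idx] for s in samples])
    fit = np.stack([s[3][fit_idx] for s in samples])
    mat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            sup = kabsch_superpose(fit[j], fit[i])
            moved = sup.apply(meas[j])
            r = float(np.sqrt(((moved - meas[i]) ** 2).sum(axis=1).mean()))
            mat[i, j] = mat[j, i] = r
    meta = [(s[0], s[1], s[2]) for s in samples]
    return mat, meta


def cluster_poses(matrix: np.ndarray, cutoff: float = 1.5, sample_meta=None) -> PoseAssignment:
    """Average-linkage agglomerative clustering of the pairwise RMSD matrix,
    cut at ``cutoff`` (A). Poses are renumbered 1.. by descending population;
    each pose's medoid is its member with the smallest summed RMSD to the
    rest of the cluster."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    matrix = np.asarray(matrix, dtype=float)
    m = matrix.shape[0]
    if m == 1:
        return PoseAssignment(
            labels=np.array([1]), populations=np.array([1.0]),
            medoids=np.array([0]), sample_meta=sample_meta,
        )
    condensed = squareform(matrix, checks=False)
    raw = fcluster(average(condensed), t=cutoff, criterion="distance")
    clusters, counts = np.unique(raw, return_counts=True)
    # order clusters by population (desc), tie-break by first appearance
    order = sorted(
        range(len(clusters)),
        key=lambda k: (-counts[k], int(np.argmax(raw == clusters[k]))),
    )
    relabel = {clusters[k]: rank + 1 for rank, k in enumerate(order)}
    labels = np.array([relabel[c] for c in raw])
    populations = np.array(
        [np.mean(labels == p) for p in range(1, len(clusters) + 1)]
    )
    medoids = []
    for p in range(1, len(clusters) + 1):
        members = np.where(labels == p)[0]
        sums = matrix[np.ix_(members, members)].sum(axis=1)
        medoids.append(members[int(np.argmin(sums))])
    return PoseAssignment(
        labels=labels,
        populations=populations,
        medoids=np.array(medoids),
        sample_meta=sample_meta,
    )


def representative_frame(
    trajs: Sequence[Trajectory],
    selection: str,
    fit_selection: Optional[str] = None,
) -> Tuple[Tuple[int, float], Frame]:
    """Frame whose ``selection`` coordinates are closest (RMSD) to the mean
    shape over all frames of all runs, after superposing every frame's
    selection onto the first frame's.

    Ties are broken by (run_id, time). Returns ((run_id, time), Frame).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs or not any(t.n_frames for t in trajs):
        raise EmptyInputError("no frames supplied")
    topo = trajs[0].topology
    sel = topo.group(selection)
    fit = topo.group(fit_selection) if fit_selection else sel
    entries = []  # (run_id, time, fitted selection coords, frame)
    ref = None
    for traj in trajs:
        for f in traj.frames:
            if ref is None:
                ref = f.coordinates
            sup = kabsch_superpose(f.coordinates[fit], ref[fit])
            entries.append((traj.run_id, f.time, sup.apply(f.coordinates[sel]), f))
    mean = np.mean([e[2] for e in entries], axis=0)
    best = None
    for run_id, time, coords, frame in entries:
        r = float(np.sqrt(((coords - mean) ** 2).sum(axis=1).mean()))
        key = (round(r, 12), run_id, time)
        if best is None or key < best[0]:
            best = (key, (run_id, time), frame)
    return best[1], best[2]
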