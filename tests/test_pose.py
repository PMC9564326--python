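"""Superposition, RMSD series, pairwise matrices, clustering and
representative-frame extraction."""
import numpy as np
import pytest

from glycomd.errors import GeometryError, ParameterError
from glycomd.model import Frame, Trajectory
from glycomd.pose import (
    cluster_poses,
    kabsch_superpose,
    ligand_rmsd_series,
    pairwise_rmsd_matrix,
    representative_frame,
)


def _rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


def _brute_force_min_rmsd(mobile, reference, n=40):
    """Exhaustive search over a dense rotation grid (axis-angle lattice),
    independent of the SVD path."""
    best = np.inf
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    for u in np.linspace(0, np.pi, n):
        for v in np.linspace(0, 2 * np.pi, n, endpoint=False):
            axis = np.array([np.sin(u) * np.cos(v), np.sin(u) * np.sin(v), np.cos(u)])
            for ang in np.linspace(0, 2 * np.pi, 2 * n, endpoint=False):
                K = np.array([[0, -axis[2], axis[1]],
                              [axis[2], 0, -axis[0]],
                              [-axis[1], axis[0], 0]])
                R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
                r = np.sqrt(((mc @ R.T - rc) ** 2).sum(axis=1).mean())
                best = min(best, r)
    return best


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd < 1e-12
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_exact_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        R = _rot_z(90.0)
        moved = pts @ R.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd < 1e-8
        assert np.allclose(res.rotation, R, atol=1e-8)
        assert np.allclose(res.translation, [1, 2, 3], atol=1e-8)
        assert np.isclose(np.linalg.det(res.rotation), 1.0)

    def test_matches_brute_force_rotation_search(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(4, 3))
        mob = ref.copy()
        mob[0] += [0.3, -0.2, 0.1]          # one perturbed point
        res = kabsch_superpose(mob, ref)
        brute = _brute_force_min_rmsd(mob, ref)
        assert res.rmsd <= brute + 1e-4

    def test_too_few_or_collinear_points(self):
        with pytest.raises(GeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)

    def test_rmsd_invariant_under_joint_rigid_motion(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(7, 3))
        b = a + rng.normal(scale=0.3, size=(7, 3))
        base = kabsch_superpose(a, b).rmsd
        for seed in range(5):
            r = np.linalg.qr(np.random.default_rng(seed).normal(size=(3, 3)))[0]
            if np.linalg.det(r) < 0:
                r[:, 0] *= -1
            t = np.random.default_rng(seed).normal(size=3) * 10
            moved = kabsch_superpose(a @ r.T + t, b @ r.T + t).rmsd
            assert np.isclose(moved, base, atol=1e-8)


class TestRMSDSeries:
    def test_reference_frame_zero(self, stable_bundle):
        trajs, _, _ = stable_bundle
        s = ligand_rmsd_series(trajs[0], "receptor_ca", "ring_atoms",
                               trajs[0].frames[0])
        assert s.values[0] < 1e-9
        assert np.all(s.values >= 0)
        assert len(s.values) == trajs[0].n_frames

    def test_stable_vs_diffusing(self, stable_bundle, diffusing_bundle):
        st, _, _ = stable_bundle
        df, _, _ = diffusing_bundle
        ref = st[0].frames[0]
        assert ligand_rmsd_series(st[0], "receptor_ca", "ring_atoms",
                                  ref).values.max() < 1.0
        dref = df[0].frames[0]
        assert ligand_rmsd_series(df[0], "receptor_ca", "ring_atoms",
                                  dref).values[-1] > 10.0


class TestPairwiseMatrix:
    def test_identical_frames_give_zero_matrix(self, stable_bundle):
        trajs, _, _ = stable_bundle
        topo = trajs[0].topology
        frames = [Frame(trajs[0].frames[0].coordinates.copy(), time=float(k))
                  for k in range(5)]
        traj = Trajectory(topo, frames)
        mat, _ = pairwise_rmsd_matrix(traj, "ring_atoms", stride_ns=1.0)
        assert np.abs(mat).max() < 1e-9

    def test_symmetry_and_zero_diagonal(self, multipose_bundle):
        trajs, _, _ = multipose_bundle
        mat, _ = pairwise_rmsd_matrix(trajs[0], "ring_atoms", stride_ns=1.0,
                                      fit_selection="receptor_ca")
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0)

    def test_planted_poses_make_entries_bimodal(self, multipose_bundle):
        trajs, _, extras = multipose_bundle
        mat, meta = pairwise_rmsd_matrix(trajs[0], "ring_atoms", stride_ns=0.5,
                                         fit_selection="receptor_ca")
        labels = extras["pose_labels"][[m[2] for m in meta]]
        same = mat[np.equal.outer(labels, labels) & ~np.eye(len(labels), dtype=bool)]
        diff = mat[~np.equal.outer(labels, labels)]
        assert same.max() < diff.min()


class TestClustering:
    def test_zero_matrix_single_pose(self):
        asg = cluster_poses(np.zeros((6, 6)), cutoff=1.0)
        assert asg.n_poses == 1 and asg.populations[0] == 1.0

    def test_recovers_planted_dwell_fractions(self, multipose_bundle):
        trajs, _, _ = multipose_bundle
        mat, meta = pairwise_rmsd_matrix(trajs, "ring_atoms", stride_ns=0.2,
                                         fit_selection="receptor_ca")
        asg = cluster_poses(mat, cutoff=1.5, sample_meta=meta)
        assert asg.n_poses == 3
        assert np.allclose(asg.populations, (0.5, 0.3, 0.2), atol=0.05)
        assert np.isclose(asg.populations.sum(), 1.0, atol=1e-9)

    def test_huge_cutoff_single_pose(self, multipose_bundle):
        trajs, _, _ = multipose_bundle
        mat, _ = pairwise_rmsd_matrix(trajs[0], "ring_atoms", stride_ns=1.0,
                                      fit_selection="receptor_ca")
        asg = cluster_poses(mat, cutoff=mat.max() * 2)
        assert asg.n_poses == 1

    def test_invalid_cutoff(self):
        with pytest.raises(ParameterError):
            cluster_poses(np.zeros((3, 3)), cutoff=0.0)

    def test_permutation_invariance(self, multipose_bundle):
        trajs, _, _ = multipose_bundle
        mat, _ = pairwise_rmsd_matrix(trajs[0], "ring_atoms", stride_ns=0.5,
                                      fit_selection="receptor_ca")
        asg = cluster_poses(mat, cutoff=1.5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(mat.shape[0])
        asg2 = cluster_poses(mat[np.ix_(perm, perm)], cutoff=1.5)
        # pose ids are population-ordered, so labels must match through perm
        assert np.array_equal(asg.labels[perm], asg2.labels)

    def test_pose_count_non_increasing_in_cutoff(self, multipose_bundle):
        trajs, _, _ = multipose_bundle
        mat, _ = pairwise_rmsd_matrix(trajs[0], "ring_atoms", stride_ns=0.5,
                                      fit_selection="receptor_ca")
        counts = [cluster_poses(mat, cutoff=c).n_poses
                  for c in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRepresentativeFrame:
    def test_single_frame_is_its_own_representative(self, stable_bundle):
        trajs, _, _ = stable_bundle
        topo = trajs[0].topology
        single = Trajectory(topo, trajs[0].frames[:1])
        (rid, t), frame = representative_frame([single], "ring_atoms")
        assert t == trajs[0].frames[0].time
        assert frame is single.frames[0]

    def test_exhaustive_scan_oracle(self, stable_bundle):
        trajs, _, _ = stable_bundle
        traj = trajs[0]
        sel = traj.topology.group("ring_atoms")
        (rid, t_best), frame = representative_frame([traj], "ring_atoms")
        # independent recomputation: mean of fitted selections, then scan
        from glycomd.pose import kabsch_superpose as kb

        ref = traj.frames[0].coordinates
        fitted = []
        for f in traj.frames:
            sup = kb(f.coordinates[sel], ref[sel])
            fitted.append(sup.apply(f.coordinates[sel]))
        mean = np.mean(fitted, axis=0)
        rmsds = [np.sqrt(((c - mean) ** 2).sum(axis=1).mean()) for c in fitted]
        chosen = np.sqrt(
            ((fitted[int(np.argmin(rmsds))] - mean) ** 2).sum(axis=1).mean()
        )
        found = min(
            np.sqrt(((kb(frame.coordinates[sel], ref[sel]).apply(
                frame.coordinates[sel]) - mean) ** 2).sum(axis=1).mean())
            for _ in [0]
        )
        assert found <= min(rmsds) + 1e-9

    def test_duplicate_trajectories_tie_broken_by_run_id(self, stable_bundle):
        trajs, _, _ = stable_bundle
        topo = trajs[0].topology
        a = Trajectory(topo, trajs[0].frames, run_id=0)
        b = Trajectory(topo, trajs[0].frames, run_id=1)
        (rid, t), _ = representative_frame([a, b], "ring_atoms")
        assert rid == 0
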