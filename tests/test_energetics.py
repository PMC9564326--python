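"""MM terms, GB-OBC solvation, SASA, MM-GBSA assembly, decomposition and
mutant construction."""
import numpy as np
import pytest

from glycomd.energetics import (
    gb_energy,
    mmgbsa_interaction,
    mutate_to_alanine,
    pair_energy,
    per_group_decomposition,
    remove_residue,
    sasa,
)
from glycomd.errors import (
    GeometryError,
    InsufficientSamplingError,
    PartitionError,
)
from glycomd.model import (
    Atom,
    AtomParams,
    ForceFieldParams,
    Frame,
    Topology,
    Trajectory,
)

K = 332.0636


def _two_atom_system(q1, q2, r, rmin_half=0.0, eps=0.0, eps_int=1.0):
    atoms = [Atom(1, "A", "X", 1, "AAA"), Atom(2, "B", "X", 2, "BBB")]
    topo = Topology(atoms, groups={"a": [0], "b": [1]})
    table = {
        ("AAA", "A"): AtomParams(q1, rmin_half, eps, 1.0, 1.5),
        ("BBB", "B"): AtomParams(q2, rmin_half, eps, 1.0, 1.5),
    }
    params = ForceFieldParams(table, eps_int=eps_int)
    frame = Frame(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))
    return topo, params, frame


class TestPairEnergy:
    def test_coulomb_closed_form(self):
        topo, params, frame = _two_atom_system(1.0, -1.0, K / 100.0)
        e_elec, e_vdw = pair_energy(frame, topo, params, "a", "b")
        assert np.isclose(e_elec, -100.0, atol=1e-9)
        assert e_vdw == 0.0

    def test_dielectric_scaling_is_exact(self):
        topo, p1, frame = _two_atom_system(1.0, -1.0, K / 100.0, eps_int=1.0)
        _, p2, _ = _two_atom_system(1.0, -1.0, K / 100.0, eps_int=2.0)
        e1, _ = pair_energy(frame, topo, p1, "a", "b")
        e2, _ = pair_energy(frame, topo, p2, "a", "b")
        assert np.isclose(e2, e1 / 2.0, atol=1e-12)

    def test_lj_minimum(self):
        topo, params, frame = _two_atom_system(
            0.0, 0.0, 3.6, rmin_half=1.8, eps=0.2
        )
        e_elec, e_vdw = pair_energy(frame, topo, params, "a", "b")
        assert e_elec == 0.0
        assert np.isclose(e_vdw, -0.2, atol=1e-12)

    def test_overlapping_atoms_rejected(self):
        topo, params, frame = _two_atom_system(1.0, -1.0, 0.05)
        with pytest.raises(GeometryError):
            pair_energy(frame, topo, params, "a", "b")


class TestGBEnergy:
    def _single_ion(self, eff_radius=4.0, eps_int=1.0):
        """With no neighbours psi = 0, so the effective radius equals the
        offset-reduced intrinsic radius."""
        atoms = [Atom(1, "NA", "Na", 1, "ION")]
        topo = Topology(atoms, groups={"g": [0]})
        table = {("ION", "NA"): AtomParams(1.0, 1.8, 0.1, 23.0,
                                           eff_radius + 0.09)}
        return topo, ForceFieldParams(table, eps_int=eps_int)

    def test_born_closed_form(self):
        topo, params = self._single_ion()
        e, radii = gb_energy(Frame(np.zeros((1, 3))), topo, params, "g")
        born = -0.5 * (1.0 - 1.0 / 78.5) * K / 4.0
        assert np.isclose(radii[0], 4.0, atol=1e-12)
        assert abs(e - born) / abs(born) < 1e-6

    def test_zero_charges_zero_energy(self):
        atoms = [Atom(1, "C", "C", 1, "RES"), Atom(2, "C2", "C", 1, "RES")]
        topo = Topology(atoms, groups={"g": [0, 1]})
        table = {("RES", "C"): AtomParams(0.0, 1.9, 0.1, 12.0, 1.7),
                 ("RES", "C2"): AtomParams(0.0, 1.9, 0.1, 12.0, 1.7)}
        params = ForceFieldParams(table)
        e, _ = gb_energy(Frame(np.array([[0, 0, 0], [3.0, 0, 0.0]])),
                         topo, params, "g")
        assert e == 0.0

    def test_additivity_in_infinite_separation_limit(self):
        """At huge separation the pair energy tends to the sum of Born
        self-energies (the screened cross term decays as 1/r)."""
        atoms = [Atom(1, "NA", "Na", 1, "ION"), Atom(2, "NA", "Na", 2, "ION")]
        topo = Topology(atoms, groups={"g": [0, 1], "one": [0]})
        table = {("ION", "NA"): AtomParams(1.0, 1.8, 0.1, 23.0, 4.09)}
        params = ForceFieldParams(table, eps_int=1.0)
        single, _ = gb_energy(Frame(np.zeros((1, 3))),
                              Topology(atoms[:1], groups={"one": [0]}),
                              params, "one")
        r = 2.0e5
        pairw, _ = gb_energy(Frame(np.array([[0, 0, 0], [r, 0, 0.0]])),
                             topo, params, "g")
        assert abs(pairw - 2 * single) / abs(2 * single) < 1e-3

    def test_pairwise_symmetry_under_atom_exchange(self):
        atoms = [Atom(1, "A", "O", 1, "R1"), Atom(2, "B", "N", 2, "R2")]
        table = {("R1", "A"): AtomParams(-0.5, 1.7, 0.2, 16.0, 1.5),
                 ("R2", "B"): AtomParams(0.8, 1.8, 0.17, 14.0, 1.55)}
        params = ForceFieldParams(table)
        coords = np.array([[0, 0, 0], [3.1, 0.4, -0.2]])
        t1 = Topology(atoms, groups={"g": [0, 1]})
        e1, _ = gb_energy(Frame(coords), t1, params, "g")
        t2 = Topology(atoms[::-1], groups={"g": [0, 1]})
        e2, _ = gb_energy(Frame(coords[::-1]), t2, params, "g")
        assert np.isclose(e1, e2, atol=1e-10)


class TestSASA:
    def test_isolated_atom_sphere_area(self):
        areas = sasa(np.zeros((1, 3)), np.array([1.6]), probe=1.4)
        exact = 4 * np.pi * 3.0 ** 2
        assert abs(areas[0] - exact) / exact < 0.01

    def test_buried_atom_has_no_area(self):
        # central atom caged by 12 close neighbours (icosahedron vertices)
        phi = (1 + np.sqrt(5)) / 2
        verts = []
        for a in (-1, 1):
            for b in (-phi, phi):
                verts += [[0, a, b], [a, b, 0], [b, 0, a]]
        verts = np.array(verts) / np.linalg.norm([1, phi]) * 2.0
        coords = np.vstack([[0, 0, 0], verts])
        radii = np.full(len(coords), 1.6)
        areas = sasa(coords, radii, probe=1.4)
        assert areas[0] < 1e-9

    def test_total_area_decreases_as_atoms_approach(self):
        radii = np.array([1.6, 1.6])
        prev = np.inf
        for r in (6.0, 4.0, 3.0, 2.0, 1.0):
            total = sasa(np.array([[0, 0, 0], [r, 0, 0.0]]), radii,
                         n_points=4000).sum()
            assert total < prev + 1e-9
            prev = total


def _partition(topology):
    return {g: g for g in ("Neu5Ac", "Gal", "GlcNAc", "Fuc", "SO3")
            if g in topology.groups}


class TestMMGBSA:
    def test_reduces_to_pair_energy_without_solvation(self):
        topo, params, frame = _two_atom_system(1.0, -1.0, K / 100.0)
        topo.set_group("receptor", [0])
        topo.set_group("ligand", [1])
        traj = Trajectory(topo, [frame])
        ec = mmgbsa_interaction([traj], params, n_snapshots=1,
                                include_gb=False, include_sasa=False)
        assert np.isclose(ec.total, -100.0, atol=1e-9)
        assert ec.e_vdw == 0.0 and ec.dg_gb == 0.0 and ec.dg_sasa == 0.0

    def test_identical_runs_have_zero_sd(self, stable_bundle):
        trajs, params, _ = stable_bundle
        t = trajs[0]
        copies = [Trajectory(t.topology, t.frames, run_id=k) for k in range(3)]
        ec = mmgbsa_interaction(copies, params, n_snapshots=5)
        assert ec.sd == 0.0

    def test_matches_brute_force_per_frame_evaluation(self, stable_bundle):
        """Snapshot-averaged interaction equals direct evaluation of
        G(complex) - G(receptor) - G(ligand) on every frame."""
        trajs, params, _ = stable_bundle
        topo = trajs[0].topology
        short = Trajectory(topo, trajs[0].frames[:6])
        ec = mmgbsa_interaction([short], params, n_snapshots=6)
        gamma = params.surface_tension
        totals = []
        topo.set_group("_union", np.concatenate(
            [topo.group("receptor"), topo.group("ligand")]))
        for frame in short.frames:
            e_el, e_vdw = pair_energy(frame, topo, params, "receptor", "ligand")
            gb_c, _ = gb_energy(frame, topo, params, "_union")
            gb_r, _ = gb_energy(frame, topo, params, "receptor")
            gb_l, _ = gb_energy(frame, topo, params, "ligand")
            pr = params.arrays_for(topo, topo.group("receptor"))
            pl = params.arrays_for(topo, topo.group("ligand"))
            cu = np.vstack([frame.coordinates[topo.group("receptor")],
                            frame.coordinates[topo.group("ligand")]])
            ru = np.concatenate([pr["gb_radius"], pl["gb_radius"]])
            a_c = sasa(cu, ru, probe=params.probe_radius).sum()
            a_r = sasa(frame.coordinates[topo.group("receptor")],
                       pr["gb_radius"], probe=params.probe_radius).sum()
            a_l = sasa(frame.coordinates[topo.group("ligand")],
                       pl["gb_radius"], probe=params.probe_radius).sum()
            totals.append(e_el + e_vdw + (gb_c - gb_r - gb_l)
                          + gamma * (a_c - a_r - a_l))
        assert np.isclose(ec.total, np.mean(totals), atol=1e-6)

    def test_too_many_snapshots_rejected(self, stable_bundle):
        trajs, params, _ = stable_bundle
        with pytest.raises(InsufficientSamplingError):
            mmgbsa_interaction([trajs[0]], params, n_snapshots=10 ** 6)

    def test_rigid_motion_invariance(self, stable_bundle):
        """Electrostatics, vdW and GB are exactly invariant under rigid
        motion; the SASA quadrature (a fixed sphere-point lattice) is
        invariant only to within its angular resolution."""
        trajs, params, _ = stable_bundle
        topo = trajs[0].topology
        short = Trajectory(topo, trajs[0].frames[:3])
        R = np.linalg.qr(np.random.default_rng(5).normal(size=(3, 3)))[0]
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        from glycomd.model import frames_like

        moved = frames_like(short, short.coordinates() @ R.T + 7.0)
        ec1 = mmgbsa_interaction([short], params, n_snapshots=3,
                                 include_sasa=False)
        ec2 = mmgbsa_interaction([moved], params, n_snapshots=3,
                                 include_sasa=False)
        assert np.isclose(ec1.total, ec2.total, atol=1e-6)
        full1 = mmgbsa_interaction([short], params, n_snapshots=3)
        full2 = mmgbsa_interaction([moved], params, n_snapshots=3)
        assert np.isclose(full1.total, full2.total, atol=0.05)


class TestDecomposition:
    def test_single_group_reduces_to_total(self, stable_bundle):
        trajs, params, _ = stable_bundle
        topo = trajs[0].topology
        short = [Trajectory(t.topology, t.frames[:4], run_id=t.run_id)
                 for t in trajs]
        ec = mmgbsa_interaction(short, params, n_snapshots=4)
        dec = per_group_decomposition(short, params, "receptor",
                                      {"all": "ligand"}, n_snapshots=4)
        assert np.isclose(dec.energy.sum(), ec.total, atol=1e-6)
        assert len(dec) == 1

    def test_groups_sum_to_total(self, stable_bundle):
        trajs, params, _ = stable_bundle
        short = [Trajectory(t.topology, t.frames[:4], run_id=t.run_id)
                 for t in trajs]
        ec = mmgbsa_interaction(short, params, n_snapshots=4)
        dec = per_group_decomposition(
            short, params, "receptor", _partition(short[0].topology),
            n_snapshots=4,
        )
        assert np.isclose(dec.energy.sum(), ec.total, atol=1e-6)

    def test_uncharged_groups_have_zero_electrostatics(self, stable_bundle):
        trajs, params, _ = stable_bundle
        short = [Trajectory(trajs[0].topology, trajs[0].frames[:3])]
        dec = per_group_decomposition(
            short, params, "receptor", _partition(trajs[0].topology),
            n_snapshots=3,
        ).set_index("group")
        # only the sulfate carries charge on the ligand side
        assert abs(dec.loc["SO3", "e_elec"]) > 1.0
        for g in ("Neu5Ac", "Gal", "GlcNAc", "Fuc"):
            assert dec.loc[g, "e_elec"] == 0.0

    def test_bad_partition_rejected(self, stable_bundle):
        trajs, params, _ = stable_bundle
        part = _partition(trajs[0].topology)
        part.pop("Fuc")
        with pytest.raises(PartitionError):
            per_group_decomposition([trajs[0]], params, "receptor", part,
                                    n_snapshots=2)


def _tripeptide():
    """GLY-ARG-SER toy peptide with side chains."""
    atoms, coords = [], []
    serial = 0
    layout = [
        (1, "GLY", ["N", "CA", "C", "O"]),
        (2, "ARG", ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ"]),
        (3, "SER", ["N", "CA", "C", "O", "CB", "OG"]),
    ]
    for resid, resname, names in layout:
        for k, name in enumerate(names):
            serial += 1
            atoms.append(Atom(serial, name, name[0], resid, resname))
            coords.append([3.0 * resid + 0.9 * k, resid * 1.0, 0.3 * k])
    return Topology(atoms), [Frame(np.array(coords, dtype=float))]


class TestMutantConstruction:
    def test_alanine_truncation_semantics(self):
        topo, frames = _tripeptide()
        n_side = 4  # ARG atoms beyond CB: CG, CD, NE, CZ
        topo2, frames2 = mutate_to_alanine(topo, frames, [2])
        assert topo2.n_atoms == topo.n_atoms - n_side
        assert all(a.residue_name == "ALA"
                   for a in topo2.atoms if a.residue_id == 2)
        # backbone + CB coordinates bit-identical
        for name in ("N", "CA", "C", "O", "CB"):
            i_old = topo.index_of(2, name)
            i_new = topo2.index_of(2, name)
            assert np.array_equal(frames[0].coordinates[i_old],
                                  frames2[0].coordinates[i_new])

    def test_double_mutation_commutes(self):
        topo, frames = _tripeptide()
        t12, f12 = mutate_to_alanine(*mutate_to_alanine(topo, frames, [2]), [3])
        t21, f21 = mutate_to_alanine(*mutate_to_alanine(topo, frames, [3]), [2])
        tboth, fboth = mutate_to_alanine(topo, frames, [2, 3])
        for t, f in ((t12, f12), (t21, f21)):
            assert [a.name for a in t.atoms] == [a.name for a in tboth.atoms]
            assert np.array_equal(f[0].coordinates, fboth[0].coordinates)

    def test_glycine_rejected(self):
        topo, frames = _tripeptide()
        with pytest.raises(GeometryError):
            mutate_to_alanine(topo, frames, [1])

    def test_mutant_remains_parameterised(self, stable_bundle):
        trajs, params, _ = stable_bundle
        topo2, frames2 = mutate_to_alanine(
            trajs[0].topology, trajs[0].frames, [12]
        )
        arrays = params.arrays_for(topo2)      # raises if anything is missing
        assert arrays["mass"].size == topo2.n_atoms

    def test_alanine_scan_abolishes_planted_salt_bridge(self, stable_bundle):
        """Truncating the arginine that carries the +1 guanidinium charge
        removes essentially all of the sulfate's electrostatic interaction,
        the in-silico analogue of an affinity-abolishing alanine mutation."""
        trajs, params, _ = stable_bundle
        topo = trajs[0].topology
        frame = trajs[0].frames[0]
        e_wt, _ = pair_energy(frame, topo, params, "receptor", "SO3")
        topo2, frames2 = mutate_to_alanine(topo, [frame], [12])
        e_mut, _ = pair_energy(frames2[0], topo2, params, "receptor", "SO3")
        assert abs(e_mut) <= 0.1 * abs(e_wt)


class TestRemoveResidue:
    def test_defucosylation_bookkeeping(self, stable_bundle):
        trajs, _, _ = stable_bundle
        topo = trajs[0].topology
        n_fuc = len(topo.residue_indices(4))
        topo2, frames2 = remove_residue(topo, trajs[0].frames[:2], 4)
        # fucose removed, one hydroxyl hydrogen restored on the dangling O3
        assert topo2.n_atoms == topo.n_atoms - n_fuc + 1
        cap = topo2.atoms[-1]
        assert cap.element == "H" and cap.residue_name == "NAG"
        # remaining atoms' coordinates unchanged
        keep_old = [i for i in range(topo.n_atoms)
                    if topo.atoms[i].residue_id != 4]
        assert np.array_equal(trajs[0].frames[0].coordinates[keep_old],
                              frames2[0].coordinates[:-1])
        # capped O-H bond length
        o3 = topo2.index_of(3, "O3")
        d = np.linalg.norm(frames2[0].coordinates[-1]
                           - frames2[0].coordinates[o3])
        assert np.isclose(d, 0.96, atol=1e-9)

    def test_unknown_residue_rejected(self, stable_bundle):
        trajs, _, _ = stable_bundle
        from glycomd.errors import SelectionError

        with pytest.raises(SelectionError):
            remove_residue(trajs[0].topology, trajs[0].frames[:1], 999)
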