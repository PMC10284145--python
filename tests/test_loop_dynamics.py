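import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from bindcalor.loop_dynamics import (
    UNASSIGNED,
    ZA1,
    ZA2,
    DihedralSeries,
    StateTrace,
    TrajectoryCoords,
    assign_states_dihedral,
    assign_states_rmsd,
    backbone_rmsf,
    compute_dihedral_series,
    dihedral_angle,
    is_backbone,
    kabsch_rmsd,
    loop_rmsd_series,
    mean_first_transition_time,
    pair_distance_series,
    parse_selection,
    phi_hinge_quadruple,
    psi_hinge_quadruple,
    read_multimodel_pdb,
    smooth_trace,
    transition_stats,
)
from bindcalor.synthetic_data import LegGeneratorConfig, TwoStateConfig, generate_two_state_system

from conftest import make_protein_traj, random_rotation, to_pdb_text


def brute_force_min_rmsd(ref, mob):
    """Independent oracle: coarse rotation grid + Nelder-Mead polish of the
    raw (rotation, translation-by-centroid) RMSD, no SVD involved."""
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    refc = ref - ref.mean(axis=0)
    mobc = mob - mob.mean(axis=0)

    def cost(euler):
        R = Rotation.from_euler("xyz", euler).as_matrix()
        return np.sqrt(np.mean(np.sum((mobc @ R.T - refc) ** 2, axis=1)))

    grid = np.linspace(-np.pi, np.pi, 13)
    best = min(
        ((a, b, c) for a in grid for b in grid for c in grid),
        key=lambda e: cost(e),
    )
    res = minimize(cost, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return res.fun


def dihedral_oracle(p0, p1, p2, p3):
    """Plane-normal oracle with sign from the triple product."""
    p0, p1, p2, p3 = map(np.asarray, (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestKabschRmsd:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_rmsd(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self, rng):
        x = rng.normal(size=(8, 3))
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = x @ R90.T + np.array([5.0, 5.0, 5.0])
        _, _, rmsd = kabsch_rmsd(x, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_proper_rotation(self, rng):
        x = rng.normal(size=(6, 3))
        y = x.copy()
        y[:, 0] = -y[:, 0]  # mirror: best proper rotation must still have det +1
        R, _, _ = kabsch_rmsd(x, y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_grid_oracle_5_atoms(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(5, 3)) * 2.0
        mob = ref.copy()
        mob[0] += rng.normal(size=3) * 0.5  # displace one atom
        mob = mob @ random_rotation(rng).T + rng.normal(size=3)
        _, _, rmsd = kabsch_rmsd(ref, mob)
        assert rmsd == pytest.approx(brute_force_min_rmsd(ref, mob), abs=1e-3)

    def test_symmetry(self, rng):
        a = rng.normal(size=(7, 3))
        b = a + rng.normal(size=(7, 3)) * 0.3
        _, _, r_ab = kabsch_rmsd(a, b)
        _, _, r_ba = kabsch_rmsd(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

    def test_degenerate_collinear(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_rmsd(line, line + 1.0)

    def test_too_few_atoms(self, rng):
        x = rng.normal(size=(2, 3))
        with pytest.raises(ValueError):
            kabsch_rmsd(x, x)

    def test_transform_application(self, rng):
        ref = rng.normal(size=(5, 3))
        mob = ref @ random_rotation(rng).T + 3.0
        R, t, _ = kabsch_rmsd(ref, mob)
        np.testing.assert_allclose(mob @ R.T + t, ref, atol=1e-9)


class TestLoopRmsdSeries:
    def test_identical_frames_zero(self, toy_traj):
        series = loop_rmsd_series(toy_traj, toy_traj.frames[0],
                                  is_backbone, parse_selection("resid 2-4"))
        np.testing.assert_allclose(series, 0.0, atol=1e-12)

    def test_rigid_motion_zero(self, rng):
        traj = make_protein_traj(n_frames=4)
        frames = traj.frames.copy()
        for k in range(1, 4):
            frames[k] = frames[k] @ random_rotation(rng).T + rng.normal(size=3) * 10
        traj = TrajectoryCoords(atoms=traj.atoms, frames=frames, dt=traj.dt)
        series = loop_rmsd_series(traj, traj.frames[0], is_backbone, is_backbone)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_direct_formula_oracle(self):
        # displace only the measured atoms by 2 A; fit atoms untouched
        traj = make_protein_traj(n_residues=8, n_frames=2)
        frames = traj.frames.copy()
        meas = traj.select(parse_selection("resid 7-8"))
        frames[1, meas, 2] += 2.0
        moved = TrajectoryCoords(atoms=traj.atoms, frames=frames, dt=1.0)
        fit = parse_selection("resid 1-6")
        series = loop_rmsd_series(moved, moved.frames[0], fit, parse_selection("resid 7-8"))
        assert series[0] == pytest.approx(0.0, abs=1e-12)
        # fit selection is unchanged, so the fit is identity and RMSD is the direct formula
        expected = np.sqrt(np.mean(np.sum((frames[1, meas] - frames[0, meas]) ** 2, axis=1)))
        assert series[1] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(2.0, abs=1e-12)

    def test_empty_selection(self, toy_traj):
        with pytest.raises(ValueError, match="zero atoms"):
            loop_rmsd_series(toy_traj, toy_traj.frames[0], is_backbone,
                             parse_selection("resid 500-600"))

    def test_pairwise_matrix(self, rng):
        traj = make_protein_traj(n_frames=3)
        frames = traj.frames.copy()
        frames[2, :, 0] += rng.normal(0, 1, frames.shape[1])
        traj = TrajectoryCoords(atoms=traj.atoms, frames=frames, dt=1.0)
        mat = loop_rmsd_series(traj, traj.frames[0], is_backbone, is_backbone, pairwise=True)
        assert mat.shape == (3, 3)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 0.0)
        assert mat[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert mat[0, 2] > 0.1


class TestBackboneRmsf:
    def test_static_zero(self, toy_traj):
        rmsf = backbone_rmsf(toy_traj, is_backbone, is_backbone)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in rmsf.values())

    def test_two_point_alternation(self):
        traj = make_protein_traj(n_residues=6, n_frames=200)
        frames = traj.frames.copy()
        d = 0.4  # small so the global fit barely moves
        frames[::2, 0, 0] += d
        frames[1::2, 0, 0] -= d
        traj = TrajectoryCoords(atoms=traj.atoms, frames=frames, dt=1.0)
        rmsf = backbone_rmsf(traj, parse_selection("resid 2-6"), is_backbone)
        first_res = traj.atoms[0].residue_id
        assert rmsf[first_res] == pytest.approx(d / 4, rel=0.05)  # one of 4 atoms moves by +-d
        assert all(v < 0.02 for resid, v in rmsf.items() if resid != first_res)

    def test_rigid_motion_invariance(self, rng):
        traj = make_protein_traj(n_frames=5)
        frames = traj.frames.copy()
        frames += rng.normal(0, 0.2, frames.shape)
        base = TrajectoryCoords(atoms=traj.atoms, frames=frames, dt=1.0)
        moved_frames = np.stack([
            f @ random_rotation(rng).T + rng.normal(size=3) * 7 for f in frames
        ])
        moved = TrajectoryCoords(atoms=traj.atoms, frames=moved_frames, dt=1.0)
        a = backbone_rmsf(base, is_backbone, is_backbone)
        b = backbone_rmsf(moved, is_backbone, is_backbone)
        for resid in a:
            assert b[resid] == pytest.approx(a[resid], abs=1e-9)

    def test_single_frame_rejected(self):
        traj = make_protein_traj(n_frames=1)
        with pytest.raises(ValueError, match="2 frames"):
            backbone_rmsf(traj, is_backbone, is_backbone)


class TestDihedral:
    def test_cis_zero(self):
        assert dihedral_angle([1, 1, 0], [1, 0, 0], [-1, 0, 0], [-1, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_trans_180(self):
        assert dihedral_angle([1, 1, 0], [1, 0, 0], [-1, 0, 0], [-1, -1, 0]) == pytest.approx(180.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_plane_normal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 3
        assert dihedral_angle(*pts) == pytest.approx(dihedral_oracle(*pts), abs=1e-9)

    def test_series_from_trajectory(self):
        traj = make_protein_traj(n_residues=4, n_frames=3, first_resid=87)
        series = compute_dihedral_series(traj, psi_hinge_quadruple(88), "psi88")
        assert len(series) == 3
        expected = dihedral_oracle(
            *(traj.frames[0][traj.select(lambda a, r=r, n=n: a.residue_id == r and a.atom_name == n)[0]]
              for r, n in psi_hinge_quadruple(88))
        )
        assert series.angles[0] == pytest.approx(expected, abs=1e-9)

    def test_missing_atom(self):
        traj = make_protein_traj(n_residues=3, first_resid=1)
        with pytest.raises(ValueError, match="not found"):
            compute_dihedral_series(traj, phi_hinge_quadruple(96), "phi96")


class TestAssignStates:
    def test_modal_za1(self):
        psi = DihedralSeries(angles=np.array([50.0]), definition="psi")
        phi = DihedralSeries(angles=np.array([-150.0]), definition="phi")
        assert assign_states_dihedral(psi, phi).labels[0] == ZA1

    def test_modal_za2(self):
        psi = DihedralSeries(angles=np.array([-40.0]), definition="psi")
        phi = DihedralSeries(angles=np.array([-60.0]), definition="phi")
        assert assign_states_dihedral(psi, phi).labels[0] == ZA2

    def test_conflicting_hinges_unassigned(self):
        psi = DihedralSeries(angles=np.array([50.0]), definition="psi")
        phi = DihedralSeries(angles=np.array([-60.0]), definition="phi")
        assert assign_states_dihedral(psi, phi).labels[0] == UNASSIGNED

    def test_length_mismatch(self):
        psi = DihedralSeries(angles=np.array([50.0, 50.0]), definition="psi")
        phi = DihedralSeries(angles=np.array([-150.0]), definition="phi")
        with pytest.raises(ValueError, match="aligned"):
            assign_states_dihedral(psi, phi)

    def test_recovers_hidden_trace(self):
        leg = LegGeneratorConfig(mu=0, sigma=1, rho=0.0, n_frames=20_000, n_replicas=1, seed=0)
        _, hidden, psi, phi = generate_two_state_system(
            leg, TwoStateConfig(k12=0.005, k21=0.002, kappa=200.0, seed=1))
        called = assign_states_dihedral(psi, phi)
        smoothed = smooth_trace(called, min_dwell=5)
        agreement = np.mean(smoothed.labels == hidden.labels)
        assert agreement >= 0.99

    def test_rmsd_classifier(self):
        trace = assign_states_rmsd(np.array([0.5, 3.0, 2.5, 2.6]), cutoff=2.5)
        assert list(trace.labels) == [ZA1, ZA2, ZA1, ZA2]


class TestTransitionStats:
    def test_constructed_trace(self):
        labels = np.array([ZA1] * 25 + [ZA2] * 75, dtype=object)
        stats = transition_stats(StateTrace(labels=labels, dt=1000.0), min_dwell=1)
        assert stats.occupancy[ZA2] == pytest.approx(0.75)
        assert len(stats.events) == 1
        assert stats.events[0].time_ns == pytest.approx(25.0)
        assert stats.first_za1_to_za2_ns == pytest.approx(25.0)
        assert stats.n_reverse == 0

    def test_strict_alternation_smoothed_away(self):
        labels = np.array([ZA1, ZA2] * 20, dtype=object)
        stats = transition_stats(StateTrace(labels=labels), min_dwell=3)
        assert len(stats.events) == 0
        assert set(stats.smoothed.labels) == {ZA1}

    def test_flicker_inherits_previous(self):
        labels = np.array([ZA1] * 10 + [ZA2] * 2 + [ZA1] * 10 + [ZA2] * 10, dtype=object)
        stats = transition_stats(StateTrace(labels=labels), min_dwell=5)
        assert len(stats.events) == 1
        assert stats.events[0].frame == 22

    def test_occupancy_ignores_unassigned(self):
        labels = np.array([ZA1, UNASSIGNED, ZA2, ZA2], dtype=object)
        stats = transition_stats(StateTrace(labels=labels), min_dwell=1)
        assert stats.occupancy[ZA1] == pytest.approx(1 / 3)
        assert stats.occupancy[ZA2] == pytest.approx(2 / 3)
        assert stats.occupancy[ZA1] + stats.occupancy[ZA2] == pytest.approx(1.0)

    def test_all_unassigned_rejected(self):
        labels = np.array([UNASSIGNED, UNASSIGNED], dtype=object)
        with pytest.raises(ValueError, match="UNASSIGNED"):
            transition_stats(StateTrace(labels=labels))

    def test_reverse_event_count(self):
        labels = np.array([ZA1] * 10 + [ZA2] * 10 + [ZA1] * 10 + [ZA2] * 10, dtype=object)
        stats = transition_stats(StateTrace(labels=labels), min_dwell=2)
        assert stats.n_reverse == 1

    def test_mean_first_transition_geometric(self):
        k12 = 0.02
        dt = 100.0  # ps
        traces = []
        for seed in range(300):
            leg = LegGeneratorConfig(mu=0, sigma=0, rho=0.0, n_frames=1500,
                                     n_replicas=1, dt=dt, seed=seed)
            _, trace, _, _ = generate_two_state_system(
                leg, TwoStateConfig(k12=k12, k21=0.0, seed=7000 + seed))
            traces.append(trace)
        mean_ns, sem_ns, n_missing = mean_first_transition_time(traces, min_dwell=1)
        assert n_missing == 0
        expected_ns = (1 / k12) * dt / 1000.0
        assert mean_ns == pytest.approx(expected_ns, rel=0.10)


class TestPairDistance:
    def test_345(self):
        traj = make_protein_traj(n_residues=2, n_frames=1)
        frames = traj.frames.copy()
        frames[0, 0] = [0.0, 0, 0]
        frames[0, 4] = [3.0, 4, 0]
        traj = TrajectoryCoords(atoms=traj.atoms, frames=frames, dt=1.0)
        d = pair_distance_series(traj, (traj.atoms[0].residue_id, "N"),
                                 (traj.atoms[4].residue_id, "N"))
        assert d[0] == pytest.approx(5.0)

    def test_coincident_zero(self):
        traj = make_protein_traj(n_residues=2, n_frames=1)
        frames = traj.frames.copy()
        frames[0, 4] = frames[0, 0]
        traj = TrajectoryCoords(atoms=traj.atoms, frames=frames, dt=1.0)
        d = pair_distance_series(traj, (traj.atoms[0].residue_id, "N"),
                                 (traj.atoms[4].residue_id, "N"))
        assert d[0] == 0.0

    def test_rigid_invariance(self, rng):
        traj = make_protein_traj(n_residues=3, n_frames=2)
        frames = traj.frames.copy()
        frames[1] = frames[1] @ random_rotation(rng).T + rng.normal(size=3) * 9
        traj = TrajectoryCoords(atoms=traj.atoms, frames=frames, dt=1.0)
        d = pair_distance_series(traj, (traj.atoms[0].residue_id, "N"),
                                 (traj.atoms[5].residue_id, "CA"))
        assert d[0] == pytest.approx(d[1], abs=1e-9)

    def test_missing_atom(self, toy_traj):
        with pytest.raises(ValueError, match="not found"):
            pair_distance_series(toy_traj, (1, "N"), (999, "CA"))


class TestPdbRoundTrip:
    def test_multimodel_round_trip(self, rng):
        traj = make_protein_traj(n_residues=4, n_frames=3, first_resid=76)
        frames = traj.frames + rng.normal(0, 0.5, traj.frames.shape)
        traj = TrajectoryCoords(atoms=traj.atoms, frames=frames, dt=2.0)
        text = to_pdb_text(traj)
        back = read_multimodel_pdb(text, dt=2.0)
        assert back.n_frames == 3
        assert [a.residue_id for a in back.atoms] == [a.residue_id for a in traj.atoms]
        assert [a.atom_name for a in back.atoms] == [a.atom_name for a in traj.atoms]
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)  # PDB has 3 decimals


class TestSelections:
    def test_backbone(self, toy_traj):
        idx = toy_traj.select(is_backbone)
        assert len(idx) == len(toy_traj.atoms)  # toy protein is backbone-only

    def test_resid_range_and_backbone(self, toy_traj):
        pred = parse_selection("resid 2-3 and backbone")
        idx = toy_traj.select(pred)
        assert all(2 <= toy_traj.atoms[i].residue_id <= 3 for i in idx)
        assert len(idx) == 8

    def test_bad_clause(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_selection("chain A")
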