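"""Trajectory statistics: superposition, RMSD/RMSF/Rg, distances, SASA,
H-bonds, DCC, and the distance-landscape KDE."""

import numpy as np
import pytest

from coev import metrics, synth
from coev.metrics import (
    ElementDef,
    MetricError,
    dcc_matrix,
    dcc_matrix_bruteforce,
    distance_landscape,
    golden_spiral_points,
    group_distance_series,
    hbond_count_series,
    ligand_sasa_series,
    rg_series,
    rmsd_series,
    rmsf_profile,
    shrake_rupley_sasa,
    sasa_montecarlo,
    superpose,
)
from coev.structure import ResidueSelection, Structure
from coev.traj import Trajectory, concatenate


def _chain_traj(frames, resnums=None, names=None, elements=None, het=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    top = Structure(
        names=np.array(names or ["CA"] * n),
        elements=np.array(elements or ["C"] * n),
        coords=frames[0].copy(),
        resnums=np.array(resnums if resnums is not None else range(1, n + 1)),
        resnames=np.array(["ALA"] * n),
        chains=np.array(["A"] * n),
        is_het=np.array(het if het is not None else [False] * n),
    )
    return Trajectory(topology=top, frames=frames)


def _rot_z(deg):
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t), 0],
                     [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])


class TestSuperpose:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.ref = rng.normal(scale=4.0, size=(12, 3))
        self.idx = np.arange(12)

    def test_rigid_motion_removed(self):
        frame = self.ref @ _rot_z(90).T + np.array([1.0, 2.0, 3.0])
        moved, R, rmsd = superpose(frame, self.ref, self.idx)
        assert rmsd <= 1e-9
        assert np.allclose(moved, self.ref, atol=1e-9)

    def test_identity_transform(self):
        moved, R, rmsd = superpose(self.ref, self.ref, self.idx)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_mirror_gets_proper_rotation(self):
        mirrored = self.ref * np.array([-1.0, 1.0, 1.0])
        moved, R, rmsd = superpose(mirrored, self.ref, self.idx)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1  # a reflection cannot be undone by rotation

    def test_mirror_rotation_is_global_minimum(self):
        # brute-force over many random rotations confirms Kabsch optimality
        mirrored = self.ref * np.array([-1.0, 1.0, 1.0])
        _, _, rmsd = superpose(mirrored, self.ref, self.idx)
        rng = np.random.default_rng(2)
        cm = mirrored - mirrored.mean(0)
        cr = self.ref - self.ref.mean(0)
        for _ in range(300):
            A = rng.normal(size=(3, 3))
            Q, _r = np.linalg.qr(A)
            if np.linalg.det(Q) < 0:
                Q[:, 0] = -Q[:, 0]
            trial = np.sqrt(((cm @ Q.T - cr) ** 2).sum(1).mean())
            assert trial >= rmsd - 1e-9

    def test_too_few_atoms(self):
        with pytest.raises(MetricError):
            superpose(self.ref, self.ref, np.array([0, 1]))

    def test_collinear_selection(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(MetricError, match="collinear"):
            superpose(line, line, np.arange(4))


class TestRmsd:
    def test_static_copies_zero(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(10, 3))
        traj = _chain_traj(np.repeat(ref[None], 5, axis=0))
        assert np.allclose(rmsd_series(traj).values, 0.0, atol=1e-9)

    def test_two_atom_hand_example(self):
        # ref atoms at x=0,1; frame at x=0,3: centered deviations are 1.0
        frames = np.zeros((2, 2, 3))
        frames[0, 1, 0] = 1.0
        frames[1, 1, 0] = 3.0
        traj = _chain_traj(frames)
        vals = rmsd_series(traj, ref=frames[0],
                           selection=np.array([0, 1])).values
        assert vals[0] == pytest.approx(0.0, abs=1e-9)
        assert vals[1] == pytest.approx(1.0, abs=1e-9)

    def test_rigid_contamination_removed(self):
        spec = synth.GaussianTrajSpec(n_residues=40, n_frames=300, sigma=0.4,
                                      seed=8, rigid_contamination=True)
        dirty, truth = synth.make_gaussian_trajectory(spec)
        clean = truth["clean_trajectory"]
        r_dirty = rmsd_series(dirty).values
        r_clean = rmsd_series(clean).values
        assert np.abs(r_dirty - r_clean).max() < 1e-6


class TestRmsf:
    def test_static_trajectory_zero(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(8, 3))
        traj = _chain_traj(np.repeat(ref[None], 4, axis=0))
        _, vals = rmsf_profile(traj)
        assert np.allclose(vals, 0.0, atol=1e-9)

    def test_single_frame_error(self):
        traj = _chain_traj(np.zeros((1, 5, 3)) + np.arange(5)[None, :, None])
        with pytest.raises(MetricError):
            rmsf_profile(traj)

    def test_oscillating_atom_unit_rmsf(self):
        rng = np.random.default_rng(5)
        base = rng.normal(scale=5.0, size=(20, 3))
        frames = np.repeat(base[None], 6, axis=0)
        frames[::2, 0, 0] = base[0, 0] + 1.0   # atom 0 oscillates +/-1 in x
        frames[1::2, 0, 0] = base[0, 0] - 1.0
        traj = _chain_traj(frames)
        # fit on the pinned atoms so the oscillation is not absorbed
        resnums, vals = rmsf_profile(traj, fit_selection=np.arange(1, 20))
        assert vals[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(vals[1:] < 1e-9)

    def test_isotropic_gaussian_limit(self, big_gaussian_traj):
        # RMSF -> sigma*sqrt(3) for isotropic fluctuation of sigma per axis
        traj, truth = big_gaussian_traj
        _, vals = rmsf_profile(traj)
        expected = truth["sigma"][0] * np.sqrt(3)
        assert vals.mean() == pytest.approx(expected, rel=0.02)


class TestRg:
    def test_two_equal_masses_two_angstrom(self):
        frames = np.zeros((1, 2, 3))
        frames[0, 1, 0] = 2.0
        assert rg_series(_chain_traj(frames)).values[0] == pytest.approx(1.0)

    def test_single_atom_zero(self):
        assert rg_series(_chain_traj(np.zeros((1, 1, 3)))).values[0] == 0.0

    def test_four_face_positions(self):
        frames = np.array([[[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0.0]]])
        assert rg_series(_chain_traj(frames)).values[0] == pytest.approx(1.0)


class TestGroupDistanceSeries:
    def _two_res_traj(self, frames):
        return _chain_traj(frames, resnums=[1, 2])

    def test_static_equals_static_distance(self):
        frames = np.zeros((3, 2, 3))
        frames[:, 1, 0] = 7.0
        ts = group_distance_series(
            self._two_res_traj(frames),
            ResidueSelection({("A", 1)}), ResidueSelection({("A", 2)}))
        assert np.allclose(ts.values, 7.0)

    def test_linear_separation(self):
        frames = np.zeros((4, 2, 3))
        frames[:, 1, 0] = 5.0 + np.arange(4)
        ts = group_distance_series(
            self._two_res_traj(frames),
            ResidueSelection({("A", 1)}), ResidueSelection({("A", 2)}))
        assert np.allclose(ts.values, [5, 6, 7, 8])

    def test_per_frame_rigid_invariance(self):
        rng = np.random.default_rng(7)
        frames = rng.normal(scale=4.0, size=(5, 6, 3))
        traj = _chain_traj(frames, resnums=[1, 1, 1, 2, 2, 2])
        a, b = ResidueSelection({("A", 1)}), ResidueSelection({("A", 2)})
        d0 = group_distance_series(traj, a, b).values
        moved = frames.copy()
        for t in range(5):
            A = rng.normal(size=(3, 3))
            Q, _ = np.linalg.qr(A)
            if np.linalg.det(Q) < 0:
                Q[:, 0] = -Q[:, 0]
            moved[t] = frames[t] @ Q.T + rng.uniform(-8, 8, 3)
        d1 = group_distance_series(
            _chain_traj(moved, resnums=[1, 1, 1, 2, 2, 2]), a, b).values
        assert np.abs(d1 - d0).max() <= 1e-9


class TestSasa:
    def test_isolated_atom_closed_form(self):
        coords = np.array([[0.0, 0, 0]])
        radii = np.array([1.7])
        area = shrake_rupley_sasa(coords, radii, np.array([0]))[0]
        exact = 4 * np.pi * 3.1 ** 2
        assert area == pytest.approx(exact, rel=0.005)

    def test_fully_enclosed_atom_zero(self):
        shell = []
        for t in np.linspace(0.15, np.pi - 0.15, 8):
            for p in np.linspace(0, 2 * np.pi, 12, endpoint=False):
                shell.append([4 * np.sin(t) * np.cos(p),
                              4 * np.sin(t) * np.sin(p), 4 * np.cos(t)])
        coords = np.vstack([[[0.0, 0, 0]], shell])
        radii = np.concatenate([[1.7], [3.0] * len(shell)])
        assert shrake_rupley_sasa(coords, radii, np.array([0]))[0] == 0.0

    def test_two_atom_toy_versus_monte_carlo(self):
        coords = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        radii = np.array([1.7, 1.55])
        sr = shrake_rupley_sasa(coords, radii, np.array([0, 1]))
        mc = sasa_montecarlo(coords, radii, np.array([0, 1]),
                             n_points=100_000, seed=1)
        assert np.all(np.abs(sr - mc) / mc < 0.01)

    def test_sphere_points_are_unit_norm(self):
        pts = golden_spiral_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_ligand_series_and_missing_radius(self):
        frames = np.zeros((2, 2, 3))
        frames[:, 1, 0] = 50.0  # far apart: both fully exposed
        traj = _chain_traj(frames, resnums=[900, 1], names=["C1", "CA"],
                           het=[True, False])
        traj.topology.resnames = np.array(["CGP", "ALA"])
        ts = ligand_sasa_series(traj, "CGP")
        assert np.allclose(ts.values, 4 * np.pi * 3.1 ** 2, rtol=1e-9)


class TestHbonds:
    def _traj(self, o_x, with_h=True, h_pos=None):
        names = ["N1", "O"] + (["H1"] if with_h else [])
        elements = ["N", "O"] + (["H"] if with_h else [])
        het = [True, False] + ([True] if with_h else [])
        coords = [[0.0, 0, 0], [o_x, 0, 0]]
        if with_h:
            coords.append(h_pos if h_pos is not None else [1.0, 0, 0])
        frames = np.array([coords])
        resnums = [900, 1] + ([900] if with_h else [])
        traj = _chain_traj(frames, resnums=resnums, names=names,
                           elements=elements, het=het)
        traj.topology.resnames = np.array(
            ["CGP", "ALA"] + (["CGP"] if with_h else []))
        return traj

    def test_linear_geometry_counted(self):
        # N...O at 2.9 A with H on the axis: angle 180 >= 150
        ts = hbond_count_series(self._traj(2.9), "CGP")
        assert ts.values[0] == 1

    def test_distance_rule_rejects(self):
        ts = hbond_count_series(self._traj(3.6), "CGP")
        assert ts.values[0] == 0

    def test_bent_geometry_rejected(self):
        # H displaced sideways: D-H...A angle well below 150
        ts = hbond_count_series(self._traj(2.9, h_pos=[0.0, 1.0, 0]), "CGP")
        assert ts.values[0] == 0

    def test_no_hydrogens_distance_only(self):
        ts = hbond_count_series(self._traj(2.9, with_h=False), "CGP")
        assert ts.values[0] == 1

    def test_apolar_ligand_constant_zero(self):
        frames = np.zeros((3, 2, 3))
        frames[:, 1, 0] = 3.0
        traj = _chain_traj(frames, resnums=[900, 1], names=["C1", "O"],
                           elements=["C", "O"], het=[True, False])
        traj.topology.resnames = np.array(["CGP", "ALA"])
        assert np.all(hbond_count_series(traj, "CGP").values == 0)


class TestDcc:
    def test_unit_diagonal_and_symmetry(self, big_gaussian_traj):
        traj, _ = big_gaussian_traj
        sub = Trajectory(topology=traj.topology, frames=traj.frames[:2000])
        dcc = dcc_matrix(sub)
        assert np.allclose(np.diag(dcc), 1.0)
        assert np.allclose(dcc, dcc.T)
        assert dcc.min() >= -1.0 and dcc.max() <= 1.0

    def test_identical_and_negated_streams(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(200, 3))
        n_anchor = 30
        anchors = rng.normal(scale=8.0, size=(n_anchor, 3))
        frames = np.zeros((200, 3 + n_anchor, 3))
        frames[:, 0] = base
        frames[:, 1] = 20.0 + base          # identical fluctuations
        frames[:, 2] = 40.0 - base          # negated
        frames[:, 3:] = anchors[None]       # rigid core pins the fit
        traj = _chain_traj(frames)
        dcc = dcc_matrix(traj, selection=np.arange(3),
                         fit_selection=np.arange(3, 3 + n_anchor))
        assert dcc[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert dcc[0, 2] == pytest.approx(-1.0, abs=1e-9)

    def test_planted_rho_recovery(self, big_gaussian_traj):
        traj, truth = big_gaussian_traj
        dcc = dcc_matrix(traj)
        ((key, rho),) = truth["rho"].items()
        i, j = (int(v) for v in key.split(","))
        assert abs(dcc[i, j] - rho) < 0.05

    def test_matches_naive_oracle(self):
        spec = synth.GaussianTrajSpec(n_residues=6, n_frames=40, sigma=0.5,
                                      rho={(1, 4): 0.6}, seed=10)
        traj, _ = synth.make_gaussian_trajectory(spec)
        fast = dcc_matrix(traj)
        slow = dcc_matrix_bruteforce(traj)
        assert np.abs(fast - slow).max() < 1e-10

    def test_zero_variance_atom_guard(self):
        frames = np.zeros((50, 4, 3))
        frames[:, :3] = np.random.default_rng(11).normal(size=(50, 3, 3))
        # atom 3 never moves relative to the fit; after superposition its
        # variance is tiny but nonzero, so pin it exactly:
        traj = _chain_traj(frames)
        dcc = dcc_matrix(traj, selection=np.arange(4))
        assert np.all(np.isfinite(dcc))


class TestLandscape:
    def test_single_mode_recovered(self, landscape_traj_single):
        traj, truth = landscape_traj_single
        land = distance_landscape([traj], synth.LANDSCAPE_ELEMENTS)
        assert len(land.modes) >= 1
        mx, my, _ = land.modes[0]
        hx, hy = land.bandwidths
        assert abs(mx - 11.0) <= max(hx, 0.1)
        assert abs(my - 13.0) <= max(hy, 0.1)

    def test_density_integrates_to_one(self, landscape_traj_single):
        traj, _ = landscape_traj_single
        land = distance_landscape([traj], synth.LANDSCAPE_ELEMENTS)
        step = (land.x[1] - land.x[0]) * (land.y[1] - land.y[0])
        assert land.density.sum() * step == pytest.approx(1.0, abs=0.01)

    def test_bimodal_mixture_two_modes(self, landscape_traj_bimodal):
        traj, truth = landscape_traj_bimodal
        land = distance_landscape([traj], synth.LANDSCAPE_ELEMENTS)
        strong = [m for m in land.modes
                  if m[2] > 0.25 * land.modes[0][2]]
        assert len(strong) == 2
        centers = sorted((m[0], m[1]) for m in strong)
        hx, hy = land.bandwidths
        assert abs(centers[0][0] - 10.0) <= max(3 * hx, 0.2)
        assert abs(centers[0][1] - 9.0) <= max(3 * hy, 0.2)
        assert abs(centers[1][0] - 14.0) <= max(3 * hx, 0.2)
        assert abs(centers[1][1] - 13.0) <= max(3 * hy, 0.2)

    def test_grid_refinement_stability(self, landscape_traj_single):
        traj, _ = landscape_traj_single
        coarse = distance_landscape([traj], synth.LANDSCAPE_ELEMENTS,
                                    grid_step=0.2)
        fine = distance_landscape([traj], synth.LANDSCAPE_ELEMENTS,
                                  grid_step=0.1)
        assert abs(coarse.modes[0][0] - fine.modes[0][0]) < 0.2
        assert abs(coarse.modes[0][1] - fine.modes[0][1]) < 0.2

    def test_degenerate_identical_frames(self):
        spec = synth.GaussianTrajSpec(
            n_frames=2, landscape_modes=[(11.0, 13.0, 1.0, 0.3)], seed=1)
        traj, _ = synth.make_gaussian_trajectory(spec)
        traj.frames[1] = traj.frames[0]
        land = distance_landscape([traj], synth.LANDSCAPE_ELEMENTS)
        assert land.degenerate and len(land.modes) == 1

    def test_pooling_equals_concatenation(self, landscape_traj_bimodal):
        traj, _ = landscape_traj_bimodal
        half = traj.n_frames // 2
        t1 = Trajectory(topology=traj.topology, frames=traj.frames[:half],
                        replicate_id="r1")
        t2 = Trajectory(topology=traj.topology, frames=traj.frames[half:],
                        replicate_id="r2")
        split = distance_landscape([t1, t2], synth.LANDSCAPE_ELEMENTS)
        whole = distance_landscape([traj], synth.LANDSCAPE_ELEMENTS)
        assert np.allclose(split.density, whole.density)

    def test_missing_element_range(self, landscape_traj_single):
        traj, _ = landscape_traj_single
        bad = ElementDef(ranges={"beta3": (1, 3), "alpha4": (4, 6)})
        with pytest.raises(KeyError):
            distance_landscape([traj], bad)


class TestPooling:
    def test_dcc_order_free_pooling(self):
        spec = synth.GaussianTrajSpec(n_residues=10, n_frames=400, sigma=0.5,
                                      seed=12)
        traj, _ = synth.make_gaussian_trajectory(spec)
        t1 = Trajectory(topology=traj.topology, frames=traj.frames[:200])
        t2 = Trajectory(topology=traj.topology, frames=traj.frames[200:])
        pooled = metrics.pooled_dcc([t1, t2])
        direct = dcc_matrix(concatenate([t1, t2]))
        assert np.allclose(pooled, direct)
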