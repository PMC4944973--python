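import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endstate.core import Trajectory
from endstate.synthetic import (FluctuationSpec, ToyComplexSpec,
                                internal_mode_direction, make_toy_complex,
                                make_trajectory)
from endstate.trajectory import (OhPiCriterion, UnderdeterminedError,
                                 oh_pi_occupancy, pca, porcupine_export,
                                 read_porcupine, rmsf, rotation_angle,
                                 superpose)


def _rotation(theta, axis="z"):
    c, s = np.cos(theta), np.sin(theta)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


class TestSuperpose:
    def test_identical_structures_zero_rmsd(self, toy):
        _, coords, _ = toy
        _, rmsd = superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_rotation(self, toy):
        _, coords, _ = toy
        moved = coords @ _rotation(np.radians(30.0)).T + np.array([5.0, 6, 7])
        out, rmsd = superpose(moved, coords)
        assert rmsd < 1e-9
        assert np.allclose(out, coords, atol=1e-9)

    def test_mirror_image_keeps_positive_rmsd(self, toy):
        _, coords, _ = toy
        mirror = coords.copy()
        mirror[:, 0] *= -1.0
        _, rmsd = superpose(mirror, coords)
        assert rmsd > 0.1

    def test_underdetermined_selection_raises(self, toy):
        _, coords, _ = toy
        with pytest.raises(UnderdeterminedError):
            superpose(coords, coords, selection=[0, 1])


class TestRmsf:
    def test_static_trajectory_all_zero(self, toy):
        topology, coords, _ = toy
        traj = make_trajectory(topology, coords, FluctuationSpec(
            n_frames=10, isotropic_sigma=0.0, seed=0))
        vals, flagged = rmsf(traj, range(topology.n_atoms))
        assert not flagged
        assert np.max(vals) == pytest.approx(0.0, abs=1e-12)

    def test_single_frame_flagged(self, toy):
        topology, coords, _ = toy
        traj = Trajectory(topology, coords[None], np.array([10.0]))
        vals, flagged = rmsf(traj, range(topology.n_atoms))
        assert flagged and np.all(vals == 0.0)

    def test_jittered_atom_recovers_sigma_sqrt3(self):
        # large system, jitter one central atom: the mean-structure fit then
        # absorbs a negligible share of the planted variance
        topology, coords, _ = make_toy_complex(ToyComplexSpec(
            ("ALA",) * 8, ("ALA",) * 8))
        target = topology.n_atoms // 2
        sigma = 0.2
        rng = np.random.default_rng(9)
        frames = np.repeat(coords[None], 5000, axis=0)
        frames[:, target, :] += rng.normal(0, sigma, size=(5000, 3))
        traj = Trajectory(topology, frames, 10.0 * np.arange(1, 5001))
        vals, _ = rmsf(traj, range(topology.n_atoms))
        assert vals[target] == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_rmsf_squared_sums_to_covariance_trace(self, toy):
        topology, coords, _ = toy
        traj = make_trajectory(topology, coords, FluctuationSpec(
            n_frames=300, isotropic_sigma=0.08, seed=2))
        sel = [i for i, a in enumerate(topology.atoms) if a.name == "CA"]
        vals, _ = rmsf(traj, sel)
        result = pca(traj, sel)
        assert np.sum(vals ** 2) == pytest.approx(result.eigenvalues.sum(),
                                                  rel=1e-9)


class TestPca:
    def test_planted_mode_recovery(self, toy):
        topology, coords, _ = toy
        direction = internal_mode_direction(coords, seed=0)
        lam = 0.5
        traj = make_trajectory(topology, coords, FluctuationSpec(
            n_frames=5000, isotropic_sigma=0.02,
            modes=((tuple(direction), lam),), seed=4))
        result = pca(traj, range(topology.n_atoms))
        assert result.eigenvalues[0] == pytest.approx(lam, rel=0.10)
        assert abs(result.eigenvectors[:, 0] @ direction) > 0.99

    def test_three_planted_modes_ordered_recovery(self, toy):
        topology, coords, _ = toy
        dirs = np.array([internal_mode_direction(coords, seed=s)
                         for s in (1, 2, 3)])
        q, _ = np.linalg.qr(dirs.T)
        dirs = q.T[:3]
        variances = (0.8, 0.4, 0.2)
        traj = make_trajectory(topology, coords, FluctuationSpec(
            n_frames=5000, isotropic_sigma=0.02,
            modes=tuple((tuple(d), v) for d, v in zip(dirs, variances)),
            seed=5))
        result = pca(traj, range(topology.n_atoms))
        for k, v in enumerate(variances):
            assert result.eigenvalues[k] == pytest.approx(v, rel=0.10)

    def test_static_trajectory_zero_eigenvalues(self, toy):
        topology, coords, _ = toy
        traj = make_trajectory(topology, coords, FluctuationSpec(
            n_frames=5, isotropic_sigma=0.0, seed=0))
        result = pca(traj, range(topology.n_atoms))
        assert np.max(result.eigenvalues) == pytest.approx(0.0, abs=1e-12)

    def test_eigenvectors_orthonormal_and_trace_conserved(self, toy_traj, toy):
        topology, _, _ = toy
        sel = [i for i, a in enumerate(topology.atoms) if a.name == "CA"]
        result = pca(toy_traj, sel)
        gram = result.eigenvectors.T @ result.eigenvectors
        assert np.max(np.abs(gram - np.eye(gram.shape[0]))) < 1e-8
        frames = result.projections  # centred coordinates in mode basis
        per_coord_var = np.var(frames @ result.eigenvectors.T, axis=0)
        assert result.eigenvalues.sum() == pytest.approx(per_coord_var.sum(),
                                                         rel=1e-9)


class TestPorcupine:
    def test_round_trip_and_direction(self, toy, tmp_path):
        topology, coords, _ = toy
        direction = internal_mode_direction(coords, seed=0)
        traj = make_trajectory(topology, coords, FluctuationSpec(
            n_frames=2000, isotropic_sigma=0.01,
            modes=((tuple(direction), 0.6),), seed=6))
        result = pca(traj, range(topology.n_atoms))
        path = porcupine_export(result, 0, 4.0, tmp_path / "mode0.txt")
        idx, pos, vec = read_porcupine(path)
        assert len(idx) == topology.n_atoms
        exported = result.eigenvectors[:, 0].reshape(-1, 3) * 4.0
        assert np.allclose(vec, exported, atol=1e-6)  # written precision
        # arrows parallel to the constructed direction
        cos = (vec.reshape(-1) @ direction) / np.linalg.norm(vec)
        assert abs(cos) > 0.99

    def test_out_of_range_mode_raises(self, toy, tmp_path):
        topology, coords, _ = toy
        traj = make_trajectory(topology, coords, FluctuationSpec(
            n_frames=10, isotropic_sigma=0.05, seed=1))
        result = pca(traj, range(topology.n_atoms))
        with pytest.raises(IndexError):
            porcupine_export(result, 10 ** 6, 1.0, tmp_path / "x.txt")


class TestRotationAngle:
    def _traj(self, frames_xyz):
        from conftest import ion_topology
        top = ion_topology([0.0] * 3, [1.5] * 3)
        frames = np.asarray(frames_xyz, float)
        return Trajectory(top, frames, 10.0 * np.arange(1, len(frames) + 1))

    def test_right_angle(self):
        traj = self._traj([[[1, 0, 0], [0, 0, 0], [0, 1, 0]]])
        series, mean, sd = rotation_angle(traj, 0, 1, 2)
        assert mean == pytest.approx(90.0, abs=1e-9)

    def test_colinear_gives_180(self):
        traj = self._traj([[[-1, 0, 0], [0, 0, 0], [2, 0, 0]]])
        _, mean, _ = rotation_angle(traj, 0, 1, 2)
        assert mean == pytest.approx(180.0, abs=1e-9)

    def test_alternating_angles_mean_and_sd(self):
        frames = []
        for k in range(100):
            a = np.radians(20.0 if k % 2 == 0 else 40.0)
            frames.append([[np.cos(a), np.sin(a), 0], [0, 0, 0], [1, 0, 0]])
        series, mean, sd = rotation_angle(self._traj(frames), 0, 1, 2)
        assert mean == pytest.approx(30.0, abs=1e-9)
        # sample (ddof=1) convention: 10.0·√(n/(n−1)) for alternating data
        assert sd == pytest.approx(10.0 * np.sqrt(100 / 99), abs=1e-9)

    def test_coincident_points_raise(self):
        traj = self._traj([[[0, 0, 0], [0, 0, 0], [1, 0, 0]]])
        with pytest.raises(ValueError):
            rotation_angle(traj, 0, 1, 2)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(1, 3, 3)) * 3.0
        traj = self._traj(base)
        _, mean1, _ = rotation_angle(traj, 0, 1, 2)
        theta = rng.uniform(0, 2 * np.pi)
        moved = base @ _rotation(theta, "x").T + rng.normal(size=3)
        _, mean2, _ = rotation_angle(self._traj(moved), 0, 1, 2)
        assert mean1 == pytest.approx(mean2, abs=1e-9)


@pytest.fixture(scope="module")
def system():
    topology, coords, _ = make_toy_complex(
        ToyComplexSpec(("SER",), ("PHE",), ((0, 0),), jitter=0.0))
    names = {a.name: i for i, a in enumerate(topology.atoms)
             if topology.atoms[i].chain_id == "B"}
    ring = [names[n] for n in ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")]
    o = next(i for i, a in enumerate(topology.atoms) if a.name == "OG")
    h = next(i for i, a in enumerate(topology.atoms) if a.name == "HG")
    return topology, coords, o, h, ring


class TestOhPi:
    def test_perpendicular_construction_is_strong(self, system):
        topology, coords, o, h, ring = system
        traj = Trajectory(topology, coords[None], np.array([10.0]))
        res = oh_pi_occupancy(traj, o, h, ring)
        assert res.distances[0] == pytest.approx(2.5, abs=0.01)
        assert res.angles[0] == pytest.approx(90.0, abs=0.5)
        assert res.occupancy == 1.0

    def test_beyond_distance_window_not_strong(self, system):
        topology, coords, o, h, ring = system
        far = coords.copy()
        far[[o, h]] += np.array([0.0, -1.1, 0.0])  # H–centroid → 3.6 Å
        traj = Trajectory(topology, far[None], np.array([10.0]))
        res = oh_pi_occupancy(traj, o, h, ring)
        assert res.distances[0] == pytest.approx(3.6, abs=0.01)
        assert res.occupancy == 0.0

    def test_occupancy_fraction_matches_per_frame_recheck(self, system):
        """100 frames, 40 constructed strong: occupancy 0.40, and every flag
        agrees with a brute-force recomputation of the two geometric tests."""
        topology, coords, o, h, ring = system
        frames = []
        for k in range(100):
            f = coords.copy()
            if k % 5 < 2:  # 40 strong frames: H kept at 2.5 Å above centroid
                pass
            else:  # pushed outside the distance window
                f[[o, h]] += np.array([0.0, -1.3, 0.0])
            frames.append(f)
        traj = Trajectory(topology, np.array(frames),
                          10.0 * np.arange(1, 101))
        crit = OhPiCriterion()
        res = oh_pi_occupancy(traj, o, h, ring, crit)
        assert res.occupancy == pytest.approx(0.40, abs=1e-12)
        for k in range(100):
            ring_xyz = traj.frames[k, ring, :]
            centroid = ring_xyz.mean(axis=0)
            d = np.linalg.norm(traj.frames[k, h] - centroid)
            u, s, vt = np.linalg.svd(ring_xyz - centroid)
            normal = vt[2]
            oh = traj.frames[k, h] - traj.frames[k, o]
            ang = np.degrees(np.arcsin(abs(oh @ normal) / np.linalg.norm(oh)))
            expect = (crit.dist_min <= d <= crit.dist_max
                      and crit.angle_min <= ang <= crit.angle_max)
            assert bool(res.flags[k]) == expect

    def test_ring_must_have_six_atoms(self, system):
        topology, coords, o, h, ring = system
        traj = Trajectory(topology, coords[None], np.array([10.0]))
        with pytest.raises(ValueError):
            oh_pi_occupancy(traj, o, h, ring[:5])
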