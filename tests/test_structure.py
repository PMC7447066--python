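"""Superposition, RMSD, RMSF, radius of gyration, COM separation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from psitraj.structure import (
    com_separation,
    pool_rmsf,
    radius_of_gyration,
    rmsd_series,
    rmsf_profile,
    summarize_series,
    superpose,
)
from psitraj.synthetic import SyntheticSpec, make_topology, make_trajectory

from conftest import toy_topology, toy_trajectory


def random_rigid_motion(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=2.0, size=3)
    return R, t


class TestSuperpose:
    def test_identity_on_self(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        R, t, moved = superpose(x, x)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(moved, x, atol=1e-10)

    def test_recovers_rigid_motion(self):
        """A rotated + translated copy superposes back to zero RMSD."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        R, t = random_rigid_motion(rng)
        y = x @ R.T + t
        _, _, moved = superpose(y, x)
        assert np.sqrt(np.mean(np.sum((moved - x) ** 2, axis=1))) < 1e-9

    def test_reflection_case_keeps_proper_rotation(self):
        """Mirrored coordinates force the det = +1 branch; RMSD stays > 0."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 3))
        y = x.copy()
        y[:, 2] *= -1  # improper transform of x
        R, _, moved = superpose(y, x)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        rmsd = np.sqrt(np.mean(np.sum((moved - x) ** 2, axis=1)))
        assert rmsd > 0.1  # a mirror image cannot be superposed exactly
        # brute force over random proper rotations: none beats the Kabsch fit
        yc = y - y.mean(0)
        xc = x - x.mean(0)
        for k in range(200):
            Rk = Rotation.random(random_state=np.random.RandomState(k)).as_matrix()
            r2 = np.sqrt(np.mean(np.sum((yc @ Rk.T - xc) ** 2, axis=1)))
            assert r2 >= rmsd - 1e-9

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 3))
        y = rng.normal(size=(20, 3))
        R, _, _ = superpose(y, x)
        rot, _ = Rotation.align_vectors(x - x.mean(0), y - y.mean(0))
        assert np.allclose(R, rot.as_matrix(), atol=1e-8)

    def test_degenerate_fit_set_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            superpose(line, line)
        with pytest.raises(ValueError, match="3 fit atoms"):
            superpose(line[:2], line[:2])


class TestRMSD:
    def test_static_trajectory_is_zero(self):
        spec = SyntheticSpec(seed=0, n_frames=4, sigma_nonloop=0.0, sigma_loop=0.0)
        traj = make_trajectory(spec)
        s = rmsd_series(traj)
        assert np.allclose(s.values, 0.0, atol=1e-12)

    def test_single_displaced_atom_closed_form(self):
        """One atom of an N-atom rigid body displaced by d, no fitting: d/sqrt(N)."""
        n, d = 16, 0.3
        rng = np.random.default_rng(4)
        base = rng.normal(size=(n, 3))
        moved = base.copy()
        moved[5, 0] += d
        top = toy_topology([("A", i + 1, "ALA", "CA") for i in range(n)])
        traj = toy_trajectory(top, np.stack([base, moved]))
        s = rmsd_series(traj, fit=False, measure_selection=np.arange(n))
        assert s.values[1] == pytest.approx(d / np.sqrt(n), rel=1e-9)

    def test_rigid_motion_invariance(self, dimer_trajectory):
        """Rotating + translating every frame leaves RMSD unchanged (<= 1e-6 nm)."""
        traj = dimer_trajectory
        rng = np.random.default_rng(5)
        moved = np.empty_like(traj.coords)
        for f in range(traj.n_frames):
            R, t = random_rigid_motion(rng)
            moved[f] = traj.coords[f] @ R.T + t
        t2 = toy_trajectory(traj.topology, moved, times=traj.times)
        a = rmsd_series(traj).values
        b = rmsd_series(t2).values
        assert np.abs(a - b).max() < 1e-6

    def test_summary_reports_replicate_count(self):
        s = summarize_series([np.array([0.1, 0.2]), np.array([0.2]), np.array([0.3])])
        assert s["n"] == 3
        assert s["mean"] == pytest.approx((0.15 + 0.2 + 0.3) / 3)


class TestRMSF:
    def test_static_trajectory_zero_both_modes(self):
        spec = SyntheticSpec(seed=0, n_frames=3, sigma_nonloop=0.0, sigma_loop=0.0)
        traj = make_trajectory(spec)
        for mode in ("raw", "pc1-filtered"):
            prof = rmsf_profile(traj, "A", mode=mode)
            assert np.allclose(prof.values, 0.0, atol=1e-9)

    def test_isotropic_jitter_closed_form(self):
        """Per-coordinate sigma 0.02 nm gives RMSF -> 0.02*sqrt(3) (10% at 5000 frames)."""
        spec = SyntheticSpec(seed=6, n_frames=5000, sigma_nonloop=0.02, sigma_loop=0.02)
        traj = make_trajectory(spec)
        prof = rmsf_profile(traj, "A", mode="raw")
        expected = 0.02 * np.sqrt(3)
        assert np.abs(prof.values - expected).max() / expected < 0.10

    def test_pc1_filter_bounded_by_raw(self, dimer_trajectory):
        raw = rmsf_profile(dimer_trajectory, "A", mode="raw").values
        filt = rmsf_profile(dimer_trajectory, "A", mode="pc1-filtered").values
        assert np.all(filt <= raw + 1e-12)

    def test_single_mode_motion_equals_raw(self):
        """Motion confined to one eigen-direction: the PC1 filter is lossless."""
        n = 6
        top = toy_topology([("A", i + 1, "ALA", "CA") for i in range(n)])
        base = np.arange(n * 3, dtype=float).reshape(n, 3) * 0.1
        direction = np.zeros((n, 3))
        direction[0] = [1.0, 0, 0]  # one collective coordinate
        amps = np.sin(np.linspace(0, 4 * np.pi, 40))
        frames = np.stack([base + a * 0.05 * direction for a in amps])
        traj = toy_trajectory(top, frames)
        raw = rmsf_profile(traj, "A", mode="raw", fit=False).values
        filt = rmsf_profile(traj, "A", mode="pc1-filtered", fit=False).values
        assert np.allclose(raw, filt, atol=1e-12)

    def test_planted_sigma_profile_recovery(self):
        """A graded per-residue amplitude profile is recovered (Spearman >= 0.95)."""
        n_res = 104
        sigma = np.linspace(0.01, 0.05, n_res)
        spec = SyntheticSpec(seed=8, n_frames=2000, sigma_profile=sigma)
        traj = make_trajectory(spec)
        pooled = pool_rmsf([rmsf_profile(traj, c, mode="raw") for c in ("A", "B")])
        rho = spearmanr(pooled["mean"], sigma).statistic
        assert rho >= 0.95
        # amplitude recovered up to the sqrt(3) isotropy factor
        ratio = pooled["mean"] / (sigma * np.sqrt(3))
        assert np.median(np.abs(ratio - 1.0)) < 0.1

    def test_too_few_frames_rejected(self, dimer_trajectory):
        one = toy_trajectory(
            dimer_trajectory.topology, dimer_trajectory.coords[:1],
            times=dimer_trajectory.times[:1],
        )
        with pytest.raises(ValueError, match="2 frames"):
            rmsf_profile(one, "A")


class TestRg:
    def test_two_unit_masses(self):
        top = toy_topology([("A", 1, "GLY", "C1"), ("A", 1, "GLY", "C2")])
        traj = toy_trajectory(top, np.array([[[0, 0, 0], [0.8, 0, 0]]]))
        s = radius_of_gyration(traj)
        assert s.values[0] == pytest.approx(0.4, rel=1e-12)

    def test_uniform_rod_closed_form(self):
        """N equal masses on a line of length L: Rg -> L/sqrt(12) (1% at N=1000)."""
        n, L = 1000, 2.0
        top = toy_topology([("A", 1, "GLY", f"C{i}") for i in range(n)])
        coords = np.zeros((1, n, 3))
        coords[0, :, 0] = np.linspace(0, L, n)
        traj = toy_trajectory(top, coords)
        s = radius_of_gyration(traj)
        assert abs(s.values[0] - L / np.sqrt(12)) / (L / np.sqrt(12)) < 0.01

    def test_rigid_motion_invariance(self, dimer_trajectory):
        traj = dimer_trajectory
        rng = np.random.default_rng(9)
        moved = np.empty_like(traj.coords)
        for f in range(traj.n_frames):
            R, t = random_rigid_motion(rng)
            moved[f] = traj.coords[f] @ R.T + t
        t2 = toy_trajectory(traj.topology, moved, times=traj.times)
        assert np.abs(
            radius_of_gyration(traj).values - radius_of_gyration(t2).values
        ).max() < 1e-6

    def test_empty_selection_rejected(self, dimer_trajectory):
        with pytest.raises(ValueError):
            radius_of_gyration(dimer_trajectory, selection=np.array([], dtype=int))


class TestCOMSeparation:
    def test_identical_groups_zero(self, dimer_trajectory):
        sel = dimer_trajectory.topology.select(chain="A")
        s = com_separation(dimer_trajectory, sel, sel)
        assert np.allclose(s.values, 0.0)

    def test_two_single_atoms(self):
        top = toy_topology([("A", 1, "GLY", "C1"), ("A", 2, "GLY", "C2")])
        traj = toy_trajectory(top, np.array([[[0, 0, 0], [0, 0, 1.5]]]))
        s = com_separation(traj, np.array([0]), np.array([1]))
        assert s.values[0] == pytest.approx(1.5)

    def test_equal_mass_pair_centroids(self):
        top = toy_topology([("A", 1, "GLY", f"C{i}") for i in range(4)])
        coords = np.array([[[0, 0, 0.5], [0, 0, -0.5], [0, 0, 1.5], [0, 0, 2.5]]])
        traj = toy_trajectory(top, coords)
        s = com_separation(traj, np.array([0, 1]), np.array([2, 3]))
        assert s.values[0] == pytest.approx(2.0)

    def test_empty_group_rejected(self, dimer_trajectory):
        with pytest.raises(ValueError):
            com_separation(dimer_trajectory, np.array([], dtype=int), np.array([0]))
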