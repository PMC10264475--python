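"""Kabsch superposition, RMSD schemes, averaging and RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from rehydra import align, synthetic
from rehydra.align import (
    MetricSeries,
    RMSDScheme,
    average_structure,
    kabsch_superpose,
    replica_mean_series,
    rmsd_series,
    rmsf_profile,
)
from rehydra.trajio import Condition, Frame, ReplicaSet, Trajectory

CHIRAL4 = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, 0.0, 3.0]]
)


def brute_force_min_rmsd(mobile, reference, n_grid=60_000, seed=5):
    """Independent oracle: minimise RMSD over a dense random rotation grid
    with a local polish, never via the Kabsch solution."""
    from scipy.optimize import minimize

    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    mats = Rotation.random(n_grid, random_state=np.random.default_rng(seed)).as_matrix()
    rotated = np.einsum("kij,nj->kni", mats, mob)
    rmsds = np.sqrt(np.mean(np.sum((rotated - ref) ** 2, axis=2), axis=1))
    best = Rotation.from_matrix(mats[np.argmin(rmsds)]).as_rotvec()

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec).apply(mob)
        return np.sqrt(np.mean(np.sum((r - ref) ** 2, axis=1)))

    res = minimize(objective, best, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return res.fun


class TestKabsch:
    def test_identity(self):
        res = kabsch_superpose(CHIRAL4, CHIRAL4)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_rigid_motion_recovered(self):
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = rot.apply(CHIRAL4) + np.array([5.0, 0.0, 0.0])
        res = kabsch_superpose(moved, CHIRAL4)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_mirror_image_matches_brute_force_not_zero(self):
        mirror = CHIRAL4 * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(mirror, CHIRAL4)
        assert res.rmsd > 0.5  # a reflection is not a rotation
        oracle = brute_force_min_rmsd(mirror, CHIRAL4)
        assert res.rmsd == pytest.approx(oracle, rel=1e-4)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_fitted_never_worse_than_unfitted(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 3)) * 3
        b = rng.normal(size=(8, 3)) * 3
        fitted = kabsch_superpose(a, b).rmsd
        unfitted = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert fitted <= unfitted + 1e-9

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(-180, 180),
        st.floats(-180, 180),
        st.floats(-50, 50),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rmsd_invariant_under_global_rigid_motion(self, seed, a1, a2, shift):
        """Applying one rigid motion to both structures leaves the fitted
        RMSD unchanged."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 3)) * 2
        b = rng.normal(size=(6, 3)) * 2
        base = kabsch_superpose(a, b).rmsd
        rot = Rotation.from_euler("xz", [a1, a2], degrees=True)
        moved = kabsch_superpose(rot.apply(a) + shift, rot.apply(b) + shift).rmsd
        assert moved == pytest.approx(base, abs=1e-8)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            kabsch_superpose(CHIRAL4[:2], CHIRAL4[:2])
        line = np.outer(np.arange(5.0), [1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_weighted_fit_prioritises_heavy_points(self):
        ref = CHIRAL4
        mob = CHIRAL4.copy()
        mob[3] += [0.0, 0.0, 2.0]
        w = np.array([1.0, 1.0, 1.0, 1e-6])
        res = kabsch_superpose(mob, ref, weights=w)
        # nearly all weight on unperturbed points -> tiny weighted rmsd
        assert res.rmsd < 1e-2


class TestRmsdSeries:
    @staticmethod
    def _traj_from_coords(topo, coords_list):
        return Trajectory(
            topo, [Frame(c, time=float(k)) for k, c in enumerate(coords_list)]
        )

    def test_static_first_frame_all_zero(self, toy5_calpha):
        topo, frame = toy5_calpha
        traj = self._traj_from_coords(topo, [frame.coordinates] * 4)
        s = rmsd_series(traj, RMSDScheme("first_frame"), selection="calpha")
        np.testing.assert_allclose(s.values, 0.0, atol=1e-9)

    def test_rigid_rotated_copies_zero(self, toy5_calpha):
        topo, frame = toy5_calpha
        coords = [
            Rotation.from_euler("xyz", [10 * k, 5 * k, -7 * k], degrees=True).apply(
                frame.coordinates
            )
            + k
            for k in range(5)
        ]
        s = rmsd_series(self._traj_from_coords(topo, coords), RMSDScheme("first_frame"))
        np.testing.assert_allclose(s.values, 0.0, atol=1e-9)

    def test_linear_morph_endpoint_oracle(self, toy20):
        topo, frame = toy20
        a = frame.coordinates
        rng = np.random.default_rng(2)
        b = a + rng.normal(scale=1.5, size=a.shape)
        coords = [a + t * (b - a) for t in np.linspace(0, 1, 11)]
        s = rmsd_series(self._traj_from_coords(topo, coords), RMSDScheme("first_frame"))
        assert np.all(np.diff(s.values) >= -1e-9)
        from rehydra.trajio import select_atoms

        ca = select_atoms(topo, "calpha")
        endpoint = kabsch_superpose(b[ca], a[ca]).rmsd
        assert s.values[-1] == pytest.approx(endpoint, rel=1e-9)

    def test_parent_mapped_needs_reference(self, toy5_calpha):
        topo, frame = toy5_calpha
        traj = self._traj_from_coords(topo, [frame.coordinates] * 2)
        scheme = RMSDScheme("parent_mapped", references=(Frame(frame.coordinates),))
        with pytest.raises(ValueError, match="replica"):
            rmsd_series(traj, scheme, replica_index=None)
        with pytest.raises(ValueError, match="replica 3"):
            rmsd_series(traj, scheme, replica_index=3)


class TestReplicaMean:
    def test_identical_series_unchanged_any_k(self):
        base = MetricSeries(times=[0.0, 1.0, 2.0], values=[1.0, 2.0, 3.0])
        for k in (1, 2, 5):
            mean = replica_mean_series([base] * k)
            np.testing.assert_allclose(mean.values, base.values)
            np.testing.assert_allclose(mean.sd, 0.0)

    def test_pointwise_mean(self):
        series = [
            MetricSeries(times=[0.0], values=[v]) for v in (1.0, 2.0, 3.0, 4.0, 5.0)
        ]
        assert replica_mean_series(series).values[0] == pytest.approx(3.0)

    def test_length_mismatch_errors(self):
        a = MetricSeries(times=[0.0, 1.0], values=[1.0, 1.0])
        b = MetricSeries(times=[0.0], values=[1.0])
        with pytest.raises(ValueError, match="points"):
            replica_mean_series([a, b])


class TestAverageStructure:
    def test_static_returns_frame(self, toy5_calpha):
        topo, frame = toy5_calpha
        traj = Trajectory(topo, [Frame(frame.coordinates, time=float(k)) for k in range(3)])
        avg = average_structure(traj)
        np.testing.assert_allclose(avg.coordinates, frame.coordinates, atol=1e-9)

    def test_symmetric_displacement_midpoint(self, toy20):
        topo, frame = toy20
        d = np.zeros_like(frame.coordinates)
        d[0] = [0.4, 0.0, 0.0]
        traj = Trajectory(
            topo,
            [Frame(frame.coordinates + d, 0.0), Frame(frame.coordinates - d, 1.0)],
        )
        # fit on the unmoved atoms so the superposition is exactly identity
        static = np.arange(1, topo.n_atoms)
        avg = average_structure(traj, selection=static)
        np.testing.assert_allclose(avg.coordinates, frame.coordinates, atol=1e-9)

    def test_jittered_mean_recovery(self, toy20):
        """The average structure converges on the true conformation at the
        Monte-Carlo rate (compared alignment-free, since the whole average
        inherits the arbitrary frame of the noisy fit reference)."""
        topo, frame = toy20
        rng = np.random.default_rng(8)
        sigma, n = 0.3, 400
        frames = [
            Frame(frame.coordinates + rng.normal(scale=sigma, size=frame.coordinates.shape), float(k))
            for k in range(n)
        ]
        avg = average_structure(Trajectory(topo, frames), selection="all")
        residual = kabsch_superpose(avg.coordinates, frame.coordinates).rmsd
        # E[rmsd] ≈ σ√(3/n); allow a generous factor for the fixed seed
        assert residual < 2.5 * sigma * np.sqrt(3.0 / n)

    def test_empty_trajectory_rejected(self, toy5_calpha):
        topo, _ = toy5_calpha
        with pytest.raises(ValueError):
            Trajectory(topo, [])


class TestRmsf:
    def test_static_replicas_zero(self, toy20):
        topo, frame = toy20
        trajs = [
            Trajectory(topo, [Frame(frame.coordinates, float(k)) for k in range(4)])
            for _ in range(3)
        ]
        prof = rmsf_profile(ReplicaSet(Condition("solution"), trajs))
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)

    @staticmethod
    def _project_out_rigid_modes(coords, disp):
        """Remove the rigid-body (translation + infinitesimal rotation)
        components of a displacement field, so a superposition fit of the
        displaced structure is the identity."""
        centered = coords - coords.mean(axis=0)
        n = len(coords)
        modes = []
        for axis in np.eye(3):
            t = np.tile(axis, (n, 1))
            modes.append(t.ravel())
            modes.append(np.cross(np.tile(axis, (n, 1)), centered).ravel())
        basis = np.linalg.qr(np.array(modes).T)[0]
        flat = disp.ravel()
        return (flat - basis @ (basis.T @ flat)).reshape(n, 3)

    def test_two_conformer_half_distance(self, toy20):
        """A residue flipping between two positions d apart fluctuates by
        d/2 (displacement built orthogonal to the rigid-body modes so the
        superposition cannot absorb any of it)."""
        topo, frame = toy20
        raw = np.zeros_like(frame.coordinates)
        raw[0] = [0.05, 0.0, 0.0]
        d = self._project_out_rigid_modes(frame.coordinates, raw)
        frames = [
            Frame(frame.coordinates + (d if k % 2 else -d), float(k)) for k in range(40)
        ]
        prof = rmsf_profile(
            ReplicaSet(Condition("solution"), [Trajectory(topo, frames)]),
            selection="all",
            per_residue="mean",
        )
        # per-atom flip distance is 2|d_i|; RMSF_i = |d_i|
        atom_amp = np.linalg.norm(d, axis=1)
        res_of = np.array([a.residue_index for a in topo.atoms])
        expected = np.array(
            [atom_amp[res_of == r].mean() for r in range(topo.n_residues)]
        )
        np.testing.assert_allclose(prof.values, expected, atol=5e-4)

    def test_invariance_rigid_motion_and_permutation(self, toy20):
        topo, frame = toy20
        spec = synthetic.RehydrationSimSpec(
            compaction_scale=1.0, sigma=0.4, n_frames=30, n_replicas=3, seed=4
        )
        rs, _ = synthetic.simulate_replicas(topo, frame, spec)
        base = rmsf_profile(rs).values
        rot = Rotation.from_euler("xyz", [30, 60, 15], degrees=True)
        moved = ReplicaSet(
            rs.condition,
            [
                Trajectory(
                    topo,
                    [Frame(rot.apply(f.coordinates) + 7.0, f.time) for f in t.frames],
                )
                for t in rs
            ],
        )
        np.testing.assert_allclose(rmsf_profile(moved).values, base, atol=1e-9)
        # permutation changes the provisional fit reference (first frame of
        # the concatenation); with one refinement pass the profiles agree to
        # the accuracy of that pass, not to machine precision
        permuted = ReplicaSet(rs.condition, list(rs)[::-1])
        np.testing.assert_allclose(rmsf_profile(permuted).values, base, atol=1e-4)

    def test_uniform_sigma_recovery(self):
        """Isotropic jitter of σ per Cα recovers RMSF = σ√3 at every residue."""
        topo, frame = synthetic.make_toy_protein(
            synthetic.ToyProteinSpec(n_residues=40, atoms_per_residue=1, seed=0)
        )
        sigma = 0.5
        spec = synthetic.RehydrationSimSpec(
            compaction_scale=1.0, sigma=sigma, n_frames=400, n_replicas=5, seed=11
        )
        rs, truth = synthetic.simulate_replicas(topo, frame, spec)
        prof = rmsf_profile(rs)
        expected = sigma * np.sqrt(3.0)
        np.testing.assert_allclose(truth.expected_rmsf, expected)
        assert np.all(np.abs(prof.values / expected - 1) < 0.05)
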