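"""Contact maps, difference/composite maps and hydrogen-bond counting."""

import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from rehydra import contacts, synthetic
from rehydra.contacts import (
    ContactMap,
    HBondCriterion,
    composite_triangle_map,
    contact_matrix_frame,
    difference_map,
    hbond_count_frame,
    hbond_series_mean,
    occupancy_map,
)
from rehydra.trajio import Atom, Condition, Frame, ReplicaSet, Topology, Trajectory, Window

from conftest import make_two_residue_frame


def exhaustive_contact_oracle(frame, topology, cutoff):
    """All-pairs minimum-distance oracle, independent of the cell list."""
    prot = topology.protein_residue_indices
    n = len(prot)
    out = np.zeros((n, n))
    for a, ra in enumerate(prot):
        for b, rb in enumerate(prot):
            ia = topology.residue_atom_indices(ra)
            ib = topology.residue_atom_indices(rb)
            dmin = cdist(frame.coordinates[ia], frame.coordinates[ib]).min()
            out[a, b] = 1.0 if dmin <= cutoff else 0.0
    return out


class TestContactMatrix:
    def test_boundary_inclusive_at_cutoff(self):
        topo, frame = make_two_residue_frame(3.5)
        assert contact_matrix_frame(frame, topo)[0, 1] == 1.0

    def test_just_beyond_cutoff_excluded(self):
        topo, frame = make_two_residue_frame(3.51)
        assert contact_matrix_frame(frame, topo)[0, 1] == 0.0

    def test_diagonal_is_one(self, toy20):
        topo, frame = toy20
        m = contact_matrix_frame(frame, topo)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_symmetry(self, toy20):
        topo, frame = toy20
        m = contact_matrix_frame(frame, topo)
        np.testing.assert_array_equal(m, m.T)

    def test_toy_matches_exhaustive_oracle(self, toy5_calpha):
        topo, frame = toy5_calpha
        for method in ("cell", "brute"):
            got = contact_matrix_frame(frame, topo, method=method)
            np.testing.assert_array_equal(
                got, exhaustive_contact_oracle(frame, topo, 3.5)
            )

    def test_cell_list_equals_brute_force_random_frames(self, toy20, rng):
        topo, frame = toy20
        for _ in range(5):
            jitter = rng.normal(scale=1.0, size=frame.coordinates.shape)
            f = Frame(frame.coordinates + jitter)
            np.testing.assert_array_equal(
                contact_matrix_frame(f, topo, method="cell"),
                contact_matrix_frame(f, topo, method="brute"),
            )

    def test_cutoff_monotonicity(self, toy20, rng):
        topo, frame = toy20
        f = Frame(frame.coordinates + rng.normal(scale=0.5, size=frame.coordinates.shape))
        prev = contact_matrix_frame(f, topo, cutoff=3.0)
        for cutoff in (3.5, 4.5, 6.0):
            cur = contact_matrix_frame(f, topo, cutoff=cutoff)
            assert np.all(cur >= prev)
            prev = cur

    def test_too_few_residues_errors(self):
        topo = Topology([Atom(1, "CA", "C", 0, "GLY")])
        with pytest.raises(ValueError, match="residues"):
            contact_matrix_frame(Frame(np.zeros((1, 3))), topo)


class TestOccupancy:
    @staticmethod
    def _replicas_with_contact_pattern(pattern_per_replica, on=3.0, off=10.0):
        """Each replica's frames place the two residues in/out of contact."""
        topo, _ = make_two_residue_frame(on)
        trajs = []
        for pattern in pattern_per_replica:
            frames = [
                Frame(
                    np.array([[0.0, 0.0, 0.0], [on if c else off, 0.0, 0.0]]),
                    time=float(k),
                )
                for k, c in enumerate(pattern)
            ]
            trajs.append(Trajectory(topo, frames))
        return ReplicaSet(Condition("rehydration", 0.0), trajs)

    def test_two_of_four_frames(self):
        rs = self._replicas_with_contact_pattern([[1, 1, 0, 0]])
        assert occupancy_map(rs).matrix[0, 1] == pytest.approx(0.5)

    def test_one_of_five_replicas(self):
        rs = self._replicas_with_contact_pattern(
            [[1, 1, 1, 1]] + [[0, 0, 0, 0]] * 4
        )
        assert occupancy_map(rs).matrix[0, 1] == pytest.approx(0.2)

    def test_always_in_contact(self):
        rs = self._replicas_with_contact_pattern([[1, 1], [1, 1]])
        assert occupancy_map(rs).matrix[0, 1] == 1.0

    def test_window_restricts_pool(self):
        rs = self._replicas_with_contact_pattern([[1, 1, 0, 0]])
        occ = occupancy_map(rs, Window(last_fraction=0.5))
        assert occ.matrix[0, 1] == 0.0

    def test_replica_permutation_invariance(self):
        rs = self._replicas_with_contact_pattern([[1, 0], [1, 1], [0, 0]])
        swapped = ReplicaSet(rs.condition, list(rs)[::-1])
        np.testing.assert_array_equal(
            occupancy_map(rs).matrix, occupancy_map(swapped).matrix
        )

    def test_bounds_and_diagonal(self, toy20):
        topo, frame = toy20
        rng = np.random.default_rng(0)
        trajs = [
            Trajectory(
                topo,
                [
                    Frame(frame.coordinates + rng.normal(scale=0.8, size=frame.coordinates.shape), float(k))
                    for k in range(3)
                ],
            )
            for _ in range(2)
        ]
        occ = occupancy_map(ReplicaSet(Condition("solution"), trajs))
        assert np.all((occ.matrix >= 0) & (occ.matrix <= 1))
        np.testing.assert_allclose(np.diag(occ.matrix), 1.0)


class TestDifferenceMaps:
    @staticmethod
    def _maps():
        labels = ["A0", "B1", "C2"]
        a = ContactMap(np.array([[1, 1, 0], [1, 1, 0.5], [0, 0.5, 1]], float), labels)
        b = ContactMap(np.array([[1, 0, 0], [0, 1, 1.0], [0, 1.0, 1]], float), labels)
        return a, b

    def test_endpoints(self):
        a, b = self._maps()
        d = difference_map(a, b)
        assert d.matrix[0, 1] == 1.0  # contact only during condition a
        assert d.matrix[1, 2] == -0.5

    def test_full_range_endpoints(self):
        labels = ["A0", "B1"]
        ones = ContactMap(np.array([[1.0, 1.0], [1.0, 1.0]]), labels)
        zeros = ContactMap(np.array([[1.0, 0.0], [0.0, 1.0]]), labels)
        assert difference_map(ones, zeros).matrix[0, 1] == 1.0
        assert difference_map(zeros, ones).matrix[0, 1] == -1.0

    def test_antisymmetry_under_swap(self):
        a, b = self._maps()
        np.testing.assert_allclose(
            difference_map(a, b).matrix + difference_map(b, a).matrix, 0.0
        )

    def test_identical_maps_zero(self):
        a, _ = self._maps()
        np.testing.assert_allclose(difference_map(a, a).matrix, 0.0)

    def test_label_mismatch_errors(self):
        a, _ = self._maps()
        other = ContactMap(np.eye(2), ["A0", "B1"])
        with pytest.raises(ValueError):
            difference_map(a, other)


class TestCompositeTriangle:
    def test_triangles_and_diagonal(self):
        labels = ["A0", "B1", "C2"]
        lo = contacts.DifferenceMap(np.full((3, 3), 0.25), labels)
        hi = contacts.DifferenceMap(np.full((3, 3), -0.5), labels)
        comp = composite_triangle_map(lo, hi)
        assert comp[2, 0] == 0.25
        assert comp[0, 2] == -0.5
        np.testing.assert_allclose(np.diag(comp), 0.0)

    def test_symmetric_sources_give_symmetric_output(self):
        labels = ["A0", "B1", "C2"]
        m = np.array([[0, 0.3, -0.2], [0.3, 0, 0.1], [-0.2, 0.1, 0]])
        d = contacts.DifferenceMap(m, labels)
        comp = composite_triangle_map(d, d)
        np.testing.assert_allclose(comp, comp.T)


class TestHbonds:
    @staticmethod
    def _nh_water_system(da_distance, angle_deg=0.0):
        """Protein N–H donor plus one water O at given D–A geometry."""
        atoms = [
            Atom(1, "N", "N", 0, "ALA"),
            Atom(2, "H", "H", 0, "ALA"),
            Atom(3, "CA", "C", 0, "ALA"),
            Atom(4, "O", "O", 1, "HOH", is_solvent=True),
        ]
        theta = np.radians(angle_deg)
        coords = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0],
                [-1.5, 0.0, 0.0],
                [da_distance * np.cos(theta), da_distance * np.sin(theta), 0.0],
            ]
        )
        return Topology(atoms), Frame(coords)

    def test_ideal_geometry_counts_one(self):
        topo, frame = self._nh_water_system(2.9, angle_deg=5.0)
        assert hbond_count_frame(frame, topo) == 1

    def test_beyond_distance_cutoff(self):
        topo, frame = self._nh_water_system(3.6, angle_deg=5.0)
        assert hbond_count_frame(frame, topo) == 0

    def test_beyond_angle_cutoff(self):
        topo, frame = self._nh_water_system(2.9, angle_deg=40.0)
        assert hbond_count_frame(frame, topo) == 0

    def test_criterion_is_configurable(self):
        topo, frame = self._nh_water_system(2.9, angle_deg=40.0)
        wide = HBondCriterion(distance_cutoff=3.5, angle_cutoff=45.0)
        assert hbond_count_frame(frame, topo, wide) == 1

    def test_no_solvent_returns_zero_with_warning(self, toy20):
        topo, frame = toy20
        with pytest.warns(UserWarning, match="no solvent"):
            assert hbond_count_frame(frame, topo) == 0

    def test_planted_waters_exact_count(self):
        topo, frame = synthetic.make_toy_protein(
            synthetic.ToyProteinSpec(n_residues=24, seed=3)
        )
        t2, f2, truth = synthetic.add_waters_with_hbonds(topo, frame, k_bonded=4, k_far=8, seed=5)
        assert truth.planted_hbond_count == 4
        assert hbond_count_frame(f2, t2) == 4

    def test_series_mean_constant_and_alternating(self):
        topo, frame = self._nh_water_system(2.9)
        topo_far, frame_far = self._nh_water_system(6.0)
        bonded = Trajectory(topo, [Frame(frame.coordinates, float(k)) for k in range(4)])
        mixed = Trajectory(
            topo,
            [
                Frame(frame.coordinates if k % 2 == 0 else frame_far.coordinates, float(k))
                for k in range(4)
            ],
        )
        const = hbond_series_mean(ReplicaSet(Condition("rehydration", 0.0), [bonded]))
        assert (const.value, const.uncertainty) == (1.0, 0.0)
        alt = hbond_series_mean(ReplicaSet(Condition("rehydration", 0.0), [mixed]))
        assert alt.value == pytest.approx(0.5)

    def test_poisson_varying_counts_match_generator_expectation(self):
        """Across seeds, planted counts drawn per frame recover their mean."""
        rng = np.random.default_rng(77)
        topo, frame = synthetic.make_toy_protein(
            synthetic.ToyProteinSpec(n_residues=30, seed=1)
        )
        lam = 3.0
        planted = []
        counted = []
        for k in range(20):
            k_b = min(int(rng.poisson(lam)), 6)
            t2, f2, truth = synthetic.add_waters_with_hbonds(
                topo, frame, k_bonded=k_b, k_far=3, seed=100 + k
            )
            planted.append(truth.planted_hbond_count)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                counted.append(hbond_count_frame(f2, t2))
        np.testing.assert_array_equal(planted, counted)
        se = np.std(counted, ddof=1) / np.sqrt(len(counted))
        assert abs(np.mean(counted) - np.mean(planted)) <= 3 * se + 1e-9
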