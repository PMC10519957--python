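"""Structural observables: RMSD, Rg, equilibration split, RDF, hydrogen
bonds and aggregate detection, each against an independent oracle."""

import numpy as np
import pytest

from assdkit.trajkit import (
    HBondCriterion,
    compute_rdf,
    detect_aggregates,
    equilibration_split,
    hbond_occupancy,
    radius_of_gyration,
    rmsd_series,
)
from assdkit.trajkit.core import Topology
from assdkit.trajkit.geometry import pairwise_minimum_image_distances
from tests.conftest import make_point_topology, make_trajectory


class TestRMSD:
    def test_identical_frame_is_zero(self):
        rng = np.random.default_rng(0)
        xyz = rng.uniform(0, 10, size=(12, 3))
        top = make_point_topology(12)
        traj = make_trajectory(top, [xyz, xyz])
        assert rmsd_series(traj) == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(1)
        xyz = rng.uniform(0, 10, size=(15, 3))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = xyz @ rot.T + np.array([3.0, -2.0, 5.0])
        top = make_point_topology(15)
        traj = make_trajectory(top, [xyz, moved], box_edge=100.0)
        assert rmsd_series(traj)[1] == pytest.approx(0.0, abs=1e-8)

    def test_matches_mdtraj_rmsd(self):
        """Cross-check against mdtraj's superposed RMSD on a random walk."""
        md = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(21)
        n_atoms, n_frames = 12, 6
        coords = np.cumsum(
            rng.normal(scale=0.3, size=(n_frames, n_atoms, 3)), axis=0
        ) + rng.uniform(2, 8, size=(1, n_atoms, 3))
        top = make_point_topology(n_atoms)
        traj = make_trajectory(top, coords, box_edge=100.0)
        ours = rmsd_series(traj)
        mtop = md.Topology()
        chain = mtop.add_chain()
        res = mtop.add_residue("DRG", chain)
        for i in range(n_atoms):
            mtop.add_atom(f"C{i}", md.element.carbon, res)
        mdt = md.Trajectory(coords / 10.0, mtop)  # nm
        theirs = md.rmsd(mdt, mdt, frame=0) * 10.0
        assert np.allclose(ours, theirs, atol=1e-4)

    def test_direct_formula_oracle_after_superposition(self):
        """RMSD equals sqrt(mean squared deviation) of the aligned coordinates
        computed independently via the Kabsch SVD."""
        rng = np.random.default_rng(2)
        ref = rng.uniform(0, 10, size=(20, 3))
        pert = ref + rng.normal(scale=0.4, size=ref.shape)
        top = make_point_topology(20)
        traj = make_trajectory(top, [ref, pert], box_edge=100.0)
        out = rmsd_series(traj)[1]
        # independent Kabsch implementation
        a = ref - ref.mean(axis=0)
        b = pert - pert.mean(axis=0)
        h = b.T @ a
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        aligned = b @ rot
        expected = np.sqrt(np.mean(np.sum((aligned - a) ** 2, axis=1)))
        assert out == pytest.approx(expected, rel=1e-9)


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        top = make_point_topology(2, molecule_ids=[0, 0])
        traj = make_trajectory(
            top, [[[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]]], box_edge=50.0
        )
        assert radius_of_gyration(traj)[0] == pytest.approx(2.0)

    def test_coincident_atoms_zero(self):
        top = make_point_topology(5, molecule_ids=[0] * 5)
        traj = make_trajectory(top, [np.ones((5, 3))], box_edge=50.0)
        assert radius_of_gyration(traj)[0] == pytest.approx(0.0)

    def test_brute_force_definition(self):
        rng = np.random.default_rng(3)
        xyz = rng.uniform(0, 10, size=(20, 3))
        masses = rng.uniform(1, 30, size=20)
        top = make_point_topology(20, molecule_ids=[0] * 20)
        top.masses = masses
        traj = make_trajectory(top, [xyz], box_edge=50.0)
        com = (masses[:, None] * xyz).sum(axis=0) / masses.sum()
        expected = np.sqrt(
            (masses * ((xyz - com) ** 2).sum(axis=1)).sum() / masses.sum()
        )
        assert radius_of_gyration(traj)[0] == pytest.approx(expected, rel=1e-10)


class TestEquilibrationSplit:
    def test_default_midpoint(self):
        assert equilibration_split(np.arange(100.0)) == 50

    def test_constant_series_plateau(self):
        assert equilibration_split(np.ones(40), mode="plateau") == 0

    def test_step_series_plateau(self):
        series = np.concatenate([np.full(30, 10.0), np.zeros(70)])
        assert equilibration_split(series, mode="plateau", tolerance=0.05) == 30

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            equilibration_split([1.0, 2.0, 3.0])


class TestRDF:
    def test_ideal_gas_limit(self):
        """Uniform random B atoms around a single A atom give g(r) = 1."""
        rng = np.random.default_rng(5)
        n_b, n_frames, edge = 600, 300, 20.0
        frames = np.empty((n_frames, n_b + 1, 3))
        frames[:, 0] = rng.uniform(0, edge, size=(n_frames, 3))
        frames[:, 1:] = rng.uniform(0, edge, size=(n_frames, n_b, 3))
        top = make_point_topology(n_b + 1)
        traj = make_trajectory(top, frames, box_edge=edge)
        rdf = compute_rdf(traj, np.array([0]), np.arange(1, n_b + 1), dr=1.0)
        # ignore the innermost bins where expected counts are tiny
        sel = rdf.bin_centers > 2.0
        assert np.all(np.abs(rdf.g[sel] - 1.0) < 0.05)

    def test_delta_peak_at_fixed_distance(self):
        top = make_point_topology(2)
        xyz = np.array([[5.0, 5.0, 5.0], [7.84, 5.0, 5.0]])
        traj = make_trajectory(top, [xyz] * 10, box_edge=20.0,
                               times=np.arange(10.0))
        rdf = compute_rdf(traj, np.array([0]), np.array([1]), dr=0.1)
        peak_bin = int(np.argmax(rdf.counts))
        # the fixed 2.84 A separation lands in the bin centred at 2.85 A
        assert rdf.bin_centers[peak_bin] == pytest.approx(2.85, abs=1e-9)
        assert rdf.counts.sum() == rdf.counts[peak_bin] == 10

    def test_raw_counts_match_enumeration_oracle(self):
        """Binned counts equal brute-force pair enumeration on 5 frames."""
        rng = np.random.default_rng(6)
        n = 30
        mol_ids = np.repeat(np.arange(10), 3)
        top = make_point_topology(n, molecule_ids=mol_ids)
        frames = rng.uniform(0, 15.0, size=(5, n, 3))
        traj = make_trajectory(top, frames, box_edge=15.0)
        sel_a = np.arange(0, 15)
        sel_b = np.arange(9, 30)
        dr, r_max = 0.25, 7.0
        rdf = compute_rdf(traj, sel_a, sel_b, dr=dr, r_max=r_max)
        edges = np.arange(int(np.ceil(r_max / dr)) + 1) * dr
        expected = np.zeros(edges.size - 1)
        for f in range(5):
            for i in sel_a:
                for j in sel_b:
                    if mol_ids[i] == mol_ids[j]:
                        continue
                    d = pairwise_minimum_image_distances(
                        frames[f, i][None], frames[f, j][None], np.full(3, 15.0)
                    )[0, 0]
                    k = int(d / dr)
                    if k < expected.size:
                        expected[k] += 1
        assert np.array_equal(rdf.counts, expected)

    def test_integer_conservation_within_rmax(self):
        rng = np.random.default_rng(7)
        n = 20
        top = make_point_topology(n)
        frames = rng.uniform(0, 12.0, size=(3, n, 3))
        traj = make_trajectory(top, frames, box_edge=12.0)
        rdf = compute_rdf(traj, np.arange(10), np.arange(10, 20), dr=0.1, r_max=6.0)
        box = np.full(3, 12.0)
        total = 0
        for f in range(3):
            d = pairwise_minimum_image_distances(
                frames[f, :10], frames[f, 10:], box
            )
            total += int((d < 6.0).sum())
        assert int(rdf.counts.sum()) == total

    def test_rmax_beyond_half_box_rejected(self):
        top = make_point_topology(4)
        traj = make_trajectory(top, [np.zeros((4, 3))], box_edge=10.0)
        with pytest.raises(ValueError, match="half the minimum box edge"):
            compute_rdf(traj, np.array([0]), np.array([1]), r_max=6.0)


def _hbond_topology():
    """Donor heavy atom (0) with hydrogen (1), acceptor (2) in another
    molecule."""
    return Topology(
        elements=["N", "H", "O"],
        masses=np.array([14.0, 1.0, 16.0]),
        molecule_ids=np.array([0, 0, 1]),
        charges=np.zeros(3),
        lj_sigma=np.ones(3),
        lj_epsilon=np.ones(3),
        molecule_species={0: "drug", 1: "oligomer"},
        donor_flags=np.array([True, False, False]),
        acceptor_flags=np.array([False, False, True]),
        hydrogen_donor_index=np.array([-1, 0, -1]),
    )


def _hbond_frame(d, angle_deg):
    """Donor at origin, acceptor at distance d on x, hydrogen placed to give
    the requested donor-H...acceptor angle."""
    from scipy.optimize import brentq

    def angle_of(alpha):
        h = np.array([np.cos(alpha), np.sin(alpha), 0.0])
        v1 = -h
        v2 = np.array([d, 0.0, 0.0]) - h
        c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.degrees(np.arccos(np.clip(c, -1, 1)))

    alpha = brentq(lambda a: angle_of(a) - angle_deg, 1e-6, np.pi / 2)
    h = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    return np.array([[10.0, 10.0, 10.0], [10.0, 10.0, 10.0] + h,
                     [10.0 + d, 10.0, 10.0]])


class TestHBonds:
    def test_conforming_geometry_full_occupancy(self):
        top = _hbond_topology()
        frame = _hbond_frame(3.0, 170.0)
        traj = make_trajectory(top, [frame] * 4, box_edge=20.0)
        report = hbond_occupancy(traj, np.array([0]), np.array([2]))
        assert report.class_occupancy == 1.0
        assert report.pair_occupancy[(0, 2)] == 1.0

    def test_distance_failure_zero_occupancy(self):
        top = _hbond_topology()
        frame = _hbond_frame(3.3, 175.0)
        traj = make_trajectory(top, [frame] * 4, box_edge=20.0)
        report = hbond_occupancy(traj, np.array([0]), np.array([2]))
        assert report.class_occupancy == 0.0

    def test_angle_failure_zero_occupancy(self):
        top = _hbond_topology()
        frame = _hbond_frame(3.0, 150.0)
        traj = make_trajectory(top, [frame] * 4, box_edge=20.0)
        report = hbond_occupancy(traj, np.array([0]), np.array([2]))
        assert report.class_occupancy == 0.0

    def test_relaxing_criterion_never_decreases_occupancy(self):
        rng = np.random.default_rng(8)
        top = _hbond_topology()
        frames = [
            _hbond_frame(rng.uniform(2.5, 4.0), rng.uniform(140.0, 180.0))
            for _ in range(30)
        ]
        traj = make_trajectory(top, frames, box_edge=20.0)
        strict = hbond_occupancy(
            traj, np.array([0]), np.array([2]), HBondCriterion(3.2, 158.0)
        )
        loose = hbond_occupancy(
            traj, np.array([0]), np.array([2]), HBondCriterion(3.6, 150.0)
        )
        assert loose.class_occupancy >= strict.class_occupancy
        for pair in strict.pair_occupancy:
            assert loose.pair_occupancy[pair] >= strict.pair_occupancy[pair]

    def test_donor_without_hydrogen_rejected(self):
        top = _hbond_topology()
        top.hydrogen_donor_index = np.array([-1, -1, -1])
        frame = _hbond_frame(3.0, 170.0)
        traj = make_trajectory(top, [frame], box_edge=20.0)
        with pytest.raises(ValueError, match="without linked hydrogens"):
            hbond_occupancy(traj, np.array([0]), np.array([2]))


class TestAggregates:
    def _topology(self, n_mols, atoms_per_mol=2):
        ids = np.repeat(np.arange(n_mols), atoms_per_mol)
        return make_point_topology(n_mols * atoms_per_mol, molecule_ids=ids)

    def test_all_far_apart_singletons(self):
        top = self._topology(4, 1)
        coords = np.array(
            [[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [10.0, 10.0, 0]]
        )
        out = detect_aggregates(coords, np.full(3, 40.0), top, [0, 1, 2, 3], 4.0)
        assert out == [[0], [1], [2], [3]]

    def test_transitive_chain_single_cluster(self):
        top = self._topology(3, 1)
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        out = detect_aggregates(coords, np.full(3, 40.0), top, [0, 1, 2], 4.0)
        assert out == [[0, 1, 2]]

    def test_matches_networkx_components_on_random_configurations(self):
        """20 random configurations against a networkx connected-components
        oracle over the full heavy-atom distance matrix."""
        import networkx as nx

        rng = np.random.default_rng(9)
        box = np.full(3, 25.0)
        for _ in range(20):
            n_mols = int(rng.integers(4, 10))
            top = self._topology(n_mols, 3)
            coords = rng.uniform(0, 25.0, size=(n_mols * 3, 3))
            cutoff = float(rng.uniform(3.0, 8.0))
            ours = detect_aggregates(coords, box, top, list(range(n_mols)), cutoff)
            graph = nx.Graph()
            graph.add_nodes_from(range(n_mols))
            for a in range(n_mols):
                for b in range(a + 1, n_mols):
                    da = pairwise_minimum_image_distances(
                        coords[top.atoms_of(a)], coords[top.atoms_of(b)], box
                    )
                    if da.min() <= cutoff:
                        graph.add_edge(a, b)
            expected = sorted(
                (sorted(c) for c in nx.connected_components(graph)),
                key=lambda c: c[0],
            )
            assert ours == expected

    def test_partitions_refine_with_smaller_cutoff(self):
        rng = np.random.default_rng(10)
        n_mols = 8
        top = self._topology(n_mols, 2)
        coords = rng.uniform(0, 20.0, size=(n_mols * 2, 3))
        box = np.full(3, 20.0)
        small = detect_aggregates(coords, box, top, list(range(n_mols)), 3.0)
        large = detect_aggregates(coords, box, top, list(range(n_mols)), 6.0)
        membership = {}
        for idx, cluster in enumerate(large):
            for m in cluster:
                membership[m] = idx
        for cluster in small:
            assert len({membership[m] for m in cluster}) == 1
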