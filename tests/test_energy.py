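"""Toy pairwise backend and the per-molecule energy decomposition."""

import numpy as np
import pytest

from assdkit.trajkit import (
    bootstrap_stats,
    drug_drug_energy,
    drug_oligomer_energy,
    stride_frames,
    toy_energy_backend,
)
from assdkit.trajkit.core import Topology
from assdkit.trajkit.energy import COULOMB_CONSTANT, EnergyComponents
from tests.conftest import make_point_topology, make_trajectory


def _charged_pair(q1, q2, sigma=1.0, epsilon=0.0):
    top = make_point_topology(2, charges=[q1, q2], sigma=sigma, epsilon=epsilon)
    return top


class TestToyBackend:
    def test_coulomb_constant_arithmetic(self):
        """Two unit opposite charges at 3.320636 A give -100 kcal/mol."""
        top = _charged_pair(1.0, -1.0)
        backend = toy_energy_backend(top, shift=False)
        coords = np.array([[0.0, 0, 0], [3.320636, 0, 0]])
        e = backend.pair_energy(coords, np.full(3, 100.0), [0], [1])
        assert e.elec == pytest.approx(-100.0, rel=1e-9)
        assert e.vdw == 0.0 and e.solv == 0.0

    def test_lj_closed_form(self):
        top = make_point_topology(2, sigma=3.0, epsilon=0.5)
        backend = toy_energy_backend(top, shift=False)
        at_sigma = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        e = backend.pair_energy(at_sigma, np.full(3, 50.0), [0], [1])
        assert e.vdw == pytest.approx(0.0, abs=1e-12)
        at_min = np.array([[0.0, 0, 0], [3.0 * 2 ** (1 / 6), 0, 0]])
        e = backend.pair_energy(at_min, np.full(3, 50.0), [0], [1])
        assert e.vdw == pytest.approx(-0.5, rel=1e-12)

    def test_brute_force_double_loop_oracle(self):
        """Random 10-atom groups against an independent double loop."""
        rng = np.random.default_rng(1)
        n = 20
        top = make_point_topology(
            n,
            molecule_ids=np.repeat([0, 1], 10),
            charges=rng.uniform(-0.5, 0.5, n),
        )
        top.lj_sigma = rng.uniform(2.0, 4.0, n)
        top.lj_epsilon = rng.uniform(0.05, 0.5, n)
        box = np.full(3, 30.0)
        coords = rng.uniform(0, 30.0, size=(n, 3))
        backend = toy_energy_backend(top, dielectric=2.0, shift=False, cutoff=10.0)
        e = backend.pair_energy(coords, box, np.arange(10), np.arange(10, 20))
        vdw = elec = 0.0
        for i in range(10):
            for j in range(10, 20):
                delta = coords[j] - coords[i]
                delta -= box * np.round(delta / box)
                r = np.linalg.norm(delta)
                if r > 10.0:
                    continue
                s = 0.5 * (top.lj_sigma[i] + top.lj_sigma[j])
                ep = np.sqrt(top.lj_epsilon[i] * top.lj_epsilon[j])
                vdw += 4 * ep * ((s / r) ** 12 - (s / r) ** 6)
                elec += (
                    COULOMB_CONSTANT * top.charges[i] * top.charges[j] / (2.0 * r)
                )
        assert e.vdw == pytest.approx(vdw, rel=1e-9)
        assert e.elec == pytest.approx(elec, rel=1e-9)

    def test_symmetry_and_empty_group(self):
        rng = np.random.default_rng(2)
        top = make_point_topology(6, charges=rng.uniform(-1, 1, 6))
        coords = rng.uniform(0, 20.0, size=(6, 3))
        box = np.full(3, 20.0)
        backend = toy_energy_backend(top)
        ab = backend.pair_energy(coords, box, [0, 1, 2], [3, 4, 5])
        ba = backend.pair_energy(coords, box, [3, 4, 5], [0, 1, 2])
        assert ab.total == pytest.approx(ba.total, rel=1e-12)
        assert backend.pair_energy(coords, box, [0, 1], []).total == 0.0

    def test_additive_over_disjoint_partitions(self):
        rng = np.random.default_rng(3)
        top = make_point_topology(9, charges=rng.uniform(-1, 1, 9))
        coords = rng.uniform(0, 20.0, size=(9, 3))
        box = np.full(3, 20.0)
        backend = toy_energy_backend(top, solvation=True)
        whole = backend.pair_energy(coords, box, [0, 1], list(range(2, 9)))
        parts = backend.pair_energy(coords, box, [0, 1], [2, 3, 4])
        parts = parts + backend.pair_energy(coords, box, [0, 1], [5, 6, 7, 8])
        assert whole.total == pytest.approx(parts.total, rel=1e-9)

    def test_overlapping_groups_rejected(self):
        top = make_point_topology(4)
        backend = toy_energy_backend(top)
        with pytest.raises(ValueError, match="disjoint"):
            backend.pair_energy(np.zeros((4, 3)), np.full(3, 10.0), [0, 1], [1, 2])

    def test_distance_floor_clamped_with_warning(self):
        top = _charged_pair(1.0, 1.0)
        backend = toy_energy_backend(top, shift=False)
        coords = np.array([[0.0, 0, 0], [0.01, 0, 0]])
        with pytest.warns(UserWarning, match="clamped"):
            e = backend.pair_energy(coords, np.full(3, 10.0), [0], [1])
        assert np.isfinite(e.total)

    def test_components_sum_to_total(self):
        rng = np.random.default_rng(4)
        top = make_point_topology(8, charges=rng.uniform(-1, 1, 8))
        backend = toy_energy_backend(top, solvation=True)
        coords = rng.uniform(0, 15.0, size=(8, 3))
        e = backend.pair_energy(coords, np.full(3, 15.0), [0, 1, 2], [4, 5, 6])
        assert e.total == pytest.approx(e.vdw + e.elec + e.solv, abs=1e-9)


class _TabulatedBackend:
    """Backend stub with prescribed molecule-pair energies."""

    def __init__(self, topology, pair_values):
        self.topology = topology
        self.pair_values = pair_values

    def pair_energy(self, coords, box, group_a, group_b):
        mols_a = {int(self.topology.molecule_ids[i]) for i in np.asarray(group_a, int)}
        mols_b = {int(self.topology.molecule_ids[i]) for i in np.asarray(group_b, int)}
        total = 0.0
        for a in mols_a:
            for b in mols_b:
                total += self.pair_values.get((min(a, b), max(a, b)), 0.0)
        return EnergyComponents(total, 0.0, 0.0)


def _cluster_system(positions, species=None):
    """One atom per molecule at the given positions."""
    n = len(positions)
    ids = np.arange(n)
    top = make_point_topology(n, molecule_ids=ids)
    if species is not None:
        top.molecule_species = dict(enumerate(species))
    traj = make_trajectory(
        top, [np.asarray(positions, float)] * 2, box_edge=100.0,
        times=np.array([0.0, 100.0]),
    )
    return top, traj


class TestDrugDrugEnergy:
    def test_two_molecule_aggregate(self):
        top, traj = _cluster_system([[0, 0, 0], [3, 0, 0]])
        backend = _TabulatedBackend(top, {(0, 1): -2.0})
        report = drug_drug_energy(traj, backend, contact_cutoff=4.0,
                                  stride_ps=100.0, start_frame=0)
        per_mol = report.records.groupby("molecule")["E_total"].mean()
        assert per_mol[0] == per_mol[1] == -2.0
        assert report.mean() == -2.0

    def test_three_molecule_hand_summed_oracle(self):
        top, traj = _cluster_system([[0, 0, 0], [3, 0, 0], [0, 3, 0]])
        backend = _TabulatedBackend(top, {(0, 1): -1.0, (0, 2): -2.0, (1, 2): -3.0})
        report = drug_drug_energy(traj, backend, contact_cutoff=5.0,
                                  stride_ps=100.0, start_frame=0)
        per_mol = report.records.groupby("molecule")["E_total"].mean()
        assert per_mol[0] == -3.0 and per_mol[1] == -4.0 and per_mol[2] == -5.0
        assert report.mean() == pytest.approx(-4.0)

    def test_isolated_molecule_excluded(self):
        top, traj = _cluster_system([[0, 0, 0], [3, 0, 0], [40, 40, 40]])
        backend = _TabulatedBackend(top, {(0, 1): -2.0})
        report = drug_drug_energy(traj, backend, contact_cutoff=4.0,
                                  stride_ps=100.0, start_frame=0)
        assert set(report.records["molecule"]) == {0, 1}
        assert report.mean() == -2.0

    def test_no_aggregates_flagged_empty(self):
        top, traj = _cluster_system([[0, 0, 0], [40, 0, 0], [0, 40, 0]])
        backend = _TabulatedBackend(top, {})
        report = drug_drug_energy(traj, backend, contact_cutoff=4.0,
                                  stride_ps=100.0, start_frame=0)
        assert report.empty and report.n_samples == 0
        with pytest.raises(ValueError, match="empty"):
            report.mean()

    def test_pair_double_counting_convention(self):
        """Summed per-molecule energies count each pair exactly twice."""
        top, traj = _cluster_system([[0, 0, 0], [3, 0, 0], [0, 3, 0]])
        pairs = {(0, 1): -1.0, (0, 2): -2.0, (1, 2): -3.0}
        backend = _TabulatedBackend(top, pairs)
        report = drug_drug_energy(traj, backend, contact_cutoff=5.0,
                                  stride_ps=100.0, start_frame=0)
        frame0 = report.records[report.records["frame"] == 0]
        assert frame0["E_total"].sum() == pytest.approx(2 * sum(pairs.values()))


class TestDrugOligomerEnergy:
    def test_additivity_oracle(self):
        """E_total = E_dd + E_oligomer for a hand-built frame."""
        top, traj = _cluster_system(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0]],
            species=["drug", "drug", "oligomer"],
        )
        backend = _TabulatedBackend(top, {(0, 1): -1.0, (0, 2): -7.0, (1, 2): -4.0})
        report = drug_oligomer_energy(traj, backend, contact_cutoff=5.0,
                                      stride_ps=100.0, start_frame=0)
        row = report.records[report.records["molecule"] == 0].iloc[0]
        assert row["E_drug_drug"] == -1.0
        assert row["E_total"] == -8.0
        assert row["E_drug_oligomer"] == -7.0

    def test_out_of_range_oligomer_gives_zero(self):
        top, traj = _cluster_system(
            [[0, 0, 0], [3, 0, 0], [45, 45, 45]],
            species=["drug", "drug", "oligomer"],
        )
        backend = _TabulatedBackend(top, {(0, 1): -2.0})
        report = drug_oligomer_energy(traj, backend, contact_cutoff=5.0,
                                      stride_ps=100.0, start_frame=0)
        assert np.all(report.records["E_drug_oligomer"] == 0.0)

    def test_missing_oligomer_rejected(self):
        top, traj = _cluster_system([[0, 0, 0], [3, 0, 0]])
        backend = _TabulatedBackend(top, {})
        with pytest.raises(ValueError, match="oligomer"):
            drug_oligomer_energy(traj, backend)


class TestStrideSampling:
    def test_nearest_at_or_after_rule(self):
        times = np.array([0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0])
        assert stride_frames(times, 0, 5.0) == [0, 2, 4, 6]
        # ticks between frames pick the next frame at or after
        times = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
        assert stride_frames(times, 0, 5.0) == [0, 2, 4]

    def test_start_index_respected(self):
        times = np.arange(0.0, 20.0, 2.0)
        picked = stride_frames(times, 5, 4.0)
        assert picked[0] == 5
        assert all(p >= 5 for p in picked)


class TestBootstrap:
    def test_constant_vector_degenerate(self):
        out = bootstrap_stats(np.full(20, 3.5), n_boot=200, seed=1)
        assert out.mean == 3.5 and out.sd == 0.0
        assert out.ci_low == out.ci_high == 3.5

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        a = bootstrap_stats(x, n_boot=300, seed=5)
        b = bootstrap_stats(x, n_boot=300, seed=5)
        assert a == b

    def test_clt_oracle(self):
        """Bootstrap SD of the mean of n standard normals ~ 1/sqrt(n)."""
        rng = np.random.default_rng(12)
        n = 10_000
        x = rng.standard_normal(n)
        out = bootstrap_stats(x, n_boot=400, seed=3)
        assert abs(out.sd - 1 / np.sqrt(n)) < 0.15 / np.sqrt(n)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_stats([1.0], n_boot=200)
        with pytest.raises(ValueError):
            bootstrap_stats([1.0, 2.0], n_boot=50)
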