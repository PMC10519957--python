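"""Trajectory-analysis operators: RMSD, Rg, equilibration split, RDF,
hydrogen-bond occupancy and aggregate detection.

Conventions
-----------
* All distances are minimum-image distances in orthorhombic boxes.
* The RDF excludes intra-molecular pairs and normalizes per frame by the
  shell volume and the ideal-gas pair expectation at the instantaneous box
  volume, so an uncorrelated homogeneous system gives g(r) -> 1.
* A hydrogen bond requires donor-heavy-atom to acceptor-heavy-atom distance
  <= d_max (default 3.2 A) and donor-H...acceptor angle >= angle_min
  (default 158 degrees); any hydrogen bonded to the donor may satisfy the
  criterion.
* An aggregate is a connected component of the molecular contact graph,
  two molecules being in contact when any inter-molecular heavy-atom
  minimum-image distance is at or below the cutoff (default 4.0 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Topology, Trajectory
from .geometry import (
    minimum_image_displacement,
    pairwise_minimum_image_distances,
)

__all__ = [
    "RDFResult",
    "HBondCriterion",
    "HBondReport",
    "AggregateSet",
    "rmsd_series",
    "radius_of_gyration",
    "equilibration_split",
    "compute_rdf",
    "hbond_occupancy",
    "detect_aggregates",
    "aggregates_series",
]

DEFAULT_CONTACT_CUTOFF = 4.0  # Angstrom


def _frame_indices(n_frames: int, frames: slice | Sequence[int] | None) -> np.ndarray:
    if frames is None:
        return np.arange(n_frames)
    if isinstance(frames, slice):
        return np.arange(n_frames)[frames]
    return np.asarray(frames, dtype=int)


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Mass-unweighted all-atom RMSD to a reference frame, per frame.

    Each frame is optimally superposed on the reference (translation removed,
    Kabsch rotation) before the deviation is measured, so rigid-body motion
    contributes nothing.
    """
    sel = (
        np.arange(traj.topology.n_atoms)
        if selection is None
        else np.asarray(selection, dtype=int)
    )
    if sel.size == 0:
        raise ValueError("empty selection")
    ref = traj.coords[reference_frame][sel]
    ref_centered = ref - ref.mean(axis=0)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mobile = traj.coords[f][sel]
        mobile_centered = mobile - mobile.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mobile_centered)
        aligned = rot.apply(mobile_centered)
        out[f] = np.sqrt(np.mean(np.sum((aligned - ref_centered) ** 2, axis=1)))
    return out


def radius_of_gyration(
    traj: Trajectory, selection: np.ndarray | None = None
) -> np.ndarray:
    """Mass-weighted radius of gyration about the selection's centre of mass."""
    sel = (
        np.arange(traj.topology.n_atoms)
        if selection is None
        else np.asarray(selection, dtype=int)
    )
    if sel.size == 0:
        raise ValueError("empty selection")
    masses = traj.topology.masses[sel]
    total = masses.sum()
    if not total > 0:
        raise ValueError("zero total mass in selection")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        xyz = traj.coords[f][sel]
        com = (masses[:, None] * xyz).sum(axis=0) / total
        out[f] = np.sqrt((masses * np.sum((xyz - com) ** 2, axis=1)).sum() / total)
    return out


def equilibration_split(
    series: Sequence[float],
    mode: Literal["half", "plateau"] = "half",
    tolerance: float | None = None,
) -> int:
    """Index from which a per-frame scalar series is considered equilibrated.

    The default rule returns the midpoint (structural convergence after about
    half the run, the qualitative rule used for the reference trajectories).
    Plateau mode returns the first index from which the forward running mean
    stays within ``tolerance`` of the final mean (mean over the last quarter).
    """
    values = np.asarray(series, dtype=float)
    if values.size < 4:
        raise ValueError("series too short for an equilibration split")
    if mode == "half":
        return values.size // 2
    if tolerance is None:
        tolerance = 0.1 * max(np.std(values), 1e-12)
    tail = values[-max(1, values.size // 4):]
    final_mean = tail.mean()
    # forward running mean r[i] = mean(values[i:])
    forward = np.cumsum(values[::-1])[::-1] / np.arange(values.size, 0, -1)
    within = np.abs(forward - final_mean) <= tolerance
    # first i such that all j >= i are within the band
    ok_from = np.where(~within[::-1])[0]
    return values.size - ok_from[0] if ok_from.size else 0


@dataclass
class RDFResult:
    """Radial distribution function with its raw histogram."""

    bin_centers: np.ndarray       # Angstrom
    g: np.ndarray                 # dimensionless
    counts: np.ndarray            # raw pair counts per bin (all frames)
    reference_density: float      # mean pair density, A^-3
    n_frames: int
    selection_sizes: tuple[int, int]

    def first_peak(self) -> tuple[float, float]:
        idx = int(np.argmax(self.g))
        return float(self.bin_centers[idx]), float(self.g[idx])


def compute_rdf(
    traj: Trajectory,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    dr: float = 0.1,
    r_max: float | None = None,
    frames: slice | Sequence[int] | None = None,
    exclude_intramolecular: bool = True,
) -> RDFResult:
    """Radial distribution function between two atom selections.

    Histograms the number of B atoms found as a function of minimum-image
    distance from each A atom and normalizes by the expected ideal-gas count
    (shell volume times instantaneous pair density), frame by frame.
    Intra-molecular pairs (and self pairs) are excluded by default.
    """
    sel_a = np.asarray(selection_a, dtype=int)
    sel_b = np.asarray(selection_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("empty selection")
    frame_idx = _frame_indices(traj.n_frames, frames)
    min_edge = float(traj.boxes[frame_idx].min())
    if r_max is None:
        r_max = min_edge / 2.0
    if r_max > min_edge / 2.0 + 1e-9:
        raise ValueError(
            f"r_max {r_max} exceeds half the minimum box edge {min_edge / 2.0}"
        )
    n_bins = int(np.ceil(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    mol = traj.topology.molecule_ids
    pair_mask = np.ones((sel_a.size, sel_b.size), dtype=bool)
    if exclude_intramolecular:
        pair_mask &= mol[sel_a][:, None] != mol[sel_b][None, :]
    else:
        pair_mask &= sel_a[:, None] != sel_b[None, :]
    n_pairs = int(pair_mask.sum())
    if n_pairs == 0:
        raise ValueError("no eligible pairs between the selections")

    counts = np.zeros(n_bins)
    expected = np.zeros(n_bins)
    shell_volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    densities = []
    for f in frame_idx:
        xyz, box = traj.frame(int(f))
        dist = pairwise_minimum_image_distances(xyz[sel_a], xyz[sel_b], box)
        dist = dist[pair_mask]
        hist, _ = np.histogram(dist, bins=edges)
        counts += hist
        volume = float(np.prod(box))
        density = n_pairs / volume
        densities.append(density)
        expected += density * shell_volumes
    g = np.divide(counts, expected, out=np.zeros_like(counts), where=expected > 0)
    return RDFResult(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        g=g,
        counts=counts,
        reference_density=float(np.mean(densities)),
        n_frames=frame_idx.size,
        selection_sizes=(sel_a.size, sel_b.size),
    )


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition."""

    d_max: float = 3.2        # donor-heavy to acceptor-heavy distance, Angstrom
    angle_min: float = 158.0  # donor-H...acceptor angle, degrees

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.angle_min <= 180:
            raise ValueError("angle_min must lie in (0, 180]")


@dataclass
class HBondReport:
    """Per donor-acceptor pair occupancies plus the pooled class occupancy."""

    pair_occupancy: dict[tuple[int, int], float]
    class_occupancy: float
    n_frames: int
    criterion: HBondCriterion

    def __post_init__(self) -> None:
        values = list(self.pair_occupancy.values()) + [self.class_occupancy]
        if any(not 0.0 <= v <= 1.0 for v in values):
            raise ValueError("occupancies must lie in [0, 1]")


def hbond_occupancy(
    traj: Trajectory,
    donors: np.ndarray,
    acceptors: np.ndarray,
    criterion: HBondCriterion | None = None,
    frames: slice | Sequence[int] | None = None,
    exclude_same_molecule: bool = True,
) -> HBondReport:
    """Hydrogen-bond occupancy between donor heavy atoms and acceptors.

    A pair is bonded in a frame when ANY hydrogen linked to the donor
    satisfies both the heavy-atom distance and the donor-H...acceptor angle
    conditions.  Pair occupancy is the fraction of analysed frames in which
    the pair bonds; the class occupancy is the fraction of frames in which
    any pair bonds.
    """
    criterion = criterion or HBondCriterion()
    top = traj.topology
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("empty donor or acceptor selection")
    donor_h = {int(d): top.hydrogens_of_donor(int(d)) for d in donors}
    missing = [d for d, hs in donor_h.items() if hs.size == 0]
    if missing:
        raise ValueError(f"donor atoms without linked hydrogens: {missing}")
    frame_idx = _frame_indices(traj.n_frames, frames)
    cos_max = np.cos(np.deg2rad(criterion.angle_min))

    pairs = [
        (int(d), int(a))
        for d in donors
        for a in acceptors
        if int(a) != int(d)
        and not (
            exclude_same_molecule
            and top.molecule_ids[int(a)] == top.molecule_ids[int(d)]
        )
    ]
    if not pairs:
        raise ValueError("no eligible donor-acceptor pairs")
    bonded_counts = {pair: 0 for pair in pairs}
    any_count = 0
    for f in frame_idx:
        xyz, box = traj.frame(int(f))
        frame_any = False
        for d, a in pairs:
            d_da = np.linalg.norm(
                minimum_image_displacement(xyz[d], xyz[a], box)
            )
            if d_da > criterion.d_max:
                continue
            for h in donor_h[d]:
                hd = minimum_image_displacement(xyz[h], xyz[d], box)
                ha = minimum_image_displacement(xyz[h], xyz[a], box)
                nhd = np.linalg.norm(hd)
                nha = np.linalg.norm(ha)
                if nhd == 0 or nha == 0:
                    continue
                cos_angle = float(np.dot(hd, ha) / (nhd * nha))
                # angle >= angle_min  <=>  cos(angle) <= cos(angle_min)
                if cos_angle <= cos_max + 1e-12:
                    bonded_counts[(d, a)] += 1
                    frame_any = True
                    break
        any_count += frame_any
    n = frame_idx.size
    return HBondReport(
        pair_occupancy={p: c / n for p, c in bonded_counts.items()},
        class_occupancy=any_count / n,
        n_frames=n,
        criterion=criterion,
    )


@dataclass
class AggregateSet:
    """Per-frame molecule clusters at a fixed contact cutoff."""

    frames: list[int]
    clusters: list[list[list[int]]]   # per frame: list of molecule-id clusters
    contact_cutoff: float

    def largest_sizes(self) -> np.ndarray:
        return np.array([max(len(c) for c in frame) for frame in self.clusters])


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def detect_aggregates(
    coords: np.ndarray,
    box: np.ndarray,
    topology: Topology,
    molecule_ids: Sequence[int] | None = None,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[list[int]]:
    """Molecule clusters in one frame as connected components of the contact
    graph; two molecules are linked when any inter-molecular heavy-atom
    minimum-image distance is at or below the cutoff.

    Returns clusters as sorted lists of molecule ids; the clusters partition
    the selected molecules.
    """
    if not contact_cutoff > 0:
        raise ValueError("contact_cutoff must be positive")
    mols = (
        topology.molecules("drug") if molecule_ids is None else list(molecule_ids)
    )
    heavy = {
        m: [
            i for i in topology.atoms_of(m)
            if topology.elements[i] != "H"
        ]
        for m in mols
    }
    uf = _UnionFind(mols)
    for idx, m1 in enumerate(mols):
        a1 = coords[heavy[m1]]
        for m2 in mols[idx + 1:]:
            dist = pairwise_minimum_image_distances(a1, coords[heavy[m2]], box)
            if float(dist.min()) <= contact_cutoff:
                uf.union(m1, m2)
    groups: dict[int, list[int]] = {}
    for m in mols:
        groups.setdefault(uf.find(m), []).append(m)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def aggregates_series(
    traj: Trajectory,
    molecule_ids: Sequence[int] | None = None,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    frames: slice | Sequence[int] | None = None,
) -> AggregateSet:
    """Aggregate partitions across trajectory frames."""
    frame_idx = _frame_indices(traj.n_frames, frames)
    clusters = []
    for f in frame_idx:
        xyz, box = traj.frame(int(f))
        clusters.append(
            detect_aggregates(xyz, box, traj.topology, molecule_ids, contact_cutoff)
        )
    return AggregateSet(
        frames=[int(f) for f in frame_idx],
        clusters=clusters,
        contact_cutoff=contact_cutoff,
    )
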