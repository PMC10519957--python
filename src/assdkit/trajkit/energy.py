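"""Per-molecule interaction-energy decomposition with a pluggable pairwise
backend, plus bootstrap statistics.

The decomposition follows the snapshot procedure used for MM/GBSA-style
aggregation energies: at a fixed stride along the equilibrated part of a
trajectory, each drug molecule belonging to an aggregate is taken one at a
time and its interaction energy with the rest of the aggregate (drug:drug)
or with the rest of the drug-oligomer complex (total) is evaluated; the
drug:oligomer energy is the difference of the two.  Molecules outside
aggregates are neglected.  Because every molecule is scored against the
rest, each intra-aggregate pair energy appears in exactly two per-molecule
values; per-molecule energies are therefore never summed into a "total
aggregate energy".

The shipped backend is a toy pairwise evaluator (Lennard-Jones + Coulomb
with an optional Born-like screening term reported as the solvation
component).  It stands in for a generalized-Born treatment, whose internals
are out of scope here; any object with the same ``pair_energy`` contract
(symmetric, zero against an empty set, additive over disjoint partitions)
can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .analysis import DEFAULT_CONTACT_CUTOFF, detect_aggregates
from .core import Topology, Trajectory
from .geometry import minimum_image_displacement, pairwise_minimum_image_distances

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyComponents",
    "EnergyBackend",
    "ToyEnergyBackend",
    "toy_energy_backend",
    "BootstrapResult",
    "bootstrap_stats",
    "EnergyReport",
    "drug_drug_energy",
    "drug_oligomer_energy",
]

#: Coulomb prefactor in kcal/mol for charges in e and distances in Angstrom.
COULOMB_CONSTANT = 332.0636

HARD_DISTANCE_FLOOR = 0.1  # Angstrom


@dataclass(frozen=True)
class EnergyComponents:
    """Interaction energy split into van der Waals, electrostatic and
    solvation parts (kcal/mol); ``total`` is their exact sum."""

    vdw: float
    elec: float
    solv: float

    @property
    def total(self) -> float:
        return self.vdw + self.elec + self.solv

    def __add__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(
            self.vdw + other.vdw, self.elec + other.elec, self.solv + other.solv
        )

    def __sub__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(
            self.vdw - other.vdw, self.elec - other.elec, self.solv - other.solv
        )


ZERO_ENERGY = EnergyComponents(0.0, 0.0, 0.0)


class EnergyBackend(Protocol):
    """Contract for pairwise-additive group-group energy evaluators."""

    def pair_energy(
        self,
        coords: np.ndarray,
        box: np.ndarray,
        group_a: Sequence[int],
        group_b: Sequence[int],
    ) -> EnergyComponents: ...


class ToyEnergyBackend:
    """Lennard-Jones + Coulomb (+ Born-like screening) pairwise evaluator.

    * LJ with Lorentz-Berthelot combining, ``4 eps ((s/r)^12 - (s/r)^6)``.
    * Coulomb ``332.0636 q_i q_j / (eps_r(r) r)`` with a constant or
      distance-dependent (``eps_r = dielectric * r``) dielectric.
    * Optional solvation term ``-(1 - 1/eps_solvent) * 332.0636 q_i q_j /
      f(r)`` with the Born-style smoothing ``f = sqrt(r^2 + a^2 exp(-r^2 /
      (4 a^2)))`` and constant effective radius ``a``.

    All terms vanish beyond the interaction cutoff; within it each pair term
    is shifted by its value at the cutoff so the energy is continuous.
    Distances below a hard floor of 0.1 A are clamped with a warning.
    """

    def __init__(
        self,
        topology: Topology,
        dielectric: float = 1.0,
        distance_dependent_dielectric: bool = False,
        cutoff: float = 12.0,
        shift: bool = True,
        solvation: bool = False,
        eps_solvent: float = 78.5,
        born_radius: float = 1.5,
    ):
        if dielectric <= 0 or cutoff <= 0 or eps_solvent <= 0 or born_radius <= 0:
            raise ValueError("backend parameters must be positive")
        self.topology = topology
        self.dielectric = dielectric
        self.distance_dependent = distance_dependent_dielectric
        self.cutoff = cutoff
        self.shift = shift
        self.solvation = solvation
        self.eps_solvent = eps_solvent
        self.born_radius = born_radius

    def _terms(
        self, r: np.ndarray, sigma: np.ndarray, eps: np.ndarray, qq: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sr6 = (sigma / r) ** 6
        vdw = 4.0 * eps * (sr6 * sr6 - sr6)
        if self.distance_dependent:
            elec = COULOMB_CONSTANT * qq / (self.dielectric * r * r)
        else:
            elec = COULOMB_CONSTANT * qq / (self.dielectric * r)
        if self.solvation:
            a2 = self.born_radius**2
            f = np.sqrt(r * r + a2 * np.exp(-(r * r) / (4.0 * a2)))
            solv = -(1.0 - 1.0 / self.eps_solvent) * COULOMB_CONSTANT * qq / f
        else:
            solv = np.zeros_like(r)
        return vdw, elec, solv

    def pair_energy(
        self,
        coords: np.ndarray,
        box: np.ndarray,
        group_a: Sequence[int],
        group_b: Sequence[int],
    ) -> EnergyComponents:
        a = np.asarray(group_a, dtype=int)
        b = np.asarray(group_b, dtype=int)
        if a.size == 0 or b.size == 0:
            return ZERO_ENERGY
        if np.intersect1d(a, b).size:
            raise ValueError("groups must be disjoint")
        top = self.topology
        r = pairwise_minimum_image_distances(coords[a], coords[b], box)
        clamped = r < HARD_DISTANCE_FLOOR
        if np.any(clamped):
            warnings.warn(
                f"{int(clamped.sum())} pair distance(s) below "
                f"{HARD_DISTANCE_FLOOR} A clamped",
                stacklevel=2,
            )
            r = np.maximum(r, HARD_DISTANCE_FLOOR)
        within = r <= self.cutoff
        if not np.any(within):
            return ZERO_ENERGY
        sigma = 0.5 * (top.lj_sigma[a][:, None] + top.lj_sigma[b][None, :])
        eps = np.sqrt(top.lj_epsilon[a][:, None] * top.lj_epsilon[b][None, :])
        qq = top.charges[a][:, None] * top.charges[b][None, :]
        vdw, elec, solv = self._terms(r, sigma, eps, qq)
        if self.shift:
            rc = np.full_like(r, self.cutoff)
            vdw_c, elec_c, solv_c = self._terms(rc, sigma, eps, qq)
            vdw, elec, solv = vdw - vdw_c, elec - elec_c, solv - solv_c
        return EnergyComponents(
            float(vdw[within].sum()),
            float(elec[within].sum()),
            float(solv[within].sum()),
        )


def toy_energy_backend(topology: Topology, **kwargs) -> ToyEnergyBackend:
    """Construct the toy Lennard-Jones/Coulomb backend (see
    :class:`ToyEnergyBackend` for parameters)."""
    return ToyEnergyBackend(topology, **kwargs)


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap-of-the-mean summary with a 95% percentile interval."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_boot: int


def bootstrap_stats(
    samples: Sequence[float],
    n_boot: int = 1000,
    seed: int = 2023,
    ci: float = 0.95,
) -> BootstrapResult:
    """Resample-with-replacement statistics of the sample mean."""
    values = np.asarray(samples, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - ci) / 2.0
    return BootstrapResult(
        mean=float(means.mean()),
        sd=float(means.std(ddof=1)),
        ci_low=float(np.quantile(means, alpha)),
        ci_high=float(np.quantile(means, 1.0 - alpha)),
        n_boot=n_boot,
    )


@dataclass
class EnergyReport:
    """Per-frame, per-molecule energies with summary and bootstrap statistics.

    ``records`` has one row per (frame, molecule) sample.  Per-molecule
    values score each molecule against the rest of its aggregate, so every
    intra-aggregate pair energy is counted twice across rows; the rows are
    averaged, never summed.
    """

    records: pd.DataFrame
    stride_ps: float
    frames: list[int]
    bootstrap: dict[str, BootstrapResult]
    empty: bool = False

    def mean(self, column: str = "E_total") -> float:
        if self.empty:
            raise ValueError("empty energy report (no aggregated molecules)")
        return float(self.records[column].mean())

    def sd(self, column: str = "E_total") -> float:
        if self.empty:
            raise ValueError("empty energy report (no aggregated molecules)")
        return float(self.records[column].std(ddof=1)) if len(self.records) > 1 else 0.0

    @property
    def n_samples(self) -> int:
        return len(self.records)


def stride_frames(
    times: np.ndarray, start_index: int, stride_ps: float
) -> list[int]:
    """Frame indices sampled at the stride: the nearest frame at or after
    each tick ``t_start + k * stride``."""
    if stride_ps <= 0:
        raise ValueError("stride must be positive")
    picked: list[int] = []
    tick = times[start_index]
    i = start_index
    n = times.size
    while i < n:
        while i < n and times[i] < tick - 1e-9:
            i += 1
        if i >= n:
            break
        if not picked or picked[-1] != i:
            picked.append(i)
        tick += stride_ps
    return picked


def _empty_report(stride_ps: float, frames: list[int], columns) -> EnergyReport:
    return EnergyReport(
        records=pd.DataFrame(columns=list(columns)),
        stride_ps=stride_ps,
        frames=frames,
        bootstrap={},
        empty=True,
    )


def _bootstrap_columns(
    records: pd.DataFrame, columns: Sequence[str], n_boot: int, seed: int
) -> dict[str, BootstrapResult]:
    out = {}
    for i, col in enumerate(columns):
        if len(records) >= 2:
            out[col] = bootstrap_stats(
                records[col].to_numpy(), n_boot=n_boot, seed=seed + i
            )
    return out


def drug_drug_energy(
    traj: Trajectory,
    backend: EnergyBackend,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    stride_ps: float = 100.0,
    start_frame: int | None = None,
    n_boot: int = 500,
    seed: int = 2023,
) -> EnergyReport:
    """Per-molecule drug:drug aggregation energies.

    For each sampled frame and each drug molecule in an aggregate of size at
    least 2, the backend scores the molecule against the rest of its
    aggregate; molecules outside aggregates are neglected.
    """
    top = traj.topology
    start = traj.n_frames // 2 if start_frame is None else start_frame
    frames = stride_frames(traj.times, start, stride_ps)
    rows = []
    for f in frames:
        xyz, box = traj.frame(f)
        clusters = detect_aggregates(
            xyz, box, top, top.molecules("drug"), contact_cutoff
        )
        for cluster in clusters:
            if len(cluster) < 2:
                continue
            atom_sets = {m: top.atoms_of(m) for m in cluster}
            for m in cluster:
                rest = np.concatenate([atom_sets[o] for o in cluster if o != m])
                e = backend.pair_energy(xyz, box, atom_sets[m], rest)
                rows.append(
                    {
                        "frame": f,
                        "time_ps": traj.times[f],
                        "molecule": m,
                        "aggregate_size": len(cluster),
                        "E_vdw": e.vdw,
                        "E_elec": e.elec,
                        "E_solv": e.solv,
                        "E_total": e.total,
                    }
                )
    columns = [
        "frame", "time_ps", "molecule", "aggregate_size",
        "E_vdw", "E_elec", "E_solv", "E_total",
    ]
    if not rows:
        return _empty_report(stride_ps, frames, columns)
    records = pd.DataFrame(rows, columns=columns)
    return EnergyReport(
        records=records,
        stride_ps=stride_ps,
        frames=frames,
        bootstrap=_bootstrap_columns(records, ["E_total"], n_boot, seed),
    )


def drug_oligomer_energy(
    traj: Trajectory,
    backend: EnergyBackend,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    stride_ps: float = 100.0,
    start_frame: int | None = None,
    n_boot: int = 500,
    seed: int = 2023,
) -> EnergyReport:
    """Per-molecule drug:oligomer energies by total-minus-drug:drug subtraction.

    For each aggregated drug molecule the backend scores it against the rest
    of the drug-oligomer complex (other aggregated drugs plus the oligomer);
    subtracting the drug:drug part gives the drug:oligomer interaction.  A
    drug molecule is aggregated when it belongs to a drug aggregate of size
    at least 2 or is itself in contact with the oligomer.
    """
    top = traj.topology
    olig_mols = top.molecules("oligomer")
    if not olig_mols:
        raise ValueError("no oligomer present in the topology")
    olig_atoms = np.concatenate([top.atoms_of(m) for m in olig_mols])
    olig_heavy = olig_atoms[
        [top.elements[i] != "H" for i in olig_atoms]
    ]
    start = traj.n_frames // 2 if start_frame is None else start_frame
    frames = stride_frames(traj.times, start, stride_ps)
    rows = []
    for f in frames:
        xyz, box = traj.frame(f)
        drug_mols = top.molecules("drug")
        clusters = detect_aggregates(xyz, box, top, drug_mols, contact_cutoff)
        in_drug_aggregate = {
            m for cluster in clusters if len(cluster) >= 2 for m in cluster
        }
        members = []
        for m in drug_mols:
            if m in in_drug_aggregate:
                members.append(m)
                continue
            heavy = [i for i in top.atoms_of(m) if top.elements[i] != "H"]
            dmin = pairwise_minimum_image_distances(
                xyz[heavy], xyz[olig_heavy], box
            ).min()
            if dmin <= contact_cutoff:
                members.append(m)
        atom_sets = {m: top.atoms_of(m) for m in members}
        for m in members:
            others = [o for o in members if o != m]
            other_atoms = (
                np.concatenate([atom_sets[o] for o in others])
                if others
                else np.array([], dtype=int)
            )
            e_dd = backend.pair_energy(xyz, box, atom_sets[m], other_atoms)
            complex_atoms = np.concatenate([other_atoms, olig_atoms])
            e_total = backend.pair_energy(xyz, box, atom_sets[m], complex_atoms)
            e_olig = e_total - e_dd
            rows.append(
                {
                    "frame": f,
                    "time_ps": traj.times[f],
                    "molecule": m,
                    "E_drug_drug": e_dd.total,
                    "E_total": e_total.total,
                    "E_drug_oligomer": e_olig.total,
                    "E_olig_vdw": e_olig.vdw,
                    "E_olig_elec": e_olig.elec,
                    "E_olig_solv": e_olig.solv,
                }
            )
    columns = [
        "frame", "time_ps", "molecule",
        "E_drug_drug", "E_total", "E_drug_oligomer",
        "E_olig_vdw", "E_olig_elec", "E_olig_solv",
    ]
    if not rows:
        return _empty_report(stride_ps, frames, columns)
    records = pd.DataFrame(rows, columns=columns)
    return EnergyReport(
        records=records,
        stride_ps=stride_ps,
        frames=frames,
        bootstrap=_bootstrap_columns(
            records, ["E_drug_drug", "E_drug_oligomer"], n_boot, seed
        ),
    )
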