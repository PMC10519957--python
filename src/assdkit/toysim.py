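"""Synthetic toy-dynamics generator.

Builds coarse bead models of supersaturated drug / oligomer / counterion
boxes and runs seeded overdamped (Brownian) dynamics on them, so that every
trajectory-analysis operator can be exercised end to end with no external
data.  The generator emulates the layout of the reference all-atom systems
-- 11-13 drug molecules in a periodic box, optionally one oligomer chain and
neutralizing counterions -- at drastically reduced resolution: a drug is a
handful of Lennard-Jones beads carrying one hydrogen-bond donor (heavy atom
plus polar hydrogen) and one acceptor; the oligomer is a harmonic bead
chain with acceptor beads along it.  Solvent is implicit (friction + noise);
interfaces stay in Angstrom and kcal/mol so the analysis operators consume
the output unchanged.

Aggregation propensity is controlled by the drug charge state (anionic
drugs repel and stay dispersed) and by the Lennard-Jones well depths
(``drug_eps_scale``, ``oligomer_eps_scale``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .formulation import random_insertion
from .trajkit.core import Bond, Topology, Trajectory
from .trajkit.geometry import minimum_image_displacement, wrap_coordinates

__all__ = [
    "ToySimParams",
    "ToySystem",
    "InstabilityError",
    "build_toy_system",
    "run_toy_dynamics",
    "plant_hbonds",
]


class InstabilityError(RuntimeError):
    """The integrator produced an exploding displacement."""


# Drug template: star around a core bead.
#   index 0 core C, 1 donor N, 2 polar H (bonded to 1), 3 acceptor O, 4 tail C
_DRUG_ELEMENTS = ["C", "N", "H", "O", "C"]
_DRUG_MASSES = [40.0, 14.0, 1.0, 16.0, 40.0]
_DRUG_SIGMA = [4.0, 3.2, 1.0, 3.0, 4.0]
_DRUG_EPS = [1.0, 0.15, 0.02, 0.15, 1.0]   # core/tail eps scaled by drug_eps_scale
_DRUG_CHARGES_NEUTRAL = [0.30, -0.45, 0.35, -0.40, 0.20]
# Deprotonated state: the -1 sits next to the acceptor and the donor dipole
# is strongly reduced (a deprotonated donor no longer donates).
_DRUG_CHARGES_ANIONIC = [-0.80, -0.20, 0.10, -0.30, 0.20]
_DRUG_OFFSETS = np.array(
    [
        [0.0, 0.0, 0.0],
        [2.5, 0.0, 0.0],
        [3.5, 0.0, 0.0],
        [-1.5, 2.0, 0.0],
        [-1.5, -2.4, 0.0],
    ]
)
# bond rest lengths equal the template geometry, so a freshly built
# molecule is at its bonded-energy minimum
_DRUG_BONDS = [
    (i, j, float(np.linalg.norm(_DRUG_OFFSETS[i] - _DRUG_OFFSETS[j])))
    for i, j in ((0, 1), (1, 2), (0, 3), (0, 4))
]

_OLIGOMER_LENGTH = 20
_OLIGOMER_BOND_R0 = 3.5
_ION_SIGMA = 6.0   # hydrated-ion effective size
_ION_EPS = 0.1


@dataclass(frozen=True)
class ToySimParams:
    """Settings for one overdamped-dynamics run.

    Units are nominal: distances in Angstrom, energies in kcal/mol, time in
    ps.  ``temperature`` is the thermal energy kT in kcal/mol (0.4 is a
    slightly cold, aggregation-friendly bath; ~0.6 corresponds to 300 K).
    """

    n_steps: int = 4000
    dt: float = 0.02                  # ps
    n_relax_steps: int = 200          # noiseless pre-relaxation steps
    friction: float = 1.0             # kcal/mol ps / A^2
    temperature: float = 0.4          # kT, kcal/mol
    drug_eps_scale: float = 1.0
    oligomer_eps_scale: float = 1.0
    seed: int = 2023
    snapshot_interval: int = 40       # steps between saved frames
    cutoff: float = 12.0              # nonbonded cutoff, A
    dielectric: float = 20.0
    force_cap: float = 10.0           # per-pair force magnitude cap, kcal/mol/A
    displacement_cap: float = 0.3     # per-atom deterministic step cap, A
    max_step_displacement: float = 2.5  # instability abort threshold, A

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.snapshot_interval < 1:
            raise ValueError("step counts and intervals must be positive")
        if min(self.dt, self.friction, self.cutoff, self.dielectric) <= 0:
            raise ValueError("dt, friction, cutoff and dielectric must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class ToySystem:
    """A built system ready for dynamics."""

    topology: Topology
    coords: np.ndarray      # (n_atoms, 3), Angstrom
    box: np.ndarray         # (3,), Angstrom


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_toy_system(
    n_drug: int,
    charge_state: Literal["neutral", "anionic"] = "neutral",
    with_oligomer: bool = False,
    box_edge: float = 50.0,
    seed: int = 2023,
    drug_eps_scale: float = 1.0,
    oligomer_eps_scale: float = 1.0,
    min_separation: float = 8.0,
) -> ToySystem:
    """Assemble drug molecules (plus optional oligomer and counterions).

    Anionic drugs carry -1 on the bead adjacent to the acceptor and one +1
    counterion bead is added per drug anion, keeping the box electroneutral.
    Molecule centres come from seeded random insertion with a minimum-image
    separation of ``min_separation``.
    """
    if n_drug < 1:
        raise ValueError("need at least one drug molecule")
    n_ions = n_drug if charge_state == "anionic" else 0
    n_molecules = n_drug + (1 if with_oligomer else 0) + n_ions
    centres = random_insertion(
        n_molecules, (box_edge,) * 3, min_separation, seed=seed
    )
    rng = np.random.default_rng(seed + 1)

    elements: list[str] = []
    masses: list[float] = []
    molecule_ids: list[int] = []
    charges: list[float] = []
    sigma: list[float] = []
    epsilon: list[float] = []
    donor: list[bool] = []
    acceptor: list[bool] = []
    h_link: list[int] = []
    bonds: list[Bond] = []
    species: dict[int, str] = {}
    coords: list[np.ndarray] = []

    drug_charges = list(
        _DRUG_CHARGES_ANIONIC if charge_state == "anionic" else _DRUG_CHARGES_NEUTRAL
    )

    mol = 0
    for d in range(n_drug):
        base = len(elements)
        rot = _random_rotation(rng)
        offsets = _DRUG_OFFSETS @ rot.T
        for k in range(len(_DRUG_ELEMENTS)):
            elements.append(_DRUG_ELEMENTS[k])
            masses.append(_DRUG_MASSES[k])
            molecule_ids.append(mol)
            charges.append(drug_charges[k])
            sigma.append(_DRUG_SIGMA[k])
            eps = _DRUG_EPS[k]
            if k in (0, 4):
                eps *= drug_eps_scale
            epsilon.append(eps)
            donor.append(k == 1)
            acceptor.append(k == 3)
            h_link.append(base + 1 if k == 2 else -1)
            coords.append(centres[mol] + offsets[k])
        for i, j, r0 in _DRUG_BONDS:
            bonds.append(Bond(base + i, base + j, r0=r0, k=10.0))
        species[mol] = "drug"
        mol += 1

    if with_oligomer:
        base = len(elements)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for k in range(_OLIGOMER_LENGTH):
            is_acceptor = k % 3 == 2
            elements.append("O" if is_acceptor else "C")
            masses.append(30.0)
            molecule_ids.append(mol)
            charges.append(-0.2 if is_acceptor else (0.2 if k % 3 == 0 and k else 0.0))
            sigma.append(4.0)
            epsilon.append(0.3 * oligomer_eps_scale)
            donor.append(False)
            acceptor.append(is_acceptor)
            h_link.append(-1)
            coords.append(centres[mol] + direction * _OLIGOMER_BOND_R0 * k)
            if k:
                bonds.append(Bond(base + k - 1, base + k, r0=_OLIGOMER_BOND_R0, k=10.0))
        species[mol] = "oligomer"
        mol += 1

    for _ in range(n_ions):
        elements.append("Na")
        masses.append(23.0)
        molecule_ids.append(mol)
        charges.append(1.0)
        sigma.append(_ION_SIGMA)
        epsilon.append(_ION_EPS)
        donor.append(False)
        acceptor.append(False)
        h_link.append(-1)
        coords.append(centres[mol])
        species[mol] = "ion"
        mol += 1

    # fix any tiny residual so the box is exactly electroneutral
    total = sum(charges)
    if abs(total - 0.0) > 1e-9:
        # distribute tiny residuals (from the oligomer pattern) over its beads
        olig_atoms = [i for i, m in enumerate(molecule_ids) if species[m] == "oligomer"]
        if olig_atoms:
            shift = -total / len(olig_atoms)
            for i in olig_atoms:
                charges[i] += shift
        else:
            raise ValueError(f"system carries net charge {total:+.3f}e")

    topology = Topology(
        elements=elements,
        masses=np.array(masses),
        molecule_ids=np.array(molecule_ids),
        charges=np.array(charges),
        lj_sigma=np.array(sigma),
        lj_epsilon=np.array(epsilon),
        molecule_species=species,
        donor_flags=np.array(donor),
        acceptor_flags=np.array(acceptor),
        hydrogen_donor_index=np.array(h_link),
        bonds=bonds,
    )
    box = np.full(3, float(box_edge))
    return ToySystem(topology, wrap_coordinates(np.array(coords), box), box)


def _forces(
    coords: np.ndarray,
    box: np.ndarray,
    top: Topology,
    params: ToySimParams,
    same_molecule: np.ndarray,
) -> np.ndarray:
    """Nonbonded (LJ + Coulomb, intermolecular) plus harmonic bond forces."""
    n = coords.shape[0]
    delta = minimum_image_displacement(coords[None, :, :], coords[:, None, :], box)
    r2 = np.sum(delta * delta, axis=-1)
    np.fill_diagonal(r2, np.inf)
    r2[same_molecule] = np.inf
    r2 = np.maximum(r2, 0.64)  # soft floor at 0.8 A against overlaps
    within = r2 <= params.cutoff**2
    r = np.sqrt(r2)

    sigma = 0.5 * (top.lj_sigma[:, None] + top.lj_sigma[None, :])
    eps = np.sqrt(top.lj_epsilon[:, None] * top.lj_epsilon[None, :])
    qq = top.charges[:, None] * top.charges[None, :]
    sr6 = (sigma**2 / r2) ** 3
    # dU/dr terms: F = -dU/dr along r_hat (delta points from j to i... sign below)
    f_lj = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    f_coul = 332.0636 * qq / (params.dielectric * r2)
    # cap only the attractive side so overlapping pairs cannot implode;
    # core repulsion stays unbounded (the displacement trust region keeps
    # the update integrable)
    f_mag = np.maximum(f_lj + f_coul, -params.force_cap)
    f_mag = np.where(within, f_mag, 0.0)
    # delta[i, j] = r_i - r_j points from j toward i, so a positive
    # (repulsive) pair term pushes i along +delta
    forces = np.sum((f_mag / r)[:, :, None] * delta, axis=1)

    for bond in top.bonds:
        d = minimum_image_displacement(coords[bond.i], coords[bond.j], box)
        dist = float(np.linalg.norm(d))
        if dist == 0:
            continue
        f = bond.k * (dist - bond.r0) * d / dist
        forces[bond.i] += f
        forces[bond.j] -= f
    return forces


def run_toy_dynamics(system: ToySystem, params: ToySimParams) -> Trajectory:
    """Overdamped Langevin dynamics; bitwise deterministic for a given seed.

    Position update per step: ``x += F dt / gamma + sqrt(2 kT dt / gamma) N``
    with periodic wrapping.  Aborts with :class:`InstabilityError` when any
    per-step displacement exceeds the configured threshold, and rejects
    parameter sets whose initial deterministic displacement exceeds 0.5 A.
    """
    top = system.topology
    coords = system.coords.copy()
    box = system.box
    rng = np.random.default_rng(params.seed)
    same_molecule = top.molecule_ids[:, None] == top.molecule_ids[None, :]
    mobility = params.dt / params.friction
    noise_scale = np.sqrt(2.0 * params.temperature * params.dt / params.friction)

    # quench insertion overlaps: capped-force steepest descent, no noise
    relax_step = min(mobility, 0.01)
    for _ in range(params.n_relax_steps):
        forces = _forces(coords, box, top, params, same_molecule)
        disp = np.clip(forces * relax_step, -0.1, 0.1)
        coords = wrap_coordinates(coords + disp, box)

    initial = _forces(coords, box, top, params, same_molecule)
    max_init = float(np.abs(initial * mobility).max())
    if max_init >= 0.5:
        raise ValueError(
            f"dt too large: initial deterministic displacement {max_init:.2f} A "
            ">= 0.5 A; reduce dt or extend the pre-relaxation"
        )

    times = [0.0]
    frames = [coords.copy()]
    for step in range(1, params.n_steps + 1):
        forces = _forces(coords, box, top, params, same_molecule)
        disp = forces * mobility
        # limited-displacement update: rescale any deterministic step larger
        # than the trust radius (keeps dense aggregates integrable)
        norms = np.linalg.norm(disp, axis=1, keepdims=True)
        scale = np.minimum(1.0, params.displacement_cap / np.maximum(norms, 1e-12))
        disp = disp * scale
        if params.temperature > 0:
            disp = disp + noise_scale * rng.standard_normal(coords.shape)
        max_disp = float(np.abs(disp).max())
        if max_disp > params.max_step_displacement:
            raise InstabilityError(
                f"step {step}: displacement {max_disp:.2f} A exceeds "
                f"{params.max_step_displacement} A (dt {params.dt}, "
                f"friction {params.friction})"
            )
        coords = wrap_coordinates(coords + disp, box)
        if step % params.snapshot_interval == 0:
            times.append(step * params.dt)
            frames.append(coords.copy())
    return Trajectory(
        topology=top,
        times=np.array(times),
        boxes=np.tile(box, (len(times), 1)),
        coords=np.array(frames),
    )


def plant_hbonds(
    traj: Trajectory,
    donor: int,
    acceptor: int,
    target_fraction: float,
    seed: int = 2023,
) -> Trajectory:
    """Overwrite donor/H/acceptor geometry so that exactly
    ``round(target_fraction * n_frames)`` randomly chosen frames satisfy the
    default hydrogen-bond criterion (d = 2.9 A, angle ~175 deg) and the rest
    fail it (d = 4.5 A).

    Test-fixture operation: the returned trajectory is a copy.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    top = traj.topology
    if not 0 <= donor < top.n_atoms or not 0 <= acceptor < top.n_atoms:
        raise ValueError("donor or acceptor atom index out of range")
    if not top.donor_flags[donor]:
        raise ValueError(f"atom {donor} is not a donor heavy atom")
    hydrogens = top.hydrogens_of_donor(donor)
    if hydrogens.size == 0:
        raise ValueError(f"donor {donor} has no linked hydrogen")
    hydrogen = int(hydrogens[0])

    n = traj.n_frames
    n_conforming = int(round(target_fraction * n))
    rng = np.random.default_rng(seed)
    conforming = set(rng.choice(n, size=n_conforming, replace=False).tolist())

    coords = traj.coords.copy()
    u = np.array([1.0, 0.0, 0.0])
    # H placed 1 A from the donor, 3 degrees off the donor->acceptor axis,
    # which gives a donor-H...acceptor angle of ~175.5 degrees at d = 2.9 A
    tilt = np.deg2rad(3.0)
    h_offset = np.array([np.cos(tilt), np.sin(tilt), 0.0])
    for f in range(n):
        base = coords[f, donor]
        d = 2.9 if f in conforming else 4.5
        coords[f, acceptor] = base + d * u
        coords[f, hydrogen] = base + h_offset
    return Trajectory(
        topology=top,
        times=traj.times.copy(),
        boxes=traj.boxes.copy(),
        coords=coords,
    )
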