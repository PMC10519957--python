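"""Topology and trajectory containers for labelled-particle systems.

A :class:`Topology` stores per-atom annotations needed by all downstream
operators: element, mass, molecule id, partial charge, Lennard-Jones
parameters and hydrogen-bond role flags (donor heavy atom, acceptor, polar
hydrogen with a link to its bonded donor).  A :class:`Trajectory` couples a
topology to a stack of periodic frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = ["Topology", "Trajectory", "Bond"]

Species = Literal["drug", "oligomer", "ion", "solvent"]


@dataclass(frozen=True)
class Bond:
    """A harmonic bond between two atoms (used by the toy dynamics)."""

    i: int
    j: int
    r0: float = 1.5       # Angstrom
    k: float = 100.0      # kcal/mol/A^2


@dataclass
class Topology:
    """Labelled particles partitioned into molecules."""

    elements: list[str]
    masses: np.ndarray                 # Da
    molecule_ids: np.ndarray           # int per atom
    charges: np.ndarray                # e
    lj_sigma: np.ndarray               # Angstrom
    lj_epsilon: np.ndarray             # kcal/mol
    molecule_species: Mapping[int, str]  # molecule id -> species
    donor_flags: np.ndarray = None     # heavy atoms that donate H-bonds
    acceptor_flags: np.ndarray = None  # H-bond acceptors
    hydrogen_donor_index: np.ndarray = None  # per atom: donor index or -1
    names: list[str] | None = None
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.elements)
        self.masses = np.asarray(self.masses, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        if self.donor_flags is None:
            self.donor_flags = np.zeros(n, dtype=bool)
        if self.acceptor_flags is None:
            self.acceptor_flags = np.zeros(n, dtype=bool)
        if self.hydrogen_donor_index is None:
            self.hydrogen_donor_index = np.full(n, -1, dtype=int)
        self.donor_flags = np.asarray(self.donor_flags, dtype=bool)
        self.acceptor_flags = np.asarray(self.acceptor_flags, dtype=bool)
        self.hydrogen_donor_index = np.asarray(self.hydrogen_donor_index, dtype=int)
        if self.names is None:
            self.names = [f"{el}{i}" for i, el in enumerate(self.elements)]
        arrays = (
            self.masses, self.molecule_ids, self.charges,
            self.lj_sigma, self.lj_epsilon, self.donor_flags,
            self.acceptor_flags, self.hydrogen_donor_index,
        )
        if any(a.shape != (n,) for a in arrays) or len(self.names) != n:
            raise ValueError("all per-atom arrays must have one entry per atom")
        missing = set(np.unique(self.molecule_ids)) - set(self.molecule_species)
        if missing:
            raise ValueError(f"molecules without species annotation: {sorted(missing)}")
        for idx in np.nonzero(self.hydrogen_donor_index >= 0)[0]:
            donor = self.hydrogen_donor_index[idx]
            if not self.donor_flags[donor]:
                raise ValueError(
                    f"atom {idx} links to atom {donor}, which is not a donor heavy atom"
                )
            if self.molecule_ids[idx] != self.molecule_ids[donor]:
                raise ValueError(
                    f"polar hydrogen {idx} and donor {donor} belong to different molecules"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def molecules(self, species: str | None = None) -> list[int]:
        """Sorted molecule ids, optionally restricted to one species."""
        ids = sorted(set(self.molecule_ids.tolist()))
        if species is None:
            return ids
        return [m for m in ids if self.molecule_species[m] == species]

    def atoms_of(self, molecule_id: int) -> np.ndarray:
        return np.nonzero(self.molecule_ids == molecule_id)[0]

    def select(
        self,
        species: str | None = None,
        element: str | None = None,
        role: Literal["donor", "acceptor", "polar_hydrogen"] | None = None,
        molecule_id: int | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Atom indices matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if species is not None:
            allowed = set(self.molecules(species))
            mask &= np.isin(self.molecule_ids, list(allowed))
        if element is not None:
            mask &= np.array([el == element for el in self.elements])
        if role == "donor":
            mask &= self.donor_flags
        elif role == "acceptor":
            mask &= self.acceptor_flags
        elif role == "polar_hydrogen":
            mask &= self.hydrogen_donor_index >= 0
        if molecule_id is not None:
            mask &= self.molecule_ids == molecule_id
        if heavy_only:
            mask &= np.array([el != "H" for el in self.elements])
        return np.nonzero(mask)[0]

    def hydrogens_of_donor(self, donor_index: int) -> np.ndarray:
        return np.nonzero(self.hydrogen_donor_index == donor_index)[0]


@dataclass
class Trajectory:
    """Periodic frames over a fixed topology."""

    topology: Topology
    times: np.ndarray        # ps
    boxes: np.ndarray        # (n_frames, 3) edge lengths, Angstrom
    coords: np.ndarray       # (n_frames, n_atoms, 3), Angstrom

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n_frames = self.times.shape[0]
        if self.coords.shape != (n_frames, self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate array {self.coords.shape} inconsistent with "
                f"{n_frames} frames of {self.topology.n_atoms} atoms"
            )
        if self.boxes.shape != (n_frames, 3):
            raise ValueError("boxes must be (n_frames, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.boxes <= 0):
            raise ValueError("box edges must be positive")
        if n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    def frame(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """(coords, box) of one frame."""
        return self.coords[index], self.boxes[index]
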