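import numpy as np
import pytest

from assdkit.gcontrib import load_default_table, load_reference_decompositions
from assdkit.trajkit.core import Topology, Trajectory


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def decomps():
    return load_reference_decompositions()


def make_point_topology(
    n_atoms,
    molecule_ids=None,
    charges=None,
    elements=None,
    sigma=3.0,
    epsilon=0.1,
    species="drug",
):
    """Minimal topology of free point particles for geometry/RDF tests."""
    if molecule_ids is None:
        molecule_ids = np.arange(n_atoms)
    molecule_ids = np.asarray(molecule_ids)
    if elements is None:
        elements = ["C"] * n_atoms
    return Topology(
        elements=list(elements),
        masses=np.ones(n_atoms),
        molecule_ids=molecule_ids,
        charges=np.zeros(n_atoms) if charges is None else np.asarray(charges, float),
        lj_sigma=np.full(n_atoms, float(sigma)),
        lj_epsilon=np.full(n_atoms, float(epsilon)),
        molecule_species={int(m): species for m in np.unique(molecule_ids)},
    )


def make_trajectory(topology, frames, box_edge=20.0, times=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    if times is None:
        times = np.arange(n, dtype=float)
    boxes = np.tile(np.full(3, float(box_edge)), (n, 1))
    return Trajectory(topology=topology, times=times, boxes=boxes, coords=frames)


@pytest.fixture
def point_topology_factory():
    return make_point_topology


@pytest.fixture
def trajectory_factory():
    return make_trajectory
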