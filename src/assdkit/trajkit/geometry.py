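"""Periodic-geometry primitives (orthorhombic boxes only)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "minimum_image_displacement",
    "minimum_image_distance",
    "pairwise_minimum_image_distances",
    "wrap_coordinates",
]


def minimum_image_displacement(a, b, box) -> np.ndarray:
    """Displacement b - a under per-axis nearest-image wrapping.

    Broadcasts over leading dimensions; ``box`` is the (3,) edge-length
    vector of an orthorhombic cell.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    delta = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_distance(a, b, box) -> float | np.ndarray:
    """Euclidean distance under the minimum-image convention."""
    delta = minimum_image_displacement(a, b, box)
    return np.linalg.norm(delta, axis=-1)


def pairwise_minimum_image_distances(
    coords_a: np.ndarray, coords_b: np.ndarray, box
) -> np.ndarray:
    """(n_a, n_b) matrix of minimum-image distances between two coordinate sets."""
    delta = minimum_image_displacement(
        coords_a[:, None, :], coords_b[None, :, :], box
    )
    return np.sqrt(np.sum(delta * delta, axis=-1))


def wrap_coordinates(coords: np.ndarray, box) -> np.ndarray:
    """Wrap coordinates into the primary cell [0, box)."""
    box = np.asarray(box, dtype=float)
    return np.mod(coords, box)
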