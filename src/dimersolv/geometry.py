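"""Minimum-image geometry helpers (orthorhombic boxes only)."""

from __future__ import annotations

import numpy as np

from .errors import SelectionError
from .topology import Topology, Trajectory, require_nonempty


def minimum_image(dvec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vector(s) into the minimum-image convention."""
    dvec = np.asarray(dvec, dtype=float)
    box = np.asarray(box, dtype=float)
    return dvec - box * np.round(dvec / box)


def pair_distances(
    pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """(n_a, n_b) matrix of minimum-image distances."""
    d = pos_a[:, None, :] - pos_b[None, :, :]
    d = minimum_image(d, box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def pair_sq_distances(
    pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Squared minimum-image distances; exact at stated cutoffs (no sqrt)."""
    d = pos_a[:, None, :] - pos_b[None, :, :]
    d = minimum_image(d, box)
    return np.einsum("ijk,ijk->ij", d, d)


def center_of_mass(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> np.ndarray:
    """Centroid or mass-weighted centroid of coordinates.

    Assumes the group is whole (not split across the periodic boundary);
    the toy generators always emit whole molecules.
    """
    coords = np.asarray(coords, dtype=float)
    if masses is None:
        return coords.mean(axis=0)
    masses = np.asarray(masses, dtype=float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def com_distance(
    topology: Topology,
    frame: np.ndarray,
    box: np.ndarray,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    mass_weighted: bool = True,
) -> float:
    """Minimum-image distance between the (mass-weighted) centroids of two
    disjoint selections. This is the reaction coordinate xi = r_COM-COM."""
    selection_a = require_nonempty(np.asarray(selection_a), "selection_a")
    selection_b = require_nonempty(np.asarray(selection_b), "selection_b")
    if np.intersect1d(selection_a, selection_b).size:
        raise SelectionError("selections overlap")
    ma = topology.masses[selection_a] if mass_weighted else None
    mb = topology.masses[selection_b] if mass_weighted else None
    ca = center_of_mass(frame[selection_a], ma)
    cb = center_of_mass(frame[selection_b], mb)
    return float(np.linalg.norm(minimum_image(ca - cb, box)))


def com_distance_series(
    topology: Topology,
    trajectory: Trajectory,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame COM distance along a trajectory."""
    return np.array(
        [
            com_distance(topology, f, b, selection_a, selection_b, mass_weighted)
            for f, b in trajectory
        ]
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
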