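"""Vectorized geometry primitives shared by the builder, force field and tests."""

from __future__ import annotations

import numpy as np

__all__ = ["bond_lengths", "bend_angles", "dihedral_angles", "rotation_matrix"]


def bond_lengths(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Distances |x_i - x_j| for an (n, 2) index array."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.linalg.norm(d, axis=1)


def bend_angles(coords: np.ndarray, triples: np.ndarray) -> np.ndarray:
    """Angles theta_ijk (rad) at the middle bead of each (i, j, k) triple."""
    triples = np.asarray(triples, dtype=int).reshape(-1, 3)
    a = coords[triples[:, 0]] - coords[triples[:, 1]]
    b = coords[triples[:, 2]] - coords[triples[:, 1]]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("degenerate angle: coincident beads")
    cosang = np.einsum("ij,ij->i", a, b) / (na * nb)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def dihedral_angles(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Signed dihedral angles phi_ijkl (rad) for (i, j, k, l) quadruples."""
    quads = np.asarray(quads, dtype=int).reshape(-1, 4)
    b1 = coords[quads[:, 1]] - coords[quads[:, 0]]
    b2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    b3 = coords[quads[:, 3]] - coords[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation by ``angle`` (rad) about a (normalized) axis vector."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ux, uy, uz = axis
    c, s = np.cos(angle), np.sin(angle)
    return np.array(
        [
            [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
        ]
    )
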