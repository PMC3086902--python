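"""Low-level geometry: minimum image, NeRF atom placement, Kabsch superposition.

All coordinates are in nm unless a function says otherwise.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "min_image_displacement",
    "min_image_distance",
    "place_atom_nerf",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd",
]


def min_image_displacement(dx: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention of a cubic box.

    ``dx`` has shape (..., 3); ``box`` is the 3 edge lengths or None (no PBC).
    """
    if box is None:
        return dx
    box = np.asarray(box, dtype=float)
    return dx - box * np.round(dx / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Pairwise-broadcastable Euclidean distance under minimum image."""
    d = min_image_displacement(np.asarray(a, float) - np.asarray(b, float), box)
    return np.sqrt((d * d).sum(axis=-1))


def place_atom_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                    bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom D given atoms A-B-C, |C-D|, angle(B,C,D) and dihedral(A,B,C,D).

    Natural extension reference frame construction; angles in radians.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    # local displacement in the (bc, m, n) frame
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimizing RMSD.

    Returns ``(R, t, rmsd)`` with the convention ``moved = mobile @ R.T + t``.
    Raises ValueError for degenerate (rank-deficient / collinear) inputs.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("superposition requires matching (n, 3) coordinate arrays")
    if P.shape[0] < 3:
        raise ValueError("superposition requires at least 3 atoms")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear point sets give a rank<2 covariance -> rotation underdetermined
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) coordinates: superposition underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    moved = P @ R.T + t
    return R, t, rmsd(moved, Q)


def apply_superposition(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD (no fitting)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt((d * d).sum() / len(d)))
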