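"""Low-level rigid-body geometry: dihedrals, internal-coordinate atom
placement, and Kabsch superposition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


class DegenerateSelectionError(ValueError):
    """Fewer than three atoms, or a collinear selection."""


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    ang = np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def angle_between(v1, v2) -> float:
    """Unsigned angle between two vectors, degrees."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Place atom D given chain A-B-C with |CD|=bond, angle(BCD) and
    dihedral(ABCD) — the natural extension reference frame step."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(180.0 - angle_deg)
    tor = np.radians(dihedral_deg)
    d_local = bond * np.array(
        [np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (det +1) and translation minimising the
    RMSD over paired atoms, plus the residual RMSD itself.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (N, 3)")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateSelectionError("need at least 3 atoms to superpose")
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    mc = mob - mob_c
    rc = ref - ref_c
    sv = np.linalg.svd(mc, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateSelectionError("selection is (nearly) collinear")
    rot, rssd = Rotation.align_vectors(rc, mc)
    R = rot.as_matrix()
    t = ref_c - mob_c @ R.T
    return Superposition(rotation=R, translation=t, rmsd=float(rssd) / np.sqrt(n))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
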