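"""Four-class Ramachandran region classification on a 10-degree grid.

Backbone (phi, psi) pairs are classified as ``most_favored``,
``additional``, ``generous`` or ``disallowed`` using nested boolean maps
on the periodic 36x36 grid, in the spirit of classical NMR-structure
validation reports.  The maps are built from explicit core basins
(alpha-helical, beta/extended, and left-handed alpha) which are then
grown by periodic binary dilation: one 10-degree shell for the
``additional`` belt and two further shells for ``generous``.  Dilation
guarantees the nesting most_favored < additional < generous by
construction.  Glycine gets a point-symmetric map (its achiral backbone
populates the mirrored basins) and proline a phi-restricted one.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

GRID_DEG = 10
NBIN = 360 // GRID_DEG

REGIONS = ("most_favored", "additional", "generous", "disallowed")


def _rect(grid: np.ndarray, phi_lo: float, phi_hi: float, psi_lo: float, psi_hi: float) -> None:
    """Mark a half-open rectangle [lo, hi) in degrees on the grid (phi rows)."""
    i0 = int((phi_lo + 180) // GRID_DEG)
    i1 = int((phi_hi + 180) // GRID_DEG)
    j0 = int((psi_lo + 180) // GRID_DEG)
    j1 = int((psi_hi + 180) // GRID_DEG)
    grid[i0:i1, j0:j1] = True


def _dilate_wrap(grid: np.ndarray, iterations: int) -> np.ndarray:
    """Binary dilation with periodic (wrapped) boundaries."""
    k = iterations
    padded = np.pad(grid, k, mode="wrap")
    dil = ndimage.binary_dilation(padded, structure=np.ones((3, 3), bool), iterations=k)
    return dil[k:-k, k:-k]


def _build(core_rects, extra_additional_rects=()):
    core = np.zeros((NBIN, NBIN), dtype=bool)
    for r in core_rects:
        _rect(core, *r)
    additional = _dilate_wrap(core, 1)
    for r in extra_additional_rects:
        _rect(additional, *r)
    generous = _dilate_wrap(additional, 2)
    return core, additional, generous


# Core basins of the general map: right-handed alpha, beta/extended
# (including the psi ~ 180 wrap), and nothing else.  The left-handed
# alpha basin enters at the "additional" level for non-glycine residues.
_GENERAL_CORE = [
    (-160, -40, -70, -10),   # alpha
    (-170, -60, 90, 180),    # beta / PPII
    (-170, -60, -180, -170), # beta, psi wrap
]
_GENERAL_ADDITIONAL = [
    (40, 70, 10, 60),        # left-handed alpha
]

_GENERAL = _build(_GENERAL_CORE, _GENERAL_ADDITIONAL)

_GLY_CORE = _GENERAL_CORE + [
    # point-symmetric partners (phi, psi) -> (-phi, -psi)
    (40, 160, 10, 70),
    (60, 170, -180, -90),
    (60, 170, 170, 180),
]
_GLYCINE = _build(_GLY_CORE)

_PRO_CORE = [
    (-110, -40, -70, -10),
    (-110, -40, 90, 180),
    (-110, -40, -180, -170),
]
_PROLINE = _build(_PRO_CORE)

_MAPS = {"general": _GENERAL, "GLY": _GLYCINE, "PRO": _PROLINE}


def ramachandran_classify(phi: float, psi: float, resname: str = "general") -> str:
    """Classify one (phi, psi) pair into the four nested regions.

    ``resname`` may be a three-letter code; glycine and proline use
    their own maps, everything else the general one.
    """
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("phi/psi must be finite")
    core, additional, generous = _MAPS.get(resname.upper(), _GENERAL)
    i = int(((phi + 180.0) % 360.0) // GRID_DEG) % NBIN
    j = int(((psi + 180.0) % 360.0) // GRID_DEG) % NBIN
    if core[i, j]:
        return "most_favored"
    if additional[i, j]:
        return "additional"
    if generous[i, j]:
        return "generous"
    return "disallowed"
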