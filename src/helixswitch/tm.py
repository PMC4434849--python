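"""Geometry of two transmembrane helices along a coarse-grained trajectory.

Each helix is reduced to backbone (BB) and side-chain (SC) beads.  The
module fits helix axes, measures the membrane-plane interhelical
distance, computes the signed crossing angle (negative = right-handed
packing), detects the initial encounter and persistent dimer intervals,
profiles contacts of the five-valine dimerization motif, and summarises
the crossing-angle distribution (median, modality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .structures import Atom, StructureEnsemble, StructureError


class Bead(NamedTuple):
    helix: str  # "A" or "B"
    resnum: int
    role: str  # "BB" or "SC"


@dataclass(frozen=True)
class CGTrajectory:
    """Time-ordered frames of labelled beads for two helices."""

    beads: tuple[Bead, ...]
    coords: np.ndarray  # (n_frames, n_beads, 3) Angstrom
    dt_ns: float = 1.0
    box: tuple[float, float, float] = (100.0, 100.0, 100.0)
    normal_axis: int = 2  # membrane normal (z by default)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_beads, 3)")
        if coords.shape[1] != len(self.beads):
            raise ValueError("bead roster and coords disagree")
        if coords.shape[0] < 1:
            raise ValueError("need at least one frame")
        helices = {b.helix for b in self.beads}
        if helices != {"A", "B"}:
            raise ValueError(f"expected helices A and B, got {sorted(helices)}")
        object.__setattr__(self, "beads", tuple(self.beads))
        object.__setattr__(self, "coords", coords)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def bead_indices(
        self,
        helix: Optional[str] = None,
        role: Optional[str] = None,
        resnums: Optional[Sequence[int]] = None,
    ) -> np.ndarray:
        resnums = set(resnums) if resnums is not None else None
        idx = [
            i
            for i, b in enumerate(self.beads)
            if (helix is None or b.helix == helix)
            and (role is None or b.role == role)
            and (resnums is None or b.resnum in resnums)
        ]
        return np.asarray(idx, int)

    # ---- I/O: whitespace table and multi-model PDB ----

    def to_table(self, path: str | Path) -> None:
        lines = [
            f"# dt_ns {self.dt_ns}",
            f"# box {self.box[0]} {self.box[1]} {self.box[2]} normal {'xyz'[self.normal_axis]}",
            "# frame helix resnum role x y z",
        ]
        for f in range(self.n_frames):
            for b, xyz in zip(self.beads, self.coords[f]):
                lines.append(
                    f"{f} {b.helix} {b.resnum} {b.role} "
                    f"{xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f}"
                )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path, dt_ns: Optional[float] = None) -> "CGTrajectory":
        box = (100.0, 100.0, 100.0)
        normal = 2
        file_dt = 1.0
        frames: dict[int, list[tuple[Bead, list[float]]]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                f = line[1:].split()
                if f[:1] == ["dt_ns"]:
                    file_dt = float(f[1])
                elif f[:1] == ["box"]:
                    box = (float(f[1]), float(f[2]), float(f[3]))
                    if len(f) >= 6 and f[4] == "normal":
                        normal = "xyz".index(f[5])
                continue
            f = line.split()
            frame = int(f[0])
            bead = Bead(helix=f[1], resnum=int(f[2]), role=f[3])
            frames.setdefault(frame, []).append(
                (bead, [float(f[4]), float(f[5]), float(f[6])])
            )
        order = sorted(frames)
        roster = tuple(b for b, _ in frames[order[0]])
        coords = np.empty((len(order), len(roster), 3))
        for k, fr in enumerate(order):
            if tuple(b for b, _ in frames[fr]) != roster:
                raise ValueError("bead roster differs between frames")
            coords[k] = [xyz for _, xyz in frames[fr]]
        return cls(
            beads=roster,
            coords=coords,
            dt_ns=dt_ns if dt_ns is not None else file_dt,
            box=box,
            normal_axis=normal,
        )

    def to_pdb(self, path: str | Path) -> None:
        """One MODEL per frame; helix as chain is not preserved by the
        shared writer, so helix id is encoded in the residue number
        offset of helix B (resnum + 1000)."""
        atoms = tuple(
            Atom(
                resnum=b.resnum + (1000 if b.helix == "B" else 0),
                resname="VAL",
                name=b.role,
                element="C",
            )
            for b in self.beads
        )
        StructureEnsemble(atoms=atoms, coords=self.coords).to_pdb(path)

    @classmethod
    def from_pdb(cls, path: str | Path, dt_ns: float = 1.0) -> "CGTrajectory":
        ens = StructureEnsemble.from_pdb(path)
        beads = tuple(
            Bead(
                helix="B" if a.resnum >= 1000 else "A",
                resnum=a.resnum % 1000,
                role=a.name,
            )
            for a in ens.atoms
        )
        return cls(beads=beads, coords=ens.coords, dt_ns=dt_ns)


@dataclass(frozen=True)
class HelixAxis:
    centroid: np.ndarray
    direction: np.ndarray  # unit, N->C
    span: tuple[int, int]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        object.__setattr__(self, "direction", d / np.linalg.norm(d))
        object.__setattr__(self, "centroid", np.asarray(self.centroid, float))


def fit_helix_axis(
    traj_or_coords,
    helix: Optional[str] = None,
    frame: int = 0,
    window: int = 4,
    raw_pca: bool = False,
) -> HelixAxis:
    """Fit the axis of one helix in one frame.

    Sliding ``window``-residue centroids of the backbone beads are
    computed along the sequence (suppressing the helical wobble of
    individual beads) and the principal direction of those centroids is
    the axis; ``raw_pca`` skips the windowing.  The direction is
    oriented N-terminus to C-terminus.
    """
    if isinstance(traj_or_coords, CGTrajectory):
        idx = traj_or_coords.bead_indices(helix=helix, role="BB")
        resnums = [traj_or_coords.beads[i].resnum for i in idx]
        order = np.argsort(resnums)
        coords = traj_or_coords.coords[frame][idx][order]
        span = (min(resnums), max(resnums))
    else:
        coords = np.asarray(traj_or_coords, float)
        span = (0, len(coords) - 1)
    if len(coords) < 7:
        raise ValueError("need at least 7 backbone beads to fit an axis")
    if raw_pca:
        pts = coords
    else:
        pts = np.array(
            [coords[i : i + window].mean(axis=0) for i in range(len(coords) - window + 1)]
        )
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]
    if np.dot(direction, pts[-1] - pts[0]) < 0:
        direction = -direction
    return HelixAxis(centroid=centroid, direction=direction, span=span)


def interhelical_distance(
    axis_a: HelixAxis, axis_b: HelixAxis, membrane_normal=(0.0, 0.0, 1.0)
) -> float:
    """Centroid separation projected onto the membrane plane."""
    n = np.asarray(membrane_normal, float)
    n = n / np.linalg.norm(n)
    d = axis_b.centroid - axis_a.centroid
    d = d - np.dot(d, n) * n
    return float(np.linalg.norm(d))


def crossing_angle(axis_a: HelixAxis, axis_b: HelixAxis) -> float:
    """Signed interhelical (crossing) angle in (-90, 90] degrees.

    The magnitude is the angle between the axis directions folded to
    <= 90 degrees; the sign is the chirality of the dihedral
    axisA -> line of closest approach -> axisB.  Negative angles
    correspond to right-handed helix packing, so a reflection of the
    coordinates flips the sign.  Exactly parallel axes return 0.
    """
    a = axis_a.direction
    b = axis_b.direction
    cross = np.cross(a, b)
    if np.linalg.norm(cross) < 1e-12:
        return 0.0
    # closest-approach points between the two axis lines
    pa, pb = axis_a.centroid, axis_b.centroid
    w0 = pa - pb
    a_dot_b = np.dot(a, b)
    denom = 1.0 - a_dot_b**2
    t = (a_dot_b * np.dot(b, w0) - np.dot(a, w0)) / denom
    s = (np.dot(b, w0) - a_dot_b * np.dot(a, w0)) / denom
    conn = (pb + s * b) - (pa + t * a)
    if np.linalg.norm(conn) < 1e-9:
        conn = cross
    n_hat = conn / np.linalg.norm(conn)
    y = np.dot(n_hat, cross)
    x = a_dot_b - np.dot(a, n_hat) * np.dot(b, n_hat)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return ang


@dataclass(frozen=True)
class DimerTimeline:
    distance: np.ndarray  # per-frame interhelical distance
    min_contact: np.ndarray  # per-frame minimum inter-helix bead distance
    encounter_frame: Optional[int]
    intervals: tuple[tuple[int, int], ...]  # inclusive frame ranges
    angles: np.ndarray  # signed crossing angle, NaN outside intervals

    def dimer_frames(self) -> np.ndarray:
        mask = np.zeros(len(self.distance), dtype=bool)
        for s, e in self.intervals:
            mask[s : e + 1] = True
        return np.flatnonzero(mask)


def _contact_runs(contact: np.ndarray, persistence: int) -> list[tuple[int, int]]:
    """Maximal contact runs, tolerating single-frame gaps, of length
    >= persistence."""
    runs: list[list[int]] = []
    current: Optional[list[int]] = None
    gap = 0
    for f, c in enumerate(contact):
        if c:
            if current is None:
                current = [f, f]
            else:
                current[1] = f
            gap = 0
        elif current is not None:
            gap += 1
            if gap > 1:
                runs.append(current)
                current = None
                gap = 0
    if current is not None:
        runs.append(current)
    return [(s, e) for s, e in runs if e - s + 1 >= persistence]


def detect_encounter_and_dimers(
    traj: CGTrajectory,
    contact_cutoff: float = 6.0,
    persistence_frames: int = 10,
) -> DimerTimeline:
    """Encounter frame and persistent dimer intervals of a trajectory.

    The encounter is the first frame where the minimum inter-helix bead
    distance drops to ``contact_cutoff`` or below.  Dimer intervals are
    maximal runs of the contact condition lasting at least
    ``persistence_frames`` (single-frame gaps tolerated); the crossing
    angle series is evaluated only inside those intervals.
    """
    ia = traj.bead_indices(helix="A")
    ib = traj.bead_indices(helix="B")
    diff = traj.coords[:, ia, None, :] - traj.coords[:, None, ib, :]
    min_contact = np.sqrt((diff**2).sum(axis=-1)).reshape(traj.n_frames, -1).min(axis=1)
    contact = min_contact <= contact_cutoff
    encounter = int(np.argmax(contact)) if contact.any() else None
    intervals = tuple(_contact_runs(contact, persistence_frames))
    distance = np.empty(traj.n_frames)
    angles = np.full(traj.n_frames, np.nan)
    dimer_mask = np.zeros(traj.n_frames, bool)
    for s, e in intervals:
        dimer_mask[s : e + 1] = True
    normal = np.eye(3)[traj.normal_axis]
    for f in range(traj.n_frames):
        axis_a = fit_helix_axis(traj, "A", f)
        axis_b = fit_helix_axis(traj, "B", f)
        distance[f] = interhelical_distance(axis_a, axis_b, normal)
        if dimer_mask[f]:
            angles[f] = crossing_angle(axis_a, axis_b)
    return DimerTimeline(
        distance=distance,
        min_contact=min_contact,
        encounter_frame=encounter,
        intervals=intervals,
        angles=angles,
    )


DEFAULT_MOTIF = (282, 286)


def motif_contact_profile(
    traj: CGTrajectory, motif: tuple[int, int] = DEFAULT_MOTIF
) -> np.ndarray:
    """Distances from each motif side chain to the opposite motif center.

    Returns an array of shape (n_frames, motif_length, 2): entry
    [f, k, 0] is d(SC of motif residue k on helix A -> center of the
    motif SC beads on helix B) and [f, k, 1] the mirrored B -> A
    distance.
    """
    residues = list(range(motif[0], motif[1] + 1))
    idx = {}
    for h in "AB":
        for r in residues:
            sel = traj.bead_indices(helix=h, role="SC", resnums=[r])
            if sel.size != 1:
                raise StructureError(f"missing SC bead for residue {r} helix {h}")
            idx[(h, r)] = sel[0]
    sc_a = traj.coords[:, [idx[("A", r)] for r in residues], :]
    sc_b = traj.coords[:, [idx[("B", r)] for r in residues], :]
    center_a = sc_a.mean(axis=1)
    center_b = sc_b.mean(axis=1)
    d_a = np.linalg.norm(sc_a - center_b[:, None, :], axis=-1)
    d_b = np.linalg.norm(sc_b - center_a[:, None, :], axis=-1)
    return np.stack([d_a, d_b], axis=-1)


def classify_orientation(frame_profile: np.ndarray, tolerance: float = 2.0) -> str:
    """symmetric iff the A->B and B->A motif distance patterns agree
    within ``tolerance`` (Angstrom) for every motif residue."""
    diff = np.abs(frame_profile[:, 0] - frame_profile[:, 1])
    return "symmetric" if np.max(diff) <= tolerance else "asymmetric"


@dataclass(frozen=True)
class AngleSummary:
    median: Optional[float]
    n_modes: int
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    empty: bool = False


def angle_distribution_summary(
    timeline: DimerTimeline, bin_width: float = 5.0
) -> AngleSummary:
    """Median and modality of the dimer-frame crossing-angle distribution.

    The histogram spans (-90, 90] with ``bin_width`` bins and is
    smoothed with a 1-bin-sigma Gaussian before modes (local maxima
    above 10% of the global maximum) are counted.
    """
    angles = timeline.angles[timeline.dimer_frames()]
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        return AngleSummary(
            median=None,
            n_modes=0,
            histogram_edges=np.array([]),
            histogram_counts=np.array([]),
            empty=True,
        )
    edges = np.arange(-90.0, 90.0 + bin_width, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    smooth = gaussian_filter1d(counts.astype(float), sigma=1.0, mode="constant")
    peak = smooth.max()
    n_modes = 0
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < len(smooth) - 1 else -np.inf
        if smooth[i] > left and smooth[i] >= right and smooth[i] > 0.1 * peak:
            n_modes += 1
    return AngleSummary(
        median=float(np.median(angles)),
        n_modes=n_modes,
        histogram_edges=edges,
        histogram_counts=counts,
    )


def residue_run_interface_check(
    traj: CGTrajectory,
    timeline: DimerTimeline,
    motif: tuple[int, int] = DEFAULT_MOTIF,
) -> Optional[float]:
    """Fraction of dimer frames whose closest inter-helix side-chain
    contact involves motif residues on both helices.

    Returns None (with a warning) when there are no dimer frames.
    """
    frames = timeline.dimer_frames()
    if frames.size == 0:
        warnings.warn("no dimer frames; interface fraction undefined", stacklevel=2)
        return None
    ia = traj.bead_indices(helix="A", role="SC")
    ib = traj.bead_indices(helix="B", role="SC")
    res_a = np.array([traj.beads[i].resnum for i in ia])
    res_b = np.array([traj.beads[i].resnum for i in ib])
    lo, hi = motif
    hits = 0
    for f in frames:
        d = np.linalg.norm(
            traj.coords[f][ia][:, None, :] - traj.coords[f][ib][None, :, :], axis=-1
        )
        k = np.unravel_index(np.argmin(d), d.shape)
        if lo <= res_a[k[0]] <= hi and lo <= res_b[k[1]] <= hi:
            hits += 1
    return hits / frames.size
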