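"""Synthetic inputs with known ground truth.

Every file format the analysis modules consume can be generated here
with its true parameters recorded alongside: ideal peptide models built
from a (phi, psi) plan, Gaussian-jittered conformer ensembles with
engineered salt bridges, two-state CD spectra whose 222 nm ellipticity
equals the coil/helix mixture exactly, geometrically satisfied
distance/torsion restraint lists, and rigid-body two-helix
coarse-grained trajectories with programmed lateral diffusion,
encounter, crossing angle and axial-rotation episodes.

The trajectory generator is kinematic, not dynamic: it emulates the
analyzable phenomenology of a coarse-grained dimerization simulation
(diffusion, encounter, persistent dimer at a set crossing angle)
without forces, lipids or solvent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .cd import CDSample, CDSpectrum, RAW_MDEG
from .geometry import place_atom
from .sequences import TROP2TM, PeptideSeq
from .structures import Atom, StructureEnsemble, ONE_TO_THREE
from .structures import DistanceRestraint, RestraintList, TorsionRestraint
from .tm import Bead, CGTrajectory, fit_helix_axis

# ---- ideal peptide builder ----

# Ideal backbone geometry (Engh/Huber-style averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA_TRANS = 180.0

COIL_PHI_PSI = (-120.0, 120.0)

# Distance (Angstrom) from CA to the charged-group pseudo-atom along the
# CA->CB direction, and the atom name used for it.
CHARGED_PSEUDO = {
    "ARG": ("NH1", 5.5),
    "LYS": ("NZ", 5.0),
    "GLU": ("OE1", 4.0),
    "ASP": ("OD1", 3.2),
    "SEP": ("O1P", 4.5),
}


class PlanError(ValueError):
    """Overlapping or out-of-range secondary-structure spans."""


def _resolve_plan(
    seq: PeptideSeq, ss_plan: Optional[Sequence[tuple[tuple[int, int], float, float]]]
) -> dict[int, tuple[float, float]]:
    plan = {lab: COIL_PHI_PSI for lab in seq.labels()}
    seen: set[int] = set()
    for (first, last), phi, psi in ss_plan or ():
        if first > last or first < seq.start_number or last > seq.end_number:
            raise PlanError(f"span {first}-{last} outside sequence")
        span = set(range(first, last + 1))
        if span & seen:
            raise PlanError("overlapping secondary-structure spans")
        seen |= span
        for lab in span:
            plan[lab] = (phi, psi)
    return plan


def build_ideal_peptide(
    seq: PeptideSeq,
    ss_plan: Optional[Sequence[tuple[tuple[int, int], float, float]]] = None,
) -> StructureEnsemble:
    """Build a one-model peptide from a per-span (phi, psi) plan.

    Backbone N, CA, C, O are placed with ideal bond geometry; each
    non-glycine residue gets a CB and, for charged residue types
    (Arg/Lys/Glu/Asp/phosphoSer), a single charged-group pseudo-atom
    along the CA->CB direction.  Residues outside any planned span are
    built as extended coil at (phi, psi) = (-120, 120).  Caps flagged on
    the sequence are emitted as ACE / NME residues.
    """
    plan = _resolve_plan(seq, ss_plan)
    labels = list(seq.labels())
    n = len(labels)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    # first residue in a canonical frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    # C makes the ideal N-CA-C angle with the N-CA bond, in the xy plane
    C[0] = CA[0] + BOND_CA_C * np.array(
        [-np.cos(np.radians(ANGLE_N_CA_C)), np.sin(np.radians(ANGLE_N_CA_C)), 0.0]
    )
    for i in range(1, n):
        phi_i = plan[labels[i]][0]
        psi_prev = plan[labels[i - 1]][1]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi_i)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []

    def emit(resnum: int, resname: str, name: str, element: str, xyz) -> None:
        atoms.append(Atom(resnum=resnum, resname=resname, name=name, element=element))
        coords.append(np.asarray(xyz, float))

    if seq.n_acetyl:
        c_ace = place_atom(C[0], CA[0], N[0], BOND_C_N, ANGLE_C_N_CA, 180.0)
        o_ace = place_atom(CA[0], N[0], c_ace, BOND_C_O, 123.0, 0.0)
        ch3 = place_atom(CA[0], N[0], c_ace, 1.50, 116.0, 180.0)
        r = seq.start_number - 1
        emit(r, "ACE", "CH3", "C", ch3)
        emit(r, "ACE", "C", "C", c_ace)
        emit(r, "ACE", "O", "O", o_ace)
    for i, lab in enumerate(labels):
        one = seq[lab]
        resname = "SEP" if seq.is_phosphorylated(lab) else ONE_TO_THREE[one]
        psi_i = plan[lab][1]
        emit(lab, resname, "N", "N", N[i])
        emit(lab, resname, "CA", "C", CA[i])
        emit(lab, resname, "C", "C", C[i])
        emit(lab, resname, "O", "O", place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0))
        if one != "G":
            cb = place_atom(C[i], N[i], CA[i], 1.53, 110.5, 122.6)
            emit(lab, resname, "CB", "C", cb)
            if resname in CHARGED_PSEUDO:
                name, radius = CHARGED_PSEUDO[resname]
                u = (cb - CA[i]) / np.linalg.norm(cb - CA[i])
                emit(lab, resname, name, name[0], CA[i] + radius * u)
    if seq.c_amide:
        psi_last = plan[labels[-1]][1]
        n_nme = place_atom(N[-1], CA[-1], C[-1], BOND_C_N, ANGLE_CA_C_N, psi_last)
        ch3 = place_atom(CA[-1], C[-1], n_nme, 1.458, ANGLE_C_N_CA, 180.0)
        r = seq.end_number + 1
        emit(r, "NME", "N", "N", n_nme)
        emit(r, "NME", "CH3", "C", ch3)
    return StructureEnsemble(atoms=tuple(atoms), coords=np.asarray(coords)[None, :, :])


def jitter_ensemble(
    model: StructureEnsemble, n_models: int, noise_sigma: float, seed: int = 0
) -> StructureEnsemble:
    """Isotropic Gaussian jitter of one model into an ensemble.

    Model 1 is the unperturbed original; the remaining models add
    independent N(0, sigma) displacements per coordinate.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    base = model.coords[0]
    coords = np.tile(base, (n_models, 1, 1))
    if noise_sigma > 0:
        coords[1:] += rng.normal(0.0, noise_sigma, size=coords[1:].shape)
    return model.with_coords(coords)


def engineer_salt_bridge(
    ensemble: StructureEnsemble,
    acidic_res: int,
    basic_res: int,
    target_distance: float = 3.0,
    models: Optional[Sequence[int]] = None,
) -> StructureEnsemble:
    """Move the charged-group pseudo-atoms to a target separation.

    Only the basic residue's pseudo-atom moves (along the line joining
    the two groups), and only in the selected models; everything else
    is untouched.
    """
    from .ensemble import ACIDIC_GROUP_ATOMS, BASIC_GROUP_ATOMS

    def group_index(resnum: int, table) -> int:
        resname = ensemble.resname(resnum)
        if resname not in table:
            raise TypeError(f"residue {resname}{resnum} is not of the required charge type")
        for name in table[resname]:
            try:
                return ensemble.atom_index(resnum, name)
            except KeyError:
                continue
        raise KeyError(f"no charged-group atom for {resname}{resnum}")

    ia = group_index(acidic_res, ACIDIC_GROUP_ATOMS)
    ib = group_index(basic_res, BASIC_GROUP_ATOMS)
    coords = ensemble.coords.copy()
    model_list = range(ensemble.n_models) if models is None else models
    for m in model_list:
        u = coords[m, ib] - coords[m, ia]
        norm = np.linalg.norm(u)
        u = u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        coords[m, ib] = coords[m, ia] + target_distance * u
    return ensemble.with_coords(coords)


# ---- CD spectra ----

# Gaussian basis shapes.  Contractual facts: the coil basis has its
# minimum at 198 nm and equals +640 deg cm^2 dmol^-1 at 222 nm; the
# helix basis has minima at 208 and 222 nm and equals -42500 at 222 nm.
_COIL_CENTER, _COIL_WIDTH, _COIL_DEPTH = 198.0, 9.0, 40000.0
_COIL_OFFSET = 640.0 + _COIL_DEPTH * np.exp(-((222.0 - _COIL_CENTER) / _COIL_WIDTH) ** 2)
_HELIX_WIDTH = 6.0
_HELIX_DEPTH_208 = 39000.0
_HELIX_DEPTH_222 = 42500.0 - _HELIX_DEPTH_208 * np.exp(
    -((222.0 - 208.0) / _HELIX_WIDTH) ** 2
)


def coil_basis(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, float)
    return _COIL_OFFSET - _COIL_DEPTH * np.exp(-(((wl - _COIL_CENTER) / _COIL_WIDTH) ** 2))


def helix_basis(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, float)
    return -_HELIX_DEPTH_208 * np.exp(-(((wl - 208.0) / _HELIX_WIDTH) ** 2)) - _HELIX_DEPTH_222 * np.exp(
        -(((wl - 222.0) / _HELIX_WIDTH) ** 2)
    )


DEFAULT_CD_SAMPLE = CDSample(conc_mM=0.05, n_residues=26, path_cm=0.1, tfe_percent=70.0)


def generate_cd_spectrum(
    f_H: float,
    wavelengths: Optional[np.ndarray] = None,
    noise_mdeg: float = 0.0,
    sample: CDSample = DEFAULT_CD_SAMPLE,
    seed: int = 0,
) -> tuple[CDSpectrum, CDSpectrum, dict]:
    """Raw two-state CD spectrum plus its matching buffer blank.

    The underlying mean residue ellipticity is the exact mixture
    f_H * helix_basis + (1 - f_H) * coil_basis, converted to raw mdeg by
    inverting the MRE normalization with the sample metadata, added to a
    smooth instrument baseline (the blank), with optional Gaussian
    noise on both raw spectra.  Returns (sample, blank, truth).
    """
    if not 0.0 <= f_H <= 1.0:
        raise ValueError("f_H must be in [0, 1]")
    wl = (
        np.arange(190.0, 270.0 + 0.25, 0.5)
        if wavelengths is None
        else np.asarray(wavelengths, float)
    )
    rng = np.random.default_rng(seed)
    mre = f_H * helix_basis(wl) + (1.0 - f_H) * coil_basis(wl)
    scale = 10.0 * (sample.conc_mM / 1000.0) * sample.n_residues * sample.path_cm
    peptide_mdeg = mre * scale
    baseline = 0.5 + 0.01 * (wl - 230.0)  # smooth instrument/buffer drift
    blank_sig = baseline.copy()
    sample_sig = baseline + peptide_mdeg
    if noise_mdeg > 0:
        sample_sig = sample_sig + rng.normal(0.0, noise_mdeg, wl.shape)
        blank_sig = blank_sig + rng.normal(0.0, noise_mdeg, wl.shape)
    truth = {
        "f_H": f_H,
        "mre_222": float(f_H * helix_basis(np.array([222.0]))[0]
                         + (1.0 - f_H) * coil_basis(np.array([222.0]))[0]),
        "peptide_mdeg": peptide_mdeg,
    }
    return (
        CDSpectrum(wl, sample_sig, units=RAW_MDEG, sample=sample),
        CDSpectrum(wl, blank_sig, units=RAW_MDEG, sample=sample),
        truth,
    )


# ---- restraints ----


class QuotaError(ValueError):
    """Requested per-class restraint quota not satisfiable from geometry."""


def generate_restraints(
    model: StructureEnsemble,
    cutoff: float = 6.0,
    quotas: Optional[tuple[int, int, int, int]] = None,
    slack: float = 0.5,
    torsion_halfwidth: Optional[float] = None,
    model_index: int = 0,
) -> RestraintList:
    """Distance (and optionally torsion) restraints satisfied by a model.

    Heavy-atom pairs within ``cutoff`` become upper limits at the true
    distance plus ``slack`` (so the source model satisfies every
    restraint by construction).  ``quotas`` requests exact per-class
    counts (intra, sequential, medium, long by |i-j|); within each class
    the shortest candidate pairs are taken, deterministically.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    coords = model.model(model_index)
    heavy = [
        (i, a) for i, a in enumerate(model.atoms)
        if a.element != "H" and a.resname not in ("ACE", "NME")
    ]
    candidates: dict[str, list[tuple[float, DistanceRestraint]]] = {
        "intra": [], "sequential": [], "medium": [], "long": []
    }
    for x in range(len(heavy)):
        i, ai = heavy[x]
        for y in range(x + 1, len(heavy)):
            j, aj = heavy[y]
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d > cutoff:
                continue
            s = abs(ai.resnum - aj.resnum)
            cls = "intra" if s == 0 else "sequential" if s == 1 else "medium" if s < 5 else "long"
            candidates[cls].append(
                (
                    d,
                    DistanceRestraint(
                        res_i=ai.resnum, atom_i=ai.name, resname_i=ai.resname,
                        res_j=aj.resnum, atom_j=aj.name, resname_j=aj.resname,
                        upper=round(d + slack, 2),
                    ),
                )
            )
    for cls in candidates:
        candidates[cls].sort(key=lambda t: (t[0], t[1].res_i, t[1].res_j, t[1].atom_i, t[1].atom_j))
    if quotas is None:
        distance = tuple(r for cls in ("intra", "sequential", "medium", "long")
                         for _, r in candidates[cls])
    else:
        names = ("intra", "sequential", "medium", "long")
        chosen = []
        for cls, want in zip(names, quotas):
            have = len(candidates[cls])
            if want > have:
                raise QuotaError(
                    f"{cls}: quota {want} exceeds {have} geometric candidates at cutoff {cutoff}"
                )
            chosen.extend(r for _, r in candidates[cls][:want])
        distance = tuple(chosen)
    torsion: tuple[TorsionRestraint, ...] = ()
    if torsion_halfwidth is not None:
        from .ensemble import backbone_dihedrals

        tors = []
        for r, (phi, psi) in backbone_dihedrals(model, model_index).items():
            resname = model.resname(r)
            for name, ang in (("PHI", phi), ("PSI", psi)):
                if np.isfinite(ang):
                    tors.append(
                        TorsionRestraint(
                            resnum=r, resname=resname, angle=name,
                            lower=ang - torsion_halfwidth,
                            upper=ang + torsion_halfwidth,
                        )
                    )
        torsion = tuple(tors)
    return RestraintList(distance=distance, torsion=torsion)


# ---- coarse-grained two-helix systems ----

CG_BB_RADIUS = 2.3  # Angstrom, backbone bead distance from the helix axis
CG_SC_OFFSET = 3.0  # side-chain bead further out along the radial direction
CG_RISE = 1.5  # Angstrom per residue
CG_TWIST = 100.0  # degrees per residue
MOTIF_FACING_RESIDUE = 284  # central valine faces the partner helix


def _cg_helix(sequence: PeptideSeq = TROP2TM) -> tuple[list[tuple[int, str]], np.ndarray, np.ndarray]:
    """Ideal coarse-grained helix along +z, centered so the fitted axis
    centroid sits at the origin and the motif-facing residue points +x.

    Returns (residue list [(resnum, role)], bb+sc coords stacked per
    residue, in roster order)."""
    labels = list(sequence.labels())
    roster: list[tuple[int, str]] = []
    coords: list[np.ndarray] = []
    mid = (len(labels) - 1) / 2.0
    face_idx = labels.index(MOTIF_FACING_RESIDUE) if MOTIF_FACING_RESIDUE in labels else mid
    for k, lab in enumerate(labels):
        theta = np.radians(CG_TWIST * (k - face_idx))
        z = CG_RISE * (k - mid)
        bb = np.array([CG_BB_RADIUS * np.cos(theta), CG_BB_RADIUS * np.sin(theta), z])
        sc = np.array(
            [
                (CG_BB_RADIUS + CG_SC_OFFSET) * np.cos(theta),
                (CG_BB_RADIUS + CG_SC_OFFSET) * np.sin(theta),
                z,
            ]
        )
        roster.extend([(lab, "BB"), (lab, "SC")])
        coords.extend([bb, sc])
    xyz = np.asarray(coords)
    bb_idx = np.arange(0, len(xyz), 2)
    axis = fit_helix_axis(xyz[bb_idx])
    xyz = xyz - axis.centroid
    return roster, xyz, bb_idx


class GeometryError(ValueError):
    pass


def build_tm_system(
    separation: float = 50.0,
    box: tuple[float, float, float] = (100.0, 100.0, 100.0),
    sequence: PeptideSeq = TROP2TM,
) -> tuple[CGTrajectory, dict]:
    """Two vertical coarse-grained helices separated along x.

    Axes are along the membrane normal (z), fitted-axis centroids in the
    membrane midplane, exactly ``separation`` apart.  Helix B is the
    180-degree rotation of helix A about the central z axis, so the
    motif faces inward on both helices.
    """
    if separation >= min(box[0], box[1]):
        raise GeometryError("separation must be smaller than the lateral box size")
    roster, base, _ = _cg_helix(sequence)
    a = base + np.array([-separation / 2.0, 0.0, 0.0])
    rz = Rotation.from_euler("z", 180.0, degrees=True).as_matrix()
    b = a @ rz.T
    beads = tuple(Bead("A", r, role) for r, role in roster) + tuple(
        Bead("B", r, role) for r, role in roster
    )
    coords = np.concatenate([a, b])[None, :, :]
    traj = CGTrajectory(beads=beads, coords=coords, box=box)
    truth = {"separation": separation, "axis_direction": [0.0, 0.0, 1.0]}
    return traj, truth


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the rigid-body dimerization surrogate.

    Defaults mirror the simulated study conditions at a desk scale: two
    transmembrane helices starting 50 Angstrom apart in a 100 x 100
    Angstrom membrane patch, diffusing laterally until a programmed
    encounter, then held as a rigid dimer at the target crossing angle
    (-27 degrees, right-handed).  ``axial_rotations`` lists
    (start_frame, end_frame, degrees) episodes in which helix B is
    rotated about its own axis, producing asymmetric motif orientations.
    """

    seed: int = 0
    n_frames: int = 500
    dt_ns: float = 4.0
    box: tuple[float, float, float] = (100.0, 100.0, 100.0)
    separation: float = 50.0
    docked_separation: float = 8.0
    encounter_frame: Optional[int] = 100
    crossing_angle_deg: float = -27.0
    axial_rotations: tuple[tuple[int, int, float], ...] = ()
    axial_offset: float = 0.0
    noise_sigma: float = 0.0
    step_sigma: float = 1.0
    sequence: PeptideSeq = TROP2TM

    def __post_init__(self) -> None:
        if self.encounter_frame is not None and not (
            0 <= self.encounter_frame < self.n_frames
        ):
            raise ValueError("encounter_frame must lie inside the trajectory")
        if not (-90.0 < self.crossing_angle_deg <= 90.0):
            raise ValueError("crossing angle must be in (-90, 90]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _axial_rotation_at(config: GeneratorConfig, frame: int) -> float:
    rho = 0.0
    for start, end, deg in config.axial_rotations:
        if start <= frame <= end:
            rho += deg
    return rho


def simulate_rigid_dimerization(config: GeneratorConfig) -> tuple[CGTrajectory, dict]:
    """Kinematic two-helix trajectory with programmed ground truth.

    Before the encounter frame the two vertical helices perform
    independent 2-D random walks (reflective walls, pair separation kept
    above contact range); from the encounter on they form a rigid dimer
    at ``docked_separation`` with the target signed crossing angle,
    helix B optionally rotated about its own axis during scheduled
    episodes and/or shifted axially.  Optional isotropic bead noise is
    added last.  Returns (trajectory, truth) where truth records the
    encounter frame, the per-frame true crossing angle and the
    per-frame orientation class.
    """
    rng = np.random.default_rng(config.seed)
    roster, base, _ = _cg_helix(config.sequence)
    n_per = len(roster)
    beads = tuple(Bead("A", r, role) for r, role in roster) + tuple(
        Bead("B", r, role) for r, role in roster
    )
    helix_extent = CG_BB_RADIUS + CG_SC_OFFSET
    lo = np.array([-config.box[0] / 2.0 + helix_extent, -config.box[1] / 2.0 + helix_extent])
    hi = -lo
    min_free_sep = config.docked_separation + 2.0 * helix_extent + 4.0

    theta = config.crossing_angle_deg
    tilt_a = Rotation.from_euler("x", -theta / 2.0, degrees=True).as_matrix()
    rz = Rotation.from_euler("z", 180.0, degrees=True).as_matrix()
    # center the dock on the dimerization motif so the crossing point of
    # the tilted axes falls at the motif, as in a motif-mediated dimer
    sc_z = [xyz[2] for (r, role), xyz in zip(roster, base)
            if role == "SC" and MOTIF_FACING_RESIDUE - 2 <= r <= MOTIF_FACING_RESIDUE + 2]
    base_dock = base - np.array([0.0, 0.0, float(np.mean(sc_z))])

    pos_a = np.array([-config.separation / 2.0, 0.0])
    pos_b = np.array([config.separation / 2.0, 0.0])
    enc = config.encounter_frame
    coords = np.empty((config.n_frames, 2 * n_per, 3))
    true_angle = np.full(config.n_frames, np.nan)
    orientation: list[str] = []
    dock_center: Optional[np.ndarray] = None
    for f in range(config.n_frames):
        if enc is None or f < enc:
            for pos in (pos_a, pos_b):
                step = rng.normal(0.0, config.step_sigma, 2)
                pos += step
                np.clip(pos, lo, hi, out=pos)
            # keep diffusing helices out of contact range before the
            # scheduled encounter
            d = np.linalg.norm(pos_a - pos_b)
            if d < min_free_sep:
                mid = (pos_a + pos_b) / 2.0
                u = (pos_a - pos_b) / d if d > 1e-9 else np.array([1.0, 0.0])
                pos_a[:] = np.clip(mid + u * min_free_sep / 2.0, lo, hi)
                pos_b[:] = np.clip(mid - u * min_free_sep / 2.0, lo, hi)
            coords[f, :n_per] = base + np.array([pos_a[0], pos_a[1], 0.0])
            coords[f, n_per:] = base @ rz.T + np.array([pos_b[0], pos_b[1], 0.0])
            orientation.append("monomer")
        else:
            if dock_center is None:
                mid = (pos_a + pos_b) / 2.0
                dock_center = np.array([mid[0], mid[1], 0.0])
            rho = _axial_rotation_at(config, f)
            base_b = base_dock @ Rotation.from_euler("z", rho, degrees=True).as_matrix().T
            base_b = base_b + np.array([0.0, 0.0, config.axial_offset])
            half = np.array([config.docked_separation / 2.0, 0.0, 0.0])
            a_xyz = base_dock @ tilt_a.T - half
            b_xyz = (base_b @ tilt_a.T - half) @ rz.T
            coords[f, :n_per] = a_xyz + dock_center
            coords[f, n_per:] = b_xyz + dock_center
            true_angle[f] = theta
            orientation.append("symmetric" if rho % 360.0 == 0.0 else "asymmetric")
    if config.noise_sigma > 0:
        coords += rng.normal(0.0, config.noise_sigma, coords.shape)
    traj = CGTrajectory(
        beads=beads, coords=coords, dt_ns=config.dt_ns, box=config.box
    )
    truth = {
        "encounter_frame": enc,
        "crossing_angle_deg": theta if enc is not None else None,
        "true_angle": true_angle,
        "orientation": orientation,
        "seed": config.seed,
    }
    return traj, truth


def write_truth(truth: dict, path: str | Path) -> None:
    """Write a ground-truth sidecar as JSON (arrays become lists)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, default=default, indent=1))
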