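"""Structural statistics over NMR-style conformer ensembles.

Implements the validation-style numbers reported for short peptide
ensembles: RMSD to the mean coordinates, dihedral-window secondary
structure, Ramachandran region percentages, salt-bridge and
hydrophobic-cluster detection, peptide-bond omega classification,
NOE restraint classification by sequence separation, restraint
violation checks, and combined 1H/15N chemical-shift perturbations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import Superposition, dihedral, kabsch_superpose, rmsd
from .ramachandran import ramachandran_classify
from .sequences import PeptideSeq
from .structures import (
    BACKBONE_ATOMS,
    DistanceRestraint,
    RestraintList,
    StructureEnsemble,
    StructureError,
    TorsionRestraint,
)

# Charged-group heavy atoms considered for salt bridges.
BASIC_GROUP_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
ACIDIC_GROUP_ATOMS = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "SEP": ("O1P", "O2P", "O3P"),
}

#: Residue types eligible for hydrophobic clusters.  Serine is included
#: by default because short-peptide work counts Ser side chains in
#: hydrophobic packing; the set is configurable.
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWYPS")


def backbone_dihedrals(
    ensemble: StructureEnsemble, model_index: int = 0
) -> dict[int, tuple[float, float]]:
    """Per-residue (phi, psi) for one model; NaN where undefined."""
    coords = ensemble.model(model_index)
    resnums = [r for r in ensemble.resnums if ensemble.resname(r) not in ("ACE", "NME")]
    bb: dict[int, dict[str, np.ndarray]] = {}
    for i, a in enumerate(ensemble.atoms):
        if a.name in ("N", "CA", "C") and a.resnum in set(resnums):
            bb.setdefault(a.resnum, {})[a.name] = coords[i]
    out: dict[int, tuple[float, float]] = {}
    for r in resnums:
        if set(bb.get(r, ())) != {"N", "CA", "C"}:
            raise StructureError(f"residue {r} missing backbone atoms")
    for k, r in enumerate(resnums):
        prev_r = resnums[k - 1] if k > 0 else None
        next_r = resnums[k + 1] if k < len(resnums) - 1 else None
        phi = psi = float("nan")
        if prev_r is not None and prev_r == r - 1:
            phi = dihedral(bb[prev_r]["C"], bb[r]["N"], bb[r]["CA"], bb[r]["C"])
        if next_r is not None and next_r == r + 1:
            psi = dihedral(bb[r]["N"], bb[r]["CA"], bb[r]["C"], bb[next_r]["N"])
        out[r] = (phi, psi)
    return out


# ---- superposition / precision ----


def superpose_model(
    ensemble: StructureEnsemble,
    mobile_index: int,
    reference_index: int,
    selection: np.ndarray,
) -> Superposition:
    """Kabsch fit of one model onto another over an atom selection."""
    return kabsch_superpose(
        ensemble.coords[mobile_index][selection],
        ensemble.coords[reference_index][selection],
    )


@dataclass(frozen=True)
class RmsdToMean:
    mean: float
    sd: float
    per_model: tuple[float, ...]


def rmsd_to_mean(
    ensemble: StructureEnsemble,
    selection: Optional[np.ndarray] = None,
    residue_range: Optional[tuple[int, int]] = None,
    backbone_only: bool = False,
) -> RmsdToMean:
    """Mean +/- sd of per-model RMSDs to the mean coordinates.

    Models are first superposed on model 1 over the selection, the
    coordinate-wise mean structure is computed, each model is then
    re-superposed onto that mean, and its RMSD to the mean reported.
    """
    if ensemble.n_models < 2:
        raise ValueError("need at least two models")
    if selection is None:
        names = BACKBONE_ATOMS if backbone_only else None
        resnums = (
            range(residue_range[0], residue_range[1] + 1) if residue_range else None
        )
        selection = ensemble.select(names=names, resnums=resnums)
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    sel_coords = ensemble.coords[:, selection, :]
    aligned = np.empty_like(sel_coords)
    aligned[0] = sel_coords[0]
    for m in range(1, ensemble.n_models):
        sup = kabsch_superpose(sel_coords[m], sel_coords[0])
        aligned[m] = sup.apply(sel_coords[m])
    mean_structure = aligned.mean(axis=0)
    per_model = []
    for m in range(ensemble.n_models):
        sup = kabsch_superpose(aligned[m], mean_structure)
        per_model.append(rmsd(sup.apply(aligned[m]), mean_structure))
    arr = np.asarray(per_model)
    return RmsdToMean(float(arr.mean()), float(arr.std(ddof=0)), tuple(arr))


# ---- secondary structure ----

ALPHA_WINDOW = ((-57.0, 40.0), (-47.0, 40.0))  # (center, halfwidth) for phi, psi
THREE_TEN_WINDOW = ((-49.0, 30.0), (-26.0, 30.0))
MIN_RUN_ALPHA = 4
MIN_RUN_310 = 3


def _in_window(phi: float, psi: float, window) -> bool:
    (pc, pw), (sc, sw) = window
    return (
        np.isfinite(phi)
        and np.isfinite(psi)
        and abs(phi - pc) <= pw
        and abs(psi - sc) <= sw
    )


def assign_secondary_structure(
    ensemble: StructureEnsemble,
    model_index: int = 0,
    seq: Optional[PeptideSeq] = None,
) -> dict[int, str]:
    """Dihedral-window secondary structure: H (alpha), G (3-10), C (coil).

    An alpha run needs >= 4 consecutive residues inside the alpha
    (phi, psi) window; a 3-10 run needs >= 3 inside the tighter 3-10
    window among residues not already alpha.  Terminal residues without
    a full (phi, psi) pair are coil.
    """
    dihedrals = backbone_dihedrals(ensemble, model_index)
    resnums = list(dihedrals)
    labels = {r: "C" for r in resnums}

    def mark_runs(window, min_run, label, eligible):
        run: list[int] = []
        for r in resnums + [None]:
            ok = (
                r is not None
                and eligible(r)
                and _in_window(*dihedrals[r], window)
                and (not run or r == run[-1] + 1)
            )
            if ok:
                run.append(r)
            else:
                if len(run) >= min_run:
                    for rr in run:
                        labels[rr] = label
                run = [r] if (r is not None and eligible(r) and _in_window(*dihedrals[r], window)) else []

    mark_runs(ALPHA_WINDOW, MIN_RUN_ALPHA, "H", lambda r: True)
    mark_runs(THREE_TEN_WINDOW, MIN_RUN_310, "G", lambda r: labels[r] == "C")
    return labels


def secondary_structure_spans(labels: dict[int, str]) -> list[tuple[str, int, int]]:
    """Compress per-residue labels into (label, first, last) spans."""
    spans = []
    for r in sorted(labels):
        lab = labels[r]
        if spans and spans[-1][0] == lab and spans[-1][2] == r - 1:
            spans[-1] = (lab, spans[-1][1], r)
        else:
            spans.append((lab, r, r))
    return spans


# ---- Ramachandran summary ----


def ramachandran_summary(
    ensemble: StructureEnsemble, models: Optional[Iterable[int]] = None
) -> dict[str, float]:
    """Percentage of residues per Ramachandran region over the ensemble.

    Only residues with both phi and psi defined contribute.  The four
    percentages always sum to 100.
    """
    counts = {"most_favored": 0, "additional": 0, "generous": 0, "disallowed": 0}
    total = 0
    for m in models if models is not None else range(ensemble.n_models):
        for r, (phi, psi) in backbone_dihedrals(ensemble, m).items():
            if not (np.isfinite(phi) and np.isfinite(psi)):
                continue
            counts[ramachandran_classify(phi, psi, ensemble.resname(r))] += 1
            total += 1
    if total == 0:
        raise ValueError("no residues with defined phi/psi")
    return {k: 100.0 * v / total for k, v in counts.items()}


# ---- salt bridges / hydrophobic clusters / omega ----


@dataclass(frozen=True)
class SaltBridge:
    acidic_res: int
    basic_res: int
    per_model: tuple[bool, ...]
    frequency: float


@dataclass(frozen=True)
class SaltBridgeReport:
    bridges: tuple[SaltBridge, ...]
    cutoff: float

    def most_frequent(self) -> tuple[SaltBridge, ...]:
        """Top-frequency bridge(s), ties included."""
        if not self.bridges:
            return ()
        top = self.bridges[0].frequency
        return tuple(b for b in self.bridges if b.frequency == top)


def _charged_groups(ensemble: StructureEnsemble, table) -> dict[int, np.ndarray]:
    groups: dict[int, np.ndarray] = {}
    for r in ensemble.resnums:
        resname = ensemble.resname(r)
        if resname not in table:
            continue
        idx = [
            i
            for i, a in enumerate(ensemble.atoms)
            if a.resnum == r and a.name in table[resname]
        ]
        if not idx:
            warnings.warn(
                f"residue {resname}{r}: charged-group atoms missing, skipped",
                stacklevel=3,
            )
            continue
        groups[r] = np.asarray(idx, int)
    return groups


def detect_salt_bridges(
    ensemble: StructureEnsemble, cutoff: float = 4.0
) -> SaltBridgeReport:
    """Acidic-O to basic-N contacts within ``cutoff`` per model.

    A bridge exists in a model iff the minimum distance between any
    basic-group nitrogen and any acidic-group oxygen (phosphate oxygens
    for phosphoserine) is <= cutoff.  Pairs are reported with their
    ensemble frequency, sorted descending.
    """
    acidic = _charged_groups(ensemble, ACIDIC_GROUP_ATOMS)
    basic = _charged_groups(ensemble, BASIC_GROUP_ATOMS)
    bridges = []
    for ar, a_idx in acidic.items():
        for br, b_idx in basic.items():
            d = np.linalg.norm(
                ensemble.coords[:, a_idx, None, :] - ensemble.coords[:, None, b_idx, :],
                axis=-1,
            )
            present = d.reshape(ensemble.n_models, -1).min(axis=1) <= cutoff
            if present.any():
                bridges.append(
                    SaltBridge(
                        acidic_res=ar,
                        basic_res=br,
                        per_model=tuple(bool(p) for p in present),
                        frequency=float(present.mean()),
                    )
                )
    bridges.sort(key=lambda b: (-b.frequency, b.acidic_res, b.basic_res))
    return SaltBridgeReport(bridges=tuple(bridges), cutoff=cutoff)


def detect_hydrophobic_clusters(
    ensemble: StructureEnsemble,
    model_index: int = 0,
    contact_cutoff: float = 5.0,
    min_size: int = 3,
    residue_types: frozenset[str] = HYDROPHOBIC_RESIDUES,
) -> list[set[int]]:
    """Connected components of side-chain contacts among apolar residues.

    Residues (restricted to ``residue_types``, one-letter codes) are
    nodes; an edge joins two residues whose side-chain heavy atoms come
    within ``contact_cutoff``.  Components of ``min_size`` or more are
    returned.
    """
    from .structures import THREE_TO_ONE

    coords = ensemble.model(model_index)
    side: dict[int, np.ndarray] = {}
    for r in ensemble.resnums:
        resname = ensemble.resname(r)
        one = THREE_TO_ONE.get(resname)
        if one is None or one not in residue_types:
            continue
        idx = [
            i
            for i, a in enumerate(ensemble.atoms)
            if a.resnum == r and a.name not in BACKBONE_ATOMS and a.element != "H"
        ]
        if idx:
            side[r] = coords[np.asarray(idx, int)]
    g = nx.Graph()
    g.add_nodes_from(side)
    residues = list(side)
    for i, ri in enumerate(residues):
        for rj in residues[i + 1 :]:
            dmin = np.min(
                np.linalg.norm(side[ri][:, None, :] - side[rj][None, :, :], axis=-1)
            )
            if dmin <= contact_cutoff:
                g.add_edge(ri, rj)
    return [set(c) for c in nx.connected_components(g) if len(c) >= min_size]


def omega_classify(
    ensemble: StructureEnsemble, resnum: int, model_index: int = 0
) -> str:
    """Peptide-bond omega class for the bond resnum -> resnum+1.

    trans for |omega| >= 150 deg, cis for |omega| <= 30 deg, otherwise
    twisted.
    """
    coords = ensemble.model(model_index)
    try:
        p = [
            coords[ensemble.atom_index(resnum, "CA")],
            coords[ensemble.atom_index(resnum, "C")],
            coords[ensemble.atom_index(resnum + 1, "N")],
            coords[ensemble.atom_index(resnum + 1, "CA")],
        ]
    except KeyError as exc:
        raise StructureError(f"missing atom for omega at residue {resnum}") from exc
    omega = dihedral(*p)
    if abs(omega) >= 150.0:
        return "trans"
    if abs(omega) <= 30.0:
        return "cis"
    return "twisted"


# ---- restraints ----


def classify_noe_restraints(
    restraints: RestraintList | Sequence[DistanceRestraint],
) -> dict[str, int]:
    """Count distance restraints by sequence separation |i-j|.

    intra: 0; sequential: 1; medium: 2-4; long: >= 5 (the standard NMR
    convention).  The four classes partition the list, so the counts
    always sum to ``total``.
    """
    dist = restraints.distance if isinstance(restraints, RestraintList) else restraints
    counts = {"intra": 0, "sequential": 0, "medium": 0, "long": 0}
    for r in dist:
        s = r.sequence_separation
        if s == 0:
            counts["intra"] += 1
        elif s == 1:
            counts["sequential"] += 1
        elif s < 5:
            counts["medium"] += 1
        else:
            counts["long"] += 1
    counts["total"] = sum(counts.values())
    return counts


def _circular_in_range(angle: float, lower: float, upper: float, tol: float) -> bool:
    """Is ``angle`` within [lower - tol, upper + tol] on the circle?"""
    span = upper - lower
    if span < 0:  # window wraps through +/-180
        span %= 360.0
    if span + 2.0 * tol >= 360.0:
        return True
    # rotate so the lower edge maps to 0, compare on [0, 360)
    rel = (angle - (lower - tol)) % 360.0
    return rel <= span + 2.0 * tol


@dataclass(frozen=True)
class ModelViolations:
    model_index: int
    distance_violations: int
    torsion_violations: int
    worst_distance: Optional[tuple[DistanceRestraint, float]]
    worst_torsion: Optional[tuple[TorsionRestraint, float]]


@dataclass(frozen=True)
class ViolationReport:
    per_model: tuple[ModelViolations, ...]
    skipped_restraints: int
    dist_tol: float
    torsion_tol: float

    @property
    def total_violations(self) -> int:
        return sum(
            m.distance_violations + m.torsion_violations for m in self.per_model
        )


def check_violations(
    ensemble: StructureEnsemble,
    restraints: RestraintList,
    dist_tol: float = 0.2,
    torsion_tol: float = 5.0,
) -> ViolationReport:
    """Check distance and torsion restraints against every model.

    A distance restraint is violated when the model distance exceeds
    its upper bound plus ``dist_tol`` (boundary inclusive: exactly at
    bound + tol is not a violation).  A torsion restraint is violated
    when the dihedral falls outside [lower - tol, upper + tol],
    compared circularly.  Restraints whose atoms cannot be resolved are
    skipped with a warning and counted.
    """
    skipped = 0
    resolved_dist = []
    for r in restraints.distance:
        try:
            i = ensemble.atom_index(r.res_i, r.atom_i)
            j = ensemble.atom_index(r.res_j, r.atom_j)
        except KeyError:
            warnings.warn(f"unresolvable restraint atoms: {r}", stacklevel=2)
            skipped += 1
            continue
        resolved_dist.append((r, i, j))
    per_model = []
    for m in range(ensemble.n_models):
        coords = ensemble.model(m)
        n_dist = 0
        worst_d: Optional[tuple[DistanceRestraint, float]] = None
        for r, i, j in resolved_dist:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            excess = d - (r.upper + dist_tol)
            if excess > 0:
                n_dist += 1
                if worst_d is None or excess > worst_d[1]:
                    worst_d = (r, excess)
        dihedrals = backbone_dihedrals(ensemble, m) if restraints.torsion else {}
        n_tors = 0
        worst_t: Optional[tuple[TorsionRestraint, float]] = None
        for t in restraints.torsion:
            if t.resnum not in dihedrals:
                warnings.warn(f"unresolvable torsion restraint: {t}", stacklevel=2)
                skipped += 1
                continue
            phi, psi = dihedrals[t.resnum]
            ang = phi if t.angle == "PHI" else psi
            if not np.isfinite(ang):
                skipped += 1
                continue
            if not _circular_in_range(ang, t.lower, t.upper, torsion_tol):
                n_tors += 1
                mid = (t.lower + t.upper) / 2.0
                dev = abs((ang - mid + 180.0) % 360.0 - 180.0)
                if worst_t is None or dev > worst_t[1]:
                    worst_t = (t, dev)
        per_model.append(
            ModelViolations(m, n_dist, n_tors, worst_d, worst_t)
        )
    return ViolationReport(
        per_model=tuple(per_model),
        skipped_restraints=skipped,
        dist_tol=dist_tol,
        torsion_tol=torsion_tol,
    )


# ---- chemical shift perturbation ----


def chemical_shift_perturbation(
    reference: pd.DataFrame,
    perturbed: pd.DataFrame,
    nitrogen_scale: float = 0.14,
) -> pd.DataFrame:
    """Combined amide CSP per residue.

    delta = sqrt(dH^2 + (scale * dN)^2) with the conventional 15N
    scaling of 0.14.  Residues present in only one table are returned
    with NaN and flagged in the ``missing`` column.
    """
    for name, df in (("reference", reference), ("perturbed", perturbed)):
        if df["residue"].duplicated().any():
            raise ValueError(f"duplicate residue in {name} table")
    merged = reference.merge(
        perturbed, on="residue", how="outer", suffixes=("_ref", "_pert"), sort=True
    )
    d_h = merged["dH_ppm_pert"] - merged["dH_ppm_ref"]
    d_n = merged["dN_ppm_pert"] - merged["dN_ppm_ref"]
    csp = np.sqrt(d_h**2 + (nitrogen_scale * d_n) ** 2)
    return pd.DataFrame(
        {
            "residue": merged["residue"],
            "delta_ppm": csp,
            "missing": csp.isna(),
        }
    )
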