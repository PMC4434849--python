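"""Containers and text I/O for NMR-style structure ensembles, distance /
torsion restraint lists, and amide peak tables.

Coordinates are stored as a shared atom roster plus a
``(n_models, n_atoms, 3)`` array, which keeps the ensemble statistics in
:mod:`helixswitch.ensemble` vectorised.  PDB reading and writing go
through Bio.PDB; restraint lists use the whitespace-column upper-limit
(``.upl``) and angle-constraint (``.aco``) dialects common in NMR
structure calculation, with 1-based author numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser, StructureBuilder

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "SEP": "S",  # phosphoserine
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "SEP"}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


class StructureError(ValueError):
    """Malformed or unsupported structure input."""


class Atom(NamedTuple):
    resnum: int  # author residue number
    resname: str  # three-letter code (SEP for phosphoserine)
    name: str
    element: str


@dataclass(frozen=True)
class StructureEnsemble:
    """Ordered models sharing one atom roster."""

    atoms: tuple[Atom, ...]
    coords: np.ndarray  # (n_models, n_atoms, 3), Angstrom

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise StructureError("coords must be (n_models, n_atoms, 3)")
        if coords.shape[1] != len(self.atoms):
            raise StructureError("coords second axis must match atom roster")
        if coords.shape[0] < 1:
            raise StructureError("ensemble needs at least one model")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(self, "coords", coords)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def resnums(self) -> list[int]:
        """Ordered unique author residue numbers."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.resnum, None)
        return list(seen)

    def resname(self, resnum: int) -> str:
        for a in self.atoms:
            if a.resnum == resnum:
                return a.resname
        raise KeyError(resnum)

    def select(
        self,
        names: Optional[Iterable[str]] = None,
        resnums: Optional[Iterable[int]] = None,
        resnames: Optional[Iterable[str]] = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given filters."""
        names = set(names) if names is not None else None
        resnums = set(resnums) if resnums is not None else None
        resnames = set(resnames) if resnames is not None else None
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if (names is None or a.name in names)
            and (resnums is None or a.resnum in resnums)
            and (resnames is None or a.resname in resnames)
        ]
        return np.asarray(idx, dtype=int)

    def atom_index(self, resnum: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.resnum == resnum and a.name == name:
                return i
        raise KeyError((resnum, name))

    def model(self, i: int) -> np.ndarray:
        return self.coords[i]

    def with_coords(self, coords: np.ndarray) -> "StructureEnsemble":
        return replace(self, coords=coords)

    # ---- PDB I/O ----

    @classmethod
    def from_pdb(cls, path: str | Path) -> "StructureEnsemble":
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("ens", str(path))
        rosters: list[tuple[Atom, ...]] = []
        all_coords: list[np.ndarray] = []
        for model in structure:
            atoms: list[Atom] = []
            xyz: list[np.ndarray] = []
            for chain in model:
                for residue in chain:
                    het, resseq, icode = residue.get_id()
                    if icode != " ":
                        raise StructureError("insertion codes are not supported")
                    resname = residue.get_resname().strip()
                    if resname in ("HOH", "WAT"):
                        continue
                    for atom in residue:
                        if atom.is_disordered():
                            atom = atom.disordered_get_list()[0]
                        atoms.append(
                            Atom(
                                resnum=resseq,
                                resname=resname,
                                name=atom.get_name(),
                                element=(atom.element or atom.get_name()[0]).strip(),
                            )
                        )
                        xyz.append(atom.get_coord().astype(float))
            rosters.append(tuple(atoms))
            all_coords.append(np.asarray(xyz, dtype=float))
        if not rosters:
            raise StructureError("no models in PDB file")
        if any(r != rosters[0] for r in rosters[1:]):
            raise StructureError("models do not share an identical atom roster")
        return cls(atoms=rosters[0], coords=np.stack(all_coords))

    def to_pdb(self, path: str | Path) -> None:
        builder = StructureBuilder.StructureBuilder()
        builder.init_structure("ens")
        for m in range(self.n_models):
            builder.init_model(m, m)
            builder.init_chain("A")
            builder.init_seg("    ")
            current_res = None
            serial = 1
            for a, xyz in zip(self.atoms, self.coords[m]):
                if current_res != a.resnum:
                    hetflag = "H_" + a.resname if a.resname in ("SEP", "ACE", "NME") else " "
                    builder.init_residue(a.resname, hetflag, a.resnum, " ")
                    current_res = a.resnum
                name = a.name
                fullname = name.center(4) if len(name) < 4 else name
                builder.init_atom(
                    name, np.asarray(xyz, float), 0.0, 1.0, " ", fullname,
                    serial, element=a.element,
                )
                serial += 1
        io = PDBIO()
        io.set_structure(builder.get_structure())
        io.save(str(path))


# ---- restraints ----


@dataclass(frozen=True)
class DistanceRestraint:
    res_i: int
    atom_i: str
    res_j: int
    atom_j: str
    upper: float  # Angstrom
    resname_i: str = "UNK"
    resname_j: str = "UNK"

    def __post_init__(self) -> None:
        if self.upper <= 0:
            raise ValueError("upper bound must be positive")

    @property
    def sequence_separation(self) -> int:
        return abs(self.res_i - self.res_j)


@dataclass(frozen=True)
class TorsionRestraint:
    resnum: int
    angle: str  # "PHI" or "PSI"
    lower: float  # degrees
    upper: float
    resname: str = "UNK"

    def __post_init__(self) -> None:
        if self.angle not in ("PHI", "PSI"):
            raise ValueError("angle must be PHI or PSI")


@dataclass(frozen=True)
class RestraintList:
    distance: tuple[DistanceRestraint, ...] = field(default_factory=tuple)
    torsion: tuple[TorsionRestraint, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "distance", tuple(self.distance))
        object.__setattr__(self, "torsion", tuple(self.torsion))

    @classmethod
    def from_files(
        cls, upl: Optional[str | Path] = None, aco: Optional[str | Path] = None
    ) -> "RestraintList":
        dist = read_upl(upl) if upl else ()
        tors = read_aco(aco) if aco else ()
        return cls(distance=tuple(dist), torsion=tuple(tors))


def read_upl(path: str | Path) -> list[DistanceRestraint]:
    """Read whitespace-column upper distance limits:
    ``res_i resname_i atom_i res_j resname_j atom_j upper``."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        f = line.split()
        if len(f) < 7:
            raise ValueError(f"malformed upl line: {line!r}")
        out.append(
            DistanceRestraint(
                res_i=int(f[0]), resname_i=f[1], atom_i=f[2],
                res_j=int(f[3]), resname_j=f[4], atom_j=f[5],
                upper=float(f[6]),
            )
        )
    return out


def write_upl(restraints: Sequence[DistanceRestraint], path: str | Path) -> None:
    lines = [
        f"{r.res_i:4d} {r.resname_i:<4s} {r.atom_i:<5s}"
        f"{r.res_j:4d} {r.resname_j:<4s} {r.atom_j:<5s}{r.upper:8.2f}"
        for r in restraints
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_aco(path: str | Path) -> list[TorsionRestraint]:
    """Read whitespace-column torsion ranges:
    ``resnum resname angle lower upper``."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        f = line.split()
        if len(f) < 5:
            raise ValueError(f"malformed aco line: {line!r}")
        out.append(
            TorsionRestraint(
                resnum=int(f[0]), resname=f[1], angle=f[2].upper(),
                lower=float(f[3]), upper=float(f[4]),
            )
        )
    return out


def write_aco(restraints: Sequence[TorsionRestraint], path: str | Path) -> None:
    lines = [
        f"{r.resnum:4d} {r.resname:<4s} {r.angle:<4s}{r.lower:9.1f}{r.upper:9.1f}"
        for r in restraints
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---- peak tables ----


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Amide peak table CSV with columns ``residue,dH_ppm,dN_ppm``."""
    df = pd.read_csv(path)
    required = {"residue", "dH_ppm", "dN_ppm"}
    if not required <= set(df.columns):
        raise ValueError("peak table needs columns residue,dH_ppm,dN_ppm")
    if df["residue"].duplicated().any():
        dupes = sorted(df.loc[df["residue"].duplicated(), "residue"].unique())
        raise ValueError(f"duplicate residue number(s) in peak table: {dupes}")
    return df


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
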