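"""Peptide sequence arithmetic in author numbering.

The peptides studied here are short synthetic fragments of the Trop2
receptor: the 26-residue cytosolic tail (residues 298-323, optionally
phosphorylated on Ser303) and the 23-residue transmembrane helix
(residues 275-297).  Everything in this module works on the one-letter
sequence with an author-numbering offset, so results can be reported in
the residue numbers used in the structural literature.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Side chains counted as basic at pH 7.4.  Histidine is deliberately
#: excluded: it is mostly neutral at this pH (see docs/methods.md).
BASIC_RESIDUES = frozenset("RK")
ACIDIC_RESIDUES = frozenset("DE")

PHOSPHORYLATABLE = frozenset("STY")


class InvalidSequenceError(ValueError):
    """Sequence contains a letter outside the 20 canonical amino acids."""


class NumberingRangeError(ValueError):
    """An author-numbered label falls outside the peptide's range."""


@dataclass(frozen=True)
class PeptideSeq:
    """A peptide with author numbering, phospho flags and cap flags.

    Parameters
    ----------
    residues:
        One-letter amino-acid string.
    start_number:
        Author number of the first residue (e.g. 298 for the Trop2 tail).
    phospho_positions:
        Author-numbered positions carrying a phosphate; each must be
        S, T or Y.
    n_acetyl, c_amide:
        Terminal blocking groups (acetyl / amide), which remove the
        terminal charges.
    """

    residues: str
    start_number: int = 1
    phospho_positions: frozenset[int] = field(default_factory=frozenset)
    n_acetyl: bool = False
    c_amide: bool = False

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise InvalidSequenceError("empty sequence")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise InvalidSequenceError(f"unknown residue letter(s): {sorted(bad)}")
        object.__setattr__(self, "phospho_positions", frozenset(self.phospho_positions))
        for pos in self.phospho_positions:
            if not (self.start_number <= pos <= self.end_number):
                raise NumberingRangeError(f"phospho position {pos} outside sequence")
            if self[pos] not in PHOSPHORYLATABLE:
                raise InvalidSequenceError(
                    f"phospho position {pos} is {self[pos]}, not S/T/Y"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.residues) - 1

    def __getitem__(self, label: int) -> str:
        """Residue letter at an author-numbered position."""
        if not (self.start_number <= label <= self.end_number):
            raise NumberingRangeError(
                f"label {label} outside [{self.start_number}, {self.end_number}]"
            )
        return self.residues[label - self.start_number]

    def labels(self) -> Iterator[int]:
        return iter(range(self.start_number, self.end_number + 1))

    def is_phosphorylated(self, label: int) -> bool:
        return label in self.phospho_positions


_PHOSPHO_TOKEN = re.compile(r"\(?p([STY])\)?")


def parse_sequence(
    text: str,
    start_number: int = 1,
    n_acetyl: bool = False,
    c_amide: bool = False,
) -> PeptideSeq:
    """Parse a sequence string with optional ``pS``-style phospho markers.

    Both ``TNRRKpSGK...`` and ``TNRRK(pS)GK...`` spellings are accepted;
    the marked residue is recorded as a phospho flag on the plain letter.
    """
    residues: list[str] = []
    phospho: set[int] = set()
    i = 0
    while i < len(text):
        m = _PHOSPHO_TOKEN.match(text, i)
        if m:
            phospho.add(start_number + len(residues))
            residues.append(m.group(1))
            i = m.end()
        else:
            residues.append(text[i])
            i += 1
    return PeptideSeq(
        "".join(residues),
        start_number=start_number,
        phospho_positions=frozenset(phospho),
        n_acetyl=n_acetyl,
        c_amide=c_amide,
    )


# The two experimentally studied fragments, in author numbering.
TROP2IC = parse_sequence("TNRRKSGKYKKVEIKELGELRKEPSL", start_number=298, n_acetyl=True)
TROP2ICP = parse_sequence(
    "TNRRK(pS)GKYKKVEIKELGELRKEPSL", start_number=298, n_acetyl=True
)
TROP2TM = parse_sequence("AGLIAVIVVVVVALVAGMAVLVI", start_number=275)


def charge_census(seq: PeptideSeq) -> dict[str, int]:
    """Count basic (R, K), acidic (D, E) and other residues.

    Counts are independent of phospho flags: the census is about the
    side-chain chemistry of the unmodified sequence.
    """
    basic = sum(1 for r in seq.residues if r in BASIC_RESIDUES)
    acidic = sum(1 for r in seq.residues if r in ACIDIC_RESIDUES)
    return {"basic": basic, "acidic": acidic, "other": len(seq) - basic - acidic}


def span_fraction(seq: PeptideSeq, first_label: int, last_label: int) -> int:
    """Percent of the peptide covered by an author-numbered span.

    Rounded half-up to the nearest integer percent, the convention used
    when a 9-residue helix in a 26-mer is reported as 35%.
    """
    if first_label > last_label:
        raise NumberingRangeError("first_label > last_label")
    for lab in (first_label, last_label):
        if not (seq.start_number <= lab <= seq.end_number):
            raise NumberingRangeError(f"label {lab} outside sequence numbering")
    frac = 100.0 * (last_label - first_label + 1) / len(seq)
    return int(math.floor(frac + 0.5))


@dataclass(frozen=True)
class HomopolymerRun:
    first_label: Optional[int]
    last_label: Optional[int]
    run_length: int


def longest_homopolymer(seq: PeptideSeq, residue: str) -> HomopolymerRun:
    """Longest maximal run of one residue type (ties: smallest start).

    Finds e.g. the five consecutive valines (Val282-Val286) that form
    the dimer interface of the transmembrane helix.
    """
    if residue not in AMINO_ACIDS:
        raise InvalidSequenceError(f"unknown residue letter: {residue!r}")
    best_start, best_len = None, 0
    run_start = None
    for idx, r in enumerate(seq.residues + "\x00"):  # sentinel flushes last run
        if r == residue:
            if run_start is None:
                run_start = idx
        else:
            if run_start is not None:
                if idx - run_start > best_len:
                    best_start, best_len = run_start, idx - run_start
                run_start = None
    if best_len == 0:
        return HomopolymerRun(None, None, 0)
    first = seq.start_number + best_start
    return HomopolymerRun(first, first + best_len - 1, best_len)


def net_charge(seq: PeptideSeq, phospho_charge: int = -2) -> int:
    """Formal side-chain net charge; termini ignored when capped.

    ``phospho_charge`` is the charge assigned to each phosphate group
    (-2 at physiological pH, -1 for the monoanionic form).
    """
    if phospho_charge not in (-1, -2):
        raise ValueError("phospho_charge must be -1 or -2")
    census = charge_census(seq)
    return census["basic"] - census["acidic"] + phospho_charge * len(
        seq.phospho_positions
    )
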