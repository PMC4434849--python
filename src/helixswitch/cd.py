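"""Circular-dichroism spectrum processing.

Raw far-UV CD scans (millidegrees vs wavelength) are blank-subtracted,
averaged, and converted to mean residue ellipticity

    [theta](lambda) = theta_mdeg(lambda) / (10 * c_M * N * l_cm)

with c_M the molar peptide concentration, N the number of residues and
l_cm the cuvette path length, giving deg cm^2 dmol^-1.  Fractional
helicity is the classical two-state estimate at 222 nm,

    f_H = ([theta]_222 - [theta]_coil) / ([theta]_helix - [theta]_coil)

against random-coil and full-helix reference values (defaults
640 and -42500 deg cm^2 dmol^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

RAW_MDEG = "raw_mdeg"
MRE = "mre"


class GridMismatchError(ValueError):
    """Two spectra do not share the same wavelength grid."""


class MetadataError(ValueError):
    """Sample metadata missing or inconsistent for the requested operation."""


class DegenerateReferenceError(ValueError):
    """Helix and coil reference ellipticities coincide."""


@dataclass(frozen=True)
class CDSample:
    """Sample metadata needed for the mean-residue-ellipticity conversion."""

    conc_mM: float
    n_residues: int
    path_cm: float
    tfe_percent: float = 0.0

    def __post_init__(self) -> None:
        if self.conc_mM <= 0:
            raise MetadataError("conc_mM must be positive")
        if self.path_cm <= 0:
            raise MetadataError("path_cm must be positive")
        if self.n_residues < 1:
            raise MetadataError("n_residues must be >= 1")
        if not (0.0 <= self.tfe_percent <= 100.0):
            raise MetadataError("tfe_percent must be in [0, 100]")


@dataclass(frozen=True)
class CDSpectrum:
    wavelengths: np.ndarray  # nm, strictly monotone
    signal: np.ndarray  # mdeg (raw) or deg cm^2 dmol^-1 (mre)
    units: str = RAW_MDEG
    sample: Optional[CDSample] = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if wl.shape != sig.shape or wl.ndim != 1:
            raise ValueError("wavelengths and signal must be 1-D and equal length")
        d = np.diff(wl)
        if len(wl) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength grid must be strictly monotone")
        if self.units not in (RAW_MDEG, MRE):
            raise ValueError(f"unknown units tag {self.units!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "signal", sig)

    def value_at(self, wavelength: float) -> float:
        """Signal at a wavelength (linear interpolation on the grid)."""
        order = np.argsort(self.wavelengths)
        return float(
            np.interp(wavelength, self.wavelengths[order], self.signal[order])
        )

    # ---- I/O: two-column CSV with header, optional YAML sidecar ----

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        df = pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "signal": self.signal}
        )
        df.to_csv(path, index=False)
        if sidecar and self.sample is not None:
            meta = {
                "units": self.units,
                "conc_mM": self.sample.conc_mM,
                "n_residues": self.sample.n_residues,
                "path_cm": self.sample.path_cm,
                "tfe_percent": self.sample.tfe_percent,
            }
            Path(str(path) + ".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        units: str = RAW_MDEG,
        sample: Optional[CDSample] = None,
    ) -> "CDSpectrum":
        df = pd.read_csv(path)
        if not {"wavelength_nm", "signal"} <= set(df.columns):
            raise ValueError("CSV must have columns wavelength_nm,signal")
        sidecar = Path(str(path) + ".yaml")
        if sample is None and sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text())
            units = meta.get("units", units)
            sample = CDSample(
                conc_mM=meta["conc_mM"],
                n_residues=meta["n_residues"],
                path_cm=meta["path_cm"],
                tfe_percent=meta.get("tfe_percent", 0.0),
            )
        return cls(
            df["wavelength_nm"].to_numpy(float),
            df["signal"].to_numpy(float),
            units=units,
            sample=sample,
        )


@dataclass(frozen=True)
class HelicityReference:
    """Two-state reference ellipticities at one wavelength (default 222 nm)."""

    theta_coil: float = 640.0
    theta_helix: float = -42500.0
    wavelength: float = 222.0

    def __post_init__(self) -> None:
        if not self.theta_helix < self.theta_coil:
            raise DegenerateReferenceError("theta_helix must be below theta_coil")


def _check_same_grid(a: CDSpectrum, b: CDSpectrum) -> None:
    if a.wavelengths.shape != b.wavelengths.shape or not np.allclose(
        a.wavelengths, b.wavelengths, rtol=0, atol=1e-9
    ):
        raise GridMismatchError("spectra are on different wavelength grids")


def subtract_blank(sample: CDSpectrum, blank: CDSpectrum) -> CDSpectrum:
    """Pointwise baseline subtraction of a matched buffer blank."""
    _check_same_grid(sample, blank)
    if sample.units != RAW_MDEG or blank.units != RAW_MDEG:
        raise ValueError("blank subtraction operates on raw mdeg spectra")
    if (
        sample.sample is not None
        and blank.sample is not None
        and sample.sample.tfe_percent != blank.sample.tfe_percent
    ):
        raise MetadataError("sample and blank recorded at different TFE percentages")
    return replace(sample, signal=sample.signal - blank.signal)


def average_scans(scans: Sequence[CDSpectrum]) -> CDSpectrum:
    """Arithmetic mean of repeated scans on identical grids."""
    if len(scans) == 0:
        raise ValueError("need at least one scan")
    first = scans[0]
    for s in scans[1:]:
        _check_same_grid(first, s)
        if s.units != first.units:
            raise ValueError("scans have mixed units")
    mean = np.mean([s.signal for s in scans], axis=0)
    return replace(first, signal=mean)


def to_mean_residue_ellipticity(raw: CDSpectrum) -> CDSpectrum:
    """Convert raw mdeg to mean residue ellipticity (deg cm^2 dmol^-1)."""
    if raw.units != RAW_MDEG:
        raise ValueError("spectrum is not in raw mdeg")
    if raw.sample is None:
        raise MetadataError("sample metadata (conc, residues, path) required")
    s = raw.sample
    denom = 10.0 * (s.conc_mM / 1000.0) * s.n_residues * s.path_cm
    return replace(raw, signal=raw.signal / denom, units=MRE)


def fractional_helicity(
    theta_obs_222: float, ref: HelicityReference = HelicityReference()
) -> float:
    """Two-state fractional helix content from [theta] at 222 nm.

    Values outside [0, 1] (baseline overshoot past a reference) are
    clamped and a warning is emitted.
    """
    f = (theta_obs_222 - ref.theta_coil) / (ref.theta_helix - ref.theta_coil)
    if f < 0.0 or f > 1.0:
        warnings.warn(
            f"fractional helicity {f:.4f} outside [0, 1]; clamped", stacklevel=2
        )
        f = min(1.0, max(0.0, f))
    return f


def helicity_from_spectrum(
    mre: CDSpectrum, ref: HelicityReference = HelicityReference()
) -> float:
    """Fractional helicity of an MRE spectrum at the reference wavelength."""
    if mre.units != MRE:
        raise ValueError("helicity is estimated on the MRE spectrum")
    return fractional_helicity(mre.value_at(ref.wavelength), ref)


def report_minima(mre: CDSpectrum, window_nm: float = 5.0) -> list[dict[str, float]]:
    """Local minima of an MRE spectrum, deepest first.

    A grid point is a minimum if it is strictly below every other point
    within ``window_nm/2`` on each side; points whose window is
    truncated by the grid edge are not eligible.  Wavelengths are
    reported at the nearest grid point.
    """
    if mre.units != MRE:
        raise ValueError("minima are reported on the MRE spectrum")
    wl, sig = mre.wavelengths, mre.signal
    if len(wl) > 1 and wl[0] > wl[-1]:
        wl, sig = wl[::-1], sig[::-1]
    step = float(np.min(np.diff(wl))) if len(wl) > 1 else np.inf
    if window_nm < step:
        raise ValueError("window_nm must be at least the grid step")
    half = max(1, int(round((window_nm / 2.0) / step)))
    if len(wl) < 2 * half + 1:
        raise ValueError("spectrum shorter than the minima window")
    out = []
    for i in range(half, len(wl) - half):
        win = sig[i - half : i + half + 1]
        if sig[i] < np.min(np.delete(win, half)):
            out.append({"wavelength": float(wl[i]), "depth": float(sig[i])})
    out.sort(key=lambda m: m["depth"])
    return out
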