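"""Gaussian-broadened spectrum synthesis: DOS and UV-Vis curves.

Density-of-states curves are sums of unit-area Gaussians centered at the
molecular-orbital energies; UV-Vis curves weight each Gaussian by the
oscillator strength of the excitation.  A unit-area Gaussian of full
width at half maximum w has peak height 2 sqrt(ln 2 / pi) / w.

Wavelength-axis views of UV-Vis curves are direct resamplings of the
energy-domain curve through lambda = hc/E (no dE/dlambda Jacobian), the
convention of the common orbital/spectrum post-processing tools.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .bundle import ExcitationSet, OrbitalSpectrum
from .constants import HC_EV_NM

#: default energy windows (min, max, step)
DOS_GRID_DEFAULT = (-15.0, 0.0, 0.01)
UVVIS_GRID_DEFAULT = (0.5, 6.5, 0.005)

#: default broadening widths, eV
FWHM_DOS_DEFAULT = 0.3
FWHM_UVVIS_DEFAULT = 0.333


class EmptySpectrumError(ValueError):
    """No lines with weight to broaden."""


@dataclass
class SpectrumCurve:
    """A broadened spectrum on a strictly monotone axis."""

    axis: np.ndarray
    intensity: np.ndarray
    fwhm: float
    kind: Literal["dos", "uvvis"]
    axis_unit: Literal["ev", "nm"] = "ev"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    def to_wavelength(self) -> "SpectrumCurve":
        """Re-express an energy-axis curve on a wavelength axis (nm)."""
        if self.axis_unit != "ev":
            return self
        lam = HC_EV_NM / self.axis[::-1]
        return SpectrumCurve(lam, self.intensity[::-1].copy(), self.fwhm,
                             self.kind, axis_unit="nm")


def _grid(spec: Sequence[float] | None, default: Sequence[float]) -> np.ndarray:
    lo, hi, step = spec if spec is not None else default
    if step <= 0 or hi <= lo:
        raise ValueError("grid must be (lo, hi, step) with step > 0, hi > lo")
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def _gauss_sum(axis: np.ndarray, centers: np.ndarray, weights: np.ndarray,
               fwhm: float) -> np.ndarray:
    # unit-area Gaussian: peak 2 sqrt(ln2/pi)/w, exponent 4 ln2 (x-c)^2/w^2
    peak = 2.0 * math.sqrt(math.log(2.0) / math.pi) / fwhm
    arg = 4.0 * math.log(2.0) / fwhm**2
    diff = axis[:, None] - centers[None, :]
    return peak * np.exp(-arg * diff**2) @ weights


def dos_curve(orbitals: OrbitalSpectrum, fwhm: float = FWHM_DOS_DEFAULT,
              grid: Sequence[float] | None = None,
              occupied: bool | None = None) -> SpectrumCurve:
    """Broadened density of states from orbital energies.

    ``occupied`` restricts the curve to occupied (True) or virtual (False)
    orbitals, the filled/virtual split used when reading gaps off a DOS
    plot; None broadens everything.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    centers = []
    for e, o in zip(orbitals.energies, orbitals.occupations):
        if occupied is None or (occupied and o > 0.5) or (not occupied and o <= 0.5):
            centers.append(e)
    if not centers:
        raise EmptySpectrumError("no orbitals to broaden")
    axis = _grid(grid, DOS_GRID_DEFAULT)
    intensity = _gauss_sum(axis, np.array(centers), np.ones(len(centers)), fwhm)
    return SpectrumCurve(axis, intensity, fwhm, "dos")


def dos_gap_reading(orbitals: OrbitalSpectrum, fwhm: float = FWHM_DOS_DEFAULT,
                    grid: Sequence[float] | None = None) -> float:
    """Gap read off the DOS plot: distance between the highest occupied and
    lowest unoccupied peak centers (argmax of the split curves)."""
    occ = dos_curve(orbitals, fwhm, grid, occupied=True)
    virt = dos_curve(orbitals, fwhm, grid, occupied=False)
    return float(virt.axis[np.argmax(virt.intensity)]
                 - occ.axis[np.argmax(occ.intensity)])


def uvvis_curve(excitations: ExcitationSet, fwhm: float = FWHM_UVVIS_DEFAULT,
                grid: Sequence[float] | None = None) -> SpectrumCurve:
    """Oscillator-strength-weighted absorption curve on an energy grid."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    lines = [ln for ln in excitations.lines if ln.oscillator_strength > 0]
    if not lines:
        raise EmptySpectrumError("all oscillator strengths are zero")
    axis = _grid(grid, UVVIS_GRID_DEFAULT)
    centers = np.array([ln.energy_ev for ln in lines])
    weights = np.array([ln.oscillator_strength for ln in lines])
    intensity = _gauss_sum(axis, centers, weights, fwhm)
    return SpectrumCurve(axis, intensity, fwhm, "uvvis")


def lambda_max(curve: SpectrumCurve) -> float:
    """Wavelength (nm) of the global absorption maximum.

    Ties break toward longer wavelength, i.e. lower energy.
    """
    if curve.kind != "uvvis":
        raise ValueError("lambda_max applies to UV-Vis curves")
    if np.all(curve.intensity == 0):
        raise ValueError("flat zero curve has no maximum")
    peak = np.max(curve.intensity)
    idx = np.flatnonzero(curve.intensity == peak)
    if curve.axis_unit == "ev":
        # lowest energy among tied maxima -> longest wavelength
        return float(HC_EV_NM / curve.axis[idx.min()])
    return float(curve.axis[idx.max()])


@dataclass(frozen=True)
class ShiftReport:
    lambda_free: float
    lambda_complex: float
    delta_lambda: float
    direction: Literal["red", "blue", "none"]


def shift_report(lambda_free: float, lambda_complex: float) -> ShiftReport:
    """Complexation-induced absorption shift; red = shift to longer lambda."""
    if lambda_free <= 0 or lambda_complex <= 0:
        raise ValueError("wavelengths must be positive")
    delta = lambda_complex - lambda_free
    direction = "red" if delta > 0 else ("blue" if delta < 0 else "none")
    return ShiftReport(lambda_free, lambda_complex, delta, direction)


def ev_nm(value: float) -> float:
    """Convert photon energy (eV) to wavelength (nm) or back (involution)."""
    if value <= 0:
        raise ValueError("value must be positive")
    return HC_EV_NM / value
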