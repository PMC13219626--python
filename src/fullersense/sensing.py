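"""Adsorption/sensing figures of merit for a sensor-analyte pair.

Implements, for molar energies in kcal/mol and gaps in eV:

* cohesive energy E_coh = (E_total - sum(E_atom)) / n (kcal/mol per atom);
* adsorption energy E_ads = E_complex - (E_sensor + E_drug);
* Arrhenius-type desorption recovery time
  tau = nu0^-1 * exp(-E_ads / (R T)) with R T in kcal/mol (E_ads is molar);
* Richardson-type conductivity sigma = A T^(3/2) exp(-HLG / (2 k)).

The conductivity exponent supports two thermal-energy conventions.  In
``physical`` mode k = kB T in eV, pairing dimensionally with the gap.  In
``paper_compat`` mode k = R T in kJ/mol (numerically 2.4777 at 298 K)
paired with the bare eV numeral of the gap — a unit mix that is not
dimensionally consistent but is the only reading that reproduces the
published conductivity tables for these systems (established by solving
ln(sigma_i/sigma_j) against gap differences).  Both are exposed; neither
is silently preferred outside fixture reproduction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .constants import (
    A_RICHARDSON,
    KB_EV,
    NU0_DEFAULT,
    R_KCAL,
    R_KJ,
    T_DEFAULT,
)

SigmaMode = Literal["physical", "paper_compat"]

#: recovery-time thresholds (s) separating reusable sensing from capture
TAU_FAST_DEFAULT = 1.0
TAU_SLOW_DEFAULT = 1.0e6


@dataclass(frozen=True)
class SensingMetrics:
    """Figures of merit for one sensor@analyte pair."""

    e_ads: float
    tau: float
    sigma_free: float
    sigma_complex: float
    regime: str


def cohesive_energy(total_energy: float, atom_energies: Sequence[float]) -> float:
    """Cohesive energy per atom; negative means a bound structure."""
    if len(atom_energies) == 0:
        raise ValueError("atom_energies must be non-empty")
    return (total_energy - sum(atom_energies)) / len(atom_energies)


def adsorption_energy(e_complex: float, e_sensor: float, e_drug: float) -> float:
    """E_ads = E_complex - (E_sensor + E_drug); negative = favorable."""
    return e_complex - (e_sensor + e_drug)


def recovery_time(e_ads: float, temperature: float = T_DEFAULT,
                  nu0: float = NU0_DEFAULT) -> float:
    """Desorption timescale tau = nu0^-1 exp(-E_ads / (R T)).

    ``e_ads`` is molar (kcal/mol), so the Boltzmann factor uses the molar
    gas constant; R T = 0.5922 kcal/mol at 298 K.
    """
    if temperature <= 0 or nu0 <= 0:
        raise ValueError("temperature and nu0 must be positive")
    try:
        return (1.0 / nu0) * math.exp(-e_ads / (R_KCAL * temperature))
    except OverflowError:
        return math.inf  # desorption timescale beyond float range


def conductivity(hlg: float, temperature: float = T_DEFAULT,
                 a_richardson: float = A_RICHARDSON,
                 mode: SigmaMode = "physical") -> float:
    """Band-gap conductivity proxy sigma = A T^(3/2) exp(-HLG/(2k)), S/m."""
    if hlg < 0:
        raise ValueError("gap must be non-negative")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if mode == "physical":
        k = KB_EV * temperature
    elif mode == "paper_compat":
        k = R_KJ * temperature
    else:
        raise ValueError(f"unknown sigma mode: {mode!r}")
    return a_richardson * temperature ** 1.5 * math.exp(-hlg / (2.0 * k))


def dipole_magnitude(components: Sequence[float]) -> float:
    """Euclidean norm of the (mx, my, mz) dipole vector, Debye."""
    v = np.asarray(components, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)):
        raise ValueError("dipole needs three finite components")
    return float(np.linalg.norm(v))


def mean_polarizability(tensor: np.ndarray) -> float:
    """Mean polarizability (trace/3) of a symmetric 3x3 tensor, a.u."""
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("polarizability must be 3x3")
    if np.max(np.abs(t - t.T)) > 1e-8:
        raise ValueError("polarizability tensor must be symmetric")
    return float(np.trace(t) / 3.0)


def classify_regime(tau: float, tau_fast: float = TAU_FAST_DEFAULT,
                    tau_slow: float = TAU_SLOW_DEFAULT) -> str:
    """Label a recovery time as reusable sensing vs irreversible capture."""
    if tau_fast >= tau_slow:
        raise ValueError("tau_fast must be below tau_slow")
    if tau <= tau_fast:
        return "reversible-sensor"
    if tau >= tau_slow:
        return "adsorbent"
    return "intermediate"


def sensing_metrics(e_complex: float, e_sensor: float, e_drug: float,
                    hlg_free: float, hlg_complex: float,
                    temperature: float = T_DEFAULT, nu0: float = NU0_DEFAULT,
                    sigma_mode: SigmaMode = "physical",
                    tau_fast: float = TAU_FAST_DEFAULT,
                    tau_slow: float = TAU_SLOW_DEFAULT) -> SensingMetrics:
    """Full Eq.-4/5/6 evaluation for one sensor@analyte pair."""
    e_ads = adsorption_energy(e_complex, e_sensor, e_drug)
    tau = recovery_time(e_ads, temperature, nu0)
    return SensingMetrics(
        e_ads=e_ads,
        tau=tau,
        sigma_free=conductivity(hlg_free, temperature, mode=sigma_mode),
        sigma_complex=conductivity(hlg_complex, temperature, mode=sigma_mode),
        regime=classify_regime(tau, tau_fast, tau_slow),
    )
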