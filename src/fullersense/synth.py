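"""Synthetic sensor/analyte study sets.

Generates reproducible sensor-vs-complex bundle pairs whose encoded
parameters (frontier gap, chemical potential, adsorption energy,
excitation lines, dimer separation) are recoverable by the analysis
pipeline — exactly for a noiseless spec, unbiasedly under orbital jitter.
Geometries are two-center dimers: the topology analyses need only
two-center model densities with closed-form critical points, not cages.

All randomness flows from the integer seed in the spec through a local
``numpy.random.Generator``; no global state is touched.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .bundle import (
    EnergyRecord,
    Excitation,
    ExcitationSet,
    Geometry,
    OrbitalSpectrum,
    ResultBundle,
)

#: synthetic fragment reference totals, kcal/mol (arbitrary anchors; only
#: the Eq.-4 difference is meaningful)
E_SENSOR_REF = -400000.0
E_DRUG_REF = -150000.0

#: number of filler orbitals on each side of the frontier
N_FILLER = 8


@dataclass(frozen=True)
class ScenarioSpec:
    """Controllable knobs for one synthetic sensor/complex scenario."""

    seed: int
    gap_sensor: float = 1.67
    gap_complex: float = 1.18
    mu_sensor: float = -4.415
    mu_complex: float = -4.21
    eads: float = -11.15
    excitation_lines_free: tuple[tuple[float, float], ...] = ((2.78, 0.1),)
    excitation_lines_complex: tuple[tuple[float, float], ...] = ((2.33, 0.1),)
    separation: float = 2.8
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.gap_sensor < 0 or self.gap_complex < 0:
            raise ValueError("gaps must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.separation <= 0:
            raise ValueError("separation must be positive")


class SyntheticPair(NamedTuple):
    """Sensor, sensor@analyte complex, and the isolated analyte fragment."""

    sensor: ResultBundle
    complex: ResultBundle
    drug: ResultBundle


def _orbitals(rng: np.random.Generator, gap: float, mu: float,
              noise_sd: float) -> OrbitalSpectrum:
    homo = mu - gap / 2.0
    lumo = mu + gap / 2.0
    # fillers kept >= 1 eV clear of the frontier so jitter cannot reorder
    below = homo - 1.0 - np.sort(rng.uniform(0.0, 6.0, N_FILLER))[::-1]
    above = lumo + 1.0 + np.sort(rng.uniform(0.0, 6.0, N_FILLER))
    energies = np.concatenate([below[::-1], [homo, lumo], above])
    if noise_sd > 0:
        energies = energies + rng.normal(0.0, noise_sd, energies.size)
    order = np.argsort(energies)
    energies = energies[order]
    occupations = np.concatenate(
        [np.full(N_FILLER + 1, 2.0), np.zeros(N_FILLER + 1)]
    )[order.argsort()][order]
    return OrbitalSpectrum(list(energies), list(occupations))


def _excitations(lines: tuple[tuple[float, float], ...]) -> ExcitationSet | None:
    if not lines:
        return None
    return ExcitationSet([Excitation.from_energy(ev, f) for ev, f in lines])


def make_pair(spec: ScenarioSpec) -> SyntheticPair:
    """Build the sensor/complex/drug bundles encoding the spec parameters.

    Frontier orbitals reproduce mu +/- gap/2 exactly before jitter, energy
    records satisfy E_complex - (E_sensor + E_drug) = eads exactly, and
    the complex geometry is a C-N dimer at the stated separation.
    """
    rng = np.random.default_rng(spec.seed)
    sensor_orb = _orbitals(rng, spec.gap_sensor, spec.mu_sensor, spec.noise_sd)
    complex_orb = _orbitals(rng, spec.gap_complex, spec.mu_complex, spec.noise_sd)

    sensor_geom = Geometry([("C", 0.0, 0.0, 0.0)], label="synthetic sensor site")
    drug_geom = Geometry([("N", 0.0, 0.0, 0.0)], label="synthetic analyte site")
    complex_geom = Geometry(
        [("C", 0.0, 0.0, 0.0), ("N", 0.0, 0.0, spec.separation)],
        label=f"synthetic dimer d={spec.separation:g} A",
    )

    sensor = ResultBundle(
        label=f"synthetic-sensor-{spec.seed}",
        orbitals=sensor_orb,
        energies=EnergyRecord(E_SENSOR_REF, label="sensor"),
        geometry=sensor_geom,
        excitations=_excitations(spec.excitation_lines_free),
    )
    drug = ResultBundle(
        label=f"synthetic-drug-{spec.seed}",
        orbitals=OrbitalSpectrum([-9.0, 1.0], [2.0, 0.0]),
        energies=EnergyRecord(E_DRUG_REF, label="drug"),
        geometry=drug_geom,
    )
    complex_ = ResultBundle(
        label=f"synthetic-complex-{spec.seed}",
        orbitals=complex_orb,
        energies=EnergyRecord(E_SENSOR_REF + E_DRUG_REF + spec.eads,
                              label="complex"),
        geometry=complex_geom,
        excitations=_excitations(spec.excitation_lines_complex),
    )
    return SyntheticPair(sensor, complex_, drug)


def scenario_grid(n: int, seed: int) -> list[ScenarioSpec]:
    """n scenarios spanning physisorption to chemisorption, seed-determined.

    Adsorption energies alternate between the physisorption window
    [-15, -5] and the chemisorption window [-60, -30] kcal/mol; gaps span
    0.3-2.0 eV.  All energies are negative (favorable adsorption).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        if i % 2 == 0:
            eads = float(rng.uniform(-15.0, -5.0))
        else:
            eads = float(rng.uniform(-60.0, -30.0))
        gap_sensor = float(rng.uniform(0.3, 2.0))
        gap_complex = float(rng.uniform(0.3, 2.0))
        mu = float(rng.uniform(-5.0, -3.5))
        ev_free = float(rng.uniform(1.5, 3.0))
        ev_cplx = ev_free * float(rng.uniform(0.55, 0.95))  # red-shifted
        specs.append(
            ScenarioSpec(
                seed=int(rng.integers(0, 2**31 - 1)),
                gap_sensor=gap_sensor,
                gap_complex=gap_complex,
                mu_sensor=mu,
                mu_complex=mu + float(rng.uniform(-0.3, 0.3)),
                eads=eads,
                excitation_lines_free=((ev_free, 0.1),),
                excitation_lines_complex=((ev_cplx, 0.1),),
                separation=float(rng.uniform(1.2, 3.0)),
            )
        )
    return specs
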