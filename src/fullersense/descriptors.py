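"""Conceptual-DFT reactivity descriptors from frontier orbital energies.

For frontier energies E_HOMO and E_LUMO (eV) the global descriptors are

    HLG = |E_HOMO - E_LUMO|            (energy gap)
    eta = (E_LUMO - E_HOMO) / 2        (chemical hardness, > 0)
    mu  = (E_HOMO + E_LUMO) / 2        (chemical potential)
    S   = 1 / (2 eta)                  (chemical softness, 1/eV)
    dNmax = -mu / eta                  (max charge-transfer capacity)

and the electrophilicity-based charge transfer between an isolated sensor
and its sensor@analyte complex is ECT = dNmax(sensor) - dNmax(complex);
a negative ECT reads as charge transferred from the analyte to the sensor.

All values are reported unrounded; display rounding is a formatting
concern (see :mod:`fullersense.report`).  A degenerate frontier
(eta = 0) leaves softness and dNmax undefined (``None``), never infinite.
"""
from __future__ import annotations

from dataclasses import dataclass

from .bundle import OrbitalSpectrum


@dataclass(frozen=True)
class ReactivityDescriptors:
    e_homo: float
    e_lumo: float
    hlg: float
    hardness: float
    potential: float
    softness: float | None
    dnmax: float | None

    @property
    def frontier_defined(self) -> bool:
        return self.dnmax is not None


@dataclass(frozen=True)
class ChargeTransferReport:
    dnmax_sensor: float
    dnmax_complex: float
    ect: float

    @property
    def direction(self) -> str:
        """Reading of the ECT sign (analyte->sensor when negative)."""
        if self.ect < 0:
            return "analyte-to-sensor"
        if self.ect > 0:
            return "sensor-to-analyte"
        return "none"


def reactivity_descriptors(orbitals: OrbitalSpectrum) -> ReactivityDescriptors:
    """Compute the global reactivity descriptors of an orbital spectrum."""
    e_homo = orbitals.homo()
    e_lumo = orbitals.lumo()
    hlg = abs(e_homo - e_lumo)
    eta = (e_lumo - e_homo) / 2.0
    mu = (e_homo + e_lumo) / 2.0
    if eta > 0.0:
        softness: float | None = 1.0 / (2.0 * eta)
        dnmax: float | None = -mu / eta
    else:
        softness = None
        dnmax = None
    return ReactivityDescriptors(e_homo, e_lumo, hlg, eta, mu, softness, dnmax)


def ect(sensor: ReactivityDescriptors,
        complex_: ReactivityDescriptors) -> ChargeTransferReport:
    """Charge-transfer report between an isolated sensor and its complex."""
    if sensor.dnmax is None or complex_.dnmax is None:
        raise ValueError("dNmax undefined (degenerate frontier) on one side")
    return ChargeTransferReport(
        dnmax_sensor=sensor.dnmax,
        dnmax_complex=complex_.dnmax,
        ect=sensor.dnmax - complex_.dnmax,
    )
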