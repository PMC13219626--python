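"""Physical constants and unit conversions (CODATA 2018).

All conversions used anywhere in the package live here; the canonical
internal units are eV for orbital/excitation energies, kcal/mol for
thermochemistry, nm for wavelengths, Debye for dipoles, and Hartree
atomic units for density-related quantities.
"""
from __future__ import annotations

import math

#: Hartree -> kcal/mol
HARTREE_TO_KCAL = 627.5094740631

#: hc in eV*nm; E[eV] * lambda[nm] = HC_EV_NM
HC_EV_NM = 1239.84193

#: bohr per Angstrom
BOHR_PER_ANGSTROM = 1.8897259886

#: Boltzmann constant, eV/K
KB_EV = 8.617333262e-5

#: molar gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987204259e-3

#: molar gas constant, kJ mol^-1 K^-1
R_KJ = 8.314462618e-3

#: Richardson constant, A m^-2 K^-2
A_RICHARDSON = 6.0e5

#: default attempt ("effort") frequency for desorption, s^-1
NU0_DEFAULT = 1.0e12

#: default temperature, K
T_DEFAULT = 298.0

#: Thomas-Fermi kinetic-energy prefactor (3/10)(3 pi^2)^(2/3), a.u.
C_TF = 0.3 * (3.0 * math.pi**2) ** (2.0 / 3.0)

#: reduced-density-gradient prefactor 2 (3 pi^2)^(1/3)
C_RDG = 2.0 * (3.0 * math.pi**2) ** (1.0 / 3.0)
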