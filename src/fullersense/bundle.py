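"""Quantum-chemistry result bundles and the file formats around them.

A :class:`ResultBundle` is the per-system summary the rest of the pipeline
consumes: frontier orbital energies, total energies, electric tensors,
excitation lists and (optionally) a geometry.  Readers/writers are provided
for XYZ geometries, Gaussian cube volumetric files and a JSON bundle schema::

    {
      "label": "...",
      "geometry": {"atoms": [["C", x, y, z], ...], "charge": 0},
      "orbitals": {"energies_ev": [...], "occupations": [...]},
      "energies": {"total": ..., "units": "kcal/mol"|"hartree",
                   "atoms": [...]},
      "dipole_debye": [mx, my, mz],
      "polarizability_au": [[...], [...], [...]],
      "excitations": [{"ev": ..., "f": ...} | {"nm": ..., "f": ...}, ...]
    }

Units are canonicalized on read (eV, kcal/mol, Debye, a.u., nm); optional
sections that are absent stay absent.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import BOHR_PER_ANGSTROM, HARTREE_TO_KCAL, HC_EV_NM

SUPPORTED_ELEMENTS = {"H", "C", "N", "O", "Al", "Zn"}

#: atomic numbers for cube output
ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "Al": 13, "Zn": 30}


class FormatError(ValueError):
    """A file did not conform to its declared format."""


class SchemaError(ValueError):
    """A bundle JSON document violated the documented schema."""


@dataclass
class Geometry:
    """Molecular geometry in Angstroms."""

    atoms: list[tuple[str, float, float, float]]
    charge: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("geometry needs at least one atom")
        for sym, x, y, z in self.atoms:
            if sym not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element {sym!r}")
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValueError("non-finite coordinate")

    @property
    def symbols(self) -> list[str]:
        return [a[0] for a in self.atoms]

    def coords(self) -> np.ndarray:
        """Coordinates as an (n, 3) array in Angstroms."""
        return np.array([[x, y, z] for _, x, y, z in self.atoms], dtype=float)

    def translated(self, shift: Sequence[float]) -> "Geometry":
        dx, dy, dz = shift
        return Geometry(
            [(s, x + dx, y + dy, z + dz) for s, x, y, z in self.atoms],
            charge=self.charge,
            label=self.label,
        )


@dataclass
class OrbitalSpectrum:
    """Molecular orbital energies (eV, ascending) with occupations in [0, 2].

    The HOMO is the highest orbital with occupation > 0.5, the LUMO the
    lowest with occupation <= 0.5; degenerate ties break by index.
    """

    energies: list[float]
    occupations: list[float]

    def __post_init__(self) -> None:
        if len(self.energies) != len(self.occupations):
            raise ValueError("energies/occupations length mismatch")
        if any(e2 < e1 for e1, e2 in zip(self.energies, self.energies[1:])):
            raise ValueError("orbital energies must be sorted ascending")
        if any(not (0.0 <= o <= 2.0) for o in self.occupations):
            raise ValueError("occupations must lie in [0, 2]")

    def homo(self) -> float:
        occ = [e for e, o in zip(self.energies, self.occupations) if o > 0.5]
        if not occ:
            raise ValueError("no occupied orbital (occupation > 0.5)")
        return occ[-1]

    def lumo(self) -> float:
        virt = [e for e, o in zip(self.energies, self.occupations) if o <= 0.5]
        if not virt:
            raise ValueError("no virtual orbital (occupation <= 0.5)")
        return virt[0]


@dataclass
class EnergyRecord:
    """Total energy and optional isolated-atom energies, kcal/mol."""

    total_energy: float
    atom_energies: list[float] | None = None
    label: str = ""


@dataclass
class ElectricTensors:
    """Dipole vector (Debye) and static polarizability tensor (a.u.)."""

    dipole: tuple[float, float, float]
    polarizability: np.ndarray

    def __post_init__(self) -> None:
        self.polarizability = np.asarray(self.polarizability, dtype=float)
        if self.polarizability.shape != (3, 3):
            raise ValueError("polarizability must be 3x3")
        if not np.all(np.isfinite(self.polarizability)):
            raise ValueError("non-finite polarizability entry")
        if np.max(np.abs(self.polarizability - self.polarizability.T)) > 1e-8:
            raise ValueError("polarizability tensor must be symmetric")


@dataclass
class Excitation:
    """One electronic excitation: energy (eV), wavelength (nm), strength f."""

    energy_ev: float
    wavelength_nm: float
    oscillator_strength: float

    @classmethod
    def from_energy(cls, ev: float, f: float) -> "Excitation":
        if ev <= 0:
            raise ValueError("excitation energy must be positive")
        if f < 0:
            raise ValueError("oscillator strength must be non-negative")
        return cls(ev, HC_EV_NM / ev, f)

    @classmethod
    def from_wavelength(cls, nm: float, f: float) -> "Excitation":
        if nm <= 0:
            raise ValueError("wavelength must be positive")
        if f < 0:
            raise ValueError("oscillator strength must be non-negative")
        return cls(HC_EV_NM / nm, nm, f)


@dataclass
class ExcitationSet:
    """A list of excitations with E * lambda = hc enforced on construction."""

    lines: list[Excitation]

    def __post_init__(self) -> None:
        for ln in self.lines:
            if abs(ln.energy_ev * ln.wavelength_nm - HC_EV_NM) > 1e-6 * HC_EV_NM:
                raise ValueError("excitation violates E*lambda = hc")


@dataclass
class ResultBundle:
    """One system's quantum-chemistry summary in canonical units."""

    label: str
    orbitals: OrbitalSpectrum
    energies: EnergyRecord
    geometry: Geometry | None = None
    electric: ElectricTensors | None = None
    excitations: ExcitationSet | None = None
    atomic_charges: list[float] | None = None


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> Geometry:
    """Read a standard XYZ file (element symbols, Angstroms).

    The comment line is preserved verbatim as the geometry label.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (line 1)")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed atom count (line 1)") from exc
    label = lines[1] if len(lines) > 1 else ""
    atoms: list[tuple[str, float, float, float]] = []
    for i in range(natoms):
        lineno = i + 3
        if i + 2 >= len(lines) or not lines[i + 2].split():
            last = len([ln for ln in lines if ln.strip()])
            raise FormatError(
                f"{path}: header declares {natoms} atoms but records stop at line {last}"
            )
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise FormatError(f"{path}: short atom record (line {lineno})")
        sym = parts[0]
        if sym not in SUPPORTED_ELEMENTS:
            raise FormatError(f"{path}: unknown element {sym!r} (line {lineno})")
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric coordinate (line {lineno})"
            ) from exc
        atoms.append((sym, x, y, z))
    return Geometry(atoms, label=label)


def write_xyz(geometry: Geometry, path: str | Path) -> None:
    out = [str(len(geometry.atoms)), geometry.label]
    for sym, x, y, z in geometry.atoms:
        out.append(f"{sym} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# JSON bundle
# ---------------------------------------------------------------------------

_ENERGY_UNITS = {"kcal/mol": 1.0, "hartree": HARTREE_TO_KCAL}


def _require(doc: dict, key: str, path: str) -> object:
    if key not in doc:
        raise SchemaError(f"missing required key: {path}{key}")
    return doc[key]


def _floats(seq: object, path: str) -> list[float]:
    if not isinstance(seq, (list, tuple)):
        raise SchemaError(f"expected a list at {path}")
    out = []
    for i, v in enumerate(seq):
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise SchemaError(f"non-numeric entry at {path}[{i}]")
        out.append(float(v))
    return out


def read_bundle(path: str | Path) -> ResultBundle:
    """Read a JSON result bundle, converting all units to canonical."""
    doc = json.loads(Path(path).read_text())
    return bundle_from_dict(doc)


def bundle_from_dict(doc: dict) -> ResultBundle:
    label = str(_require(doc, "label", ""))
    orb = _require(doc, "orbitals", "")
    energies_ev = _floats(_require(orb, "energies_ev", "orbitals."), "orbitals.energies_ev")
    occs = _floats(_require(orb, "occupations", "orbitals."), "orbitals.occupations")
    orbitals = OrbitalSpectrum(energies_ev, occs)

    en = _require(doc, "energies", "")
    unit = en.get("units", "kcal/mol")
    if unit not in _ENERGY_UNITS:
        raise SchemaError(f"unknown unit tag at energies.units: {unit!r}")
    scale = _ENERGY_UNITS[unit]
    total = _floats([_require(en, "total", "energies.")], "energies.total")[0] * scale
    atom_energies = None
    if "atoms" in en:
        atom_energies = [v * scale for v in _floats(en["atoms"], "energies.atoms")]
    energies = EnergyRecord(total, atom_energies, label=label)

    geometry = None
    if "geometry" in doc:
        g = doc["geometry"]
        atoms = []
        for i, rec in enumerate(_require(g, "atoms", "geometry.")):
            sym = rec[0]
            x, y, z = _floats(rec[1:4], f"geometry.atoms[{i}]")
            atoms.append((sym, x, y, z))
        geometry = Geometry(atoms, charge=int(g.get("charge", 0)), label=label)
        if atom_energies is not None and len(atom_energies) != len(atoms):
            raise SchemaError("energies.atoms length must match geometry atom count")

    electric = None
    if "dipole_debye" in doc or "polarizability_au" in doc:
        dip = _floats(_require(doc, "dipole_debye", ""), "dipole_debye")
        if len(dip) != 3:
            raise SchemaError("dipole_debye must have 3 components")
        pol = np.array(
            [_floats(row, "polarizability_au") for row in _require(doc, "polarizability_au", "")]
        )
        electric = ElectricTensors((dip[0], dip[1], dip[2]), pol)

    excitations = None
    if "excitations" in doc:
        lines = []
        for i, rec in enumerate(doc["excitations"]):
            f = _floats([_require(rec, "f", f"excitations[{i}].")], "f")[0]
            if "ev" in rec:
                lines.append(Excitation.from_energy(float(rec["ev"]), f))
            elif "nm" in rec:
                lines.append(Excitation.from_wavelength(float(rec["nm"]), f))
            else:
                raise SchemaError(f"excitations[{i}] needs 'ev' or 'nm'")
        excitations = ExcitationSet(lines)

    charges = None
    if "atomic_charges" in doc:
        charges = _floats(doc["atomic_charges"], "atomic_charges")

    return ResultBundle(
        label=label,
        orbitals=orbitals,
        energies=energies,
        geometry=geometry,
        electric=electric,
        excitations=excitations,
        atomic_charges=charges,
    )


def bundle_to_dict(b: ResultBundle) -> dict:
    doc: dict = {
        "label": b.label,
        "orbitals": {
            "energies_ev": list(b.orbitals.energies),
            "occupations": list(b.orbitals.occupations),
        },
        "energies": {"total": b.energies.total_energy, "units": "kcal/mol"},
    }
    if b.energies.atom_energies is not None:
        doc["energies"]["atoms"] = list(b.energies.atom_energies)
    if b.geometry is not None:
        doc["geometry"] = {
            "atoms": [[s, x, y, z] for s, x, y, z in b.geometry.atoms],
            "charge": b.geometry.charge,
        }
    if b.electric is not None:
        doc["dipole_debye"] = list(b.electric.dipole)
        doc["polarizability_au"] = b.electric.polarizability.tolist()
    if b.excitations is not None:
        doc["excitations"] = [
            {"ev": ln.energy_ev, "f": ln.oscillator_strength}
            for ln in b.excitations.lines
        ]
    if b.atomic_charges is not None:
        doc["atomic_charges"] = list(b.atomic_charges)
    return doc


def write_bundle(b: ResultBundle, path: str | Path) -> None:
    Path(path).write_text(json.dumps(bundle_to_dict(b), indent=1))


# ---------------------------------------------------------------------------
# Gaussian cube
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Regular volumetric grid: origin and per-axis steps in Angstroms."""

    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    step: tuple[float, float, float]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[i] + self.step[i] * np.arange(self.shape[i])
            for i in range(3)
        )


def write_cube(
    values: np.ndarray,
    grid: GridSpec,
    geometry: Geometry,
    path: str | Path,
    comment: str = "fullersense volumetric data",
) -> None:
    """Write a Gaussian cube file (header in bohr, z-fastest value order)."""
    values = np.asarray(values, dtype=float)
    if values.shape != tuple(grid.shape):
        raise ValueError(
            f"value array shape {values.shape} does not match grid {grid.shape}"
        )
    b = BOHR_PER_ANGSTROM
    lines = [comment, "OUTER LOOP: X, MIDDLE: Y, INNER: Z"]
    ox, oy, oz = (c * b for c in grid.origin)
    lines.append(f"{len(geometry.atoms):5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}")
    for i in range(3):
        vec = [0.0, 0.0, 0.0]
        vec[i] = grid.step[i] * b
        lines.append(
            f"{grid.shape[i]:5d} {vec[0]:12.6f} {vec[1]:12.6f} {vec[2]:12.6f}"
        )
    for sym, x, y, z in geometry.atoms:
        zn = ATOMIC_NUMBERS[sym]
        lines.append(
            f"{zn:5d} {float(zn):12.6f} {x * b:12.6f} {y * b:12.6f} {z * b:12.6f}"
        )
    flat = values.reshape(-1)  # C order == z fastest for (nx, ny, nz)
    for start in range(0, flat.size, 6):
        lines.append(" ".join(f"{v:13.5E}" for v in flat[start : start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> tuple[np.ndarray, GridSpec, Geometry]:
    """Read back a cube written by :func:`write_cube`."""
    lines = Path(path).read_text().splitlines()
    natoms = int(lines[2].split()[0])
    origin = tuple(float(v) / BOHR_PER_ANGSTROM for v in lines[2].split()[1:4])
    shape = []
    step = []
    for i in range(3):
        parts = lines[3 + i].split()
        shape.append(int(parts[0]))
        step.append(float(parts[1 + i]) / BOHR_PER_ANGSTROM)
    atoms = []
    num_to_sym = {v: k for k, v in ATOMIC_NUMBERS.items()}
    for i in range(natoms):
        parts = lines[6 + i].split()
        atoms.append(
            (
                num_to_sym[int(parts[0])],
                float(parts[2]) / BOHR_PER_ANGSTROM,
                float(parts[3]) / BOHR_PER_ANGSTROM,
                float(parts[4]) / BOHR_PER_ANGSTROM,
            )
        )
    vals = []
    for line in lines[6 + natoms :]:
        vals.extend(float(v) for v in line.split())
    grid = GridSpec(origin, tuple(shape), tuple(step))  # type: ignore[arg-type]
    return np.array(vals).reshape(grid.shape), grid, Geometry(atoms)
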