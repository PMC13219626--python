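"""Real-space analysis of model electron densities.

The analyses the sensing study applies in real space — NCI/RDG, ELF, LOL
and QTAIM bond-critical-point properties — are implemented here on
*promolecular* model densities: each atom contributes a sum of spherical
exponential shells

    rho_elem(r) = sum_i c_i exp(-r / zeta_i)        (a.u., r in bohr)

and the molecular density is the unrelaxed superposition of atoms.  Such
densities have closed-form gradients and Hessians, so every topological
quantity is analytic and testable without a wavefunction file.

The built-in shell table is the package's own model: per-shell Slater
screening-rule exponents xi (Slater, Phys. Rev. 36, 57, 1930), decay
length zeta = 1/(2 xi) bohr, and amplitude c = N_shell / (8 pi zeta^3) so
each shell integrates to its electron population.

Field-derived indicators:

* reduced density gradient  s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3));
* NCI signed density        sign(lambda_2) * rho  (lambda_2 the middle
  Hessian eigenvalue; negative = attractive, ~0 = van der Waals,
  positive = repulsive);
* ELF (Becke-Edgecombe)     1 / (1 + (D/D_h)^2) with Pauli kinetic energy
  D = tau - |grad rho|^2/(8 rho) and D_h the Thomas-Fermi value;
* LOL (Schmider-Becke)      t / (1 + t), t = tau_TF / tau;
* Abramov kinetic density   G = (3/10)(3 pi^2)^(2/3) rho^(5/3)
                                + |grad rho|^2/(72 rho) + lap(rho)/6,
  local-virial potential    V = lap(rho)/4 - 2 G,  total  H = G + V.

On promolecular fields the kinetic energy density entering ELF/LOL is the
Thomas-Fermi + Weizsaecker estimate ("approximate ELF/LOL"); an exact
orbital-based tau is outside this model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .bundle import Geometry, GridSpec
from .constants import BOHR_PER_ANGSTROM, C_RDG, C_TF

__all__ = [
    "PromolecularModel", "FieldSample", "NCIPoint", "BCPRecord",
    "PromolecularField", "promolecular_field", "rdg", "signed_density",
    "kinetic_density", "elf", "lol", "energy_densities",
    "total_energy_density", "find_bcps", "evaluate_grid",
    "default_grid",
]

GRID_QUANTITIES = ("rho", "rdg", "signed_rho", "elf", "lol", "laplacian")

#: Slater-rule shells per element: (electron population, exponent xi)
_SLATER_SHELLS: dict[str, list[tuple[float, float]]] = {
    "H":  [(1.0, 1.0)],
    "C":  [(2.0, 5.70), (4.0, 1.625)],
    "N":  [(2.0, 6.70), (5.0, 1.95)],
    "O":  [(2.0, 7.70), (6.0, 2.275)],
    "Al": [(2.0, 12.70), (8.0, 4.425), (3.0, 7.0 / 6.0)],
    "Zn": [(2.0, 29.70), (8.0, 12.925), (8.0, 6.25), (10.0, 2.95),
           (2.0, 4.35 / 3.7)],
}


def _slater_table() -> dict[str, list[tuple[float, float]]]:
    table = {}
    for elem, shells in _SLATER_SHELLS.items():
        params = []
        for pop, xi in shells:
            zeta = 1.0 / (2.0 * xi)
            c = pop / (8.0 * math.pi * zeta**3)
            params.append((c, zeta))
        table[elem] = params
    return table


@dataclass
class PromolecularModel:
    """Per-element exponential-shell parameters (c_i a.u., zeta_i bohr)."""

    shells: Mapping[str, Sequence[tuple[float, float]]] = field(
        default_factory=_slater_table
    )

    def __post_init__(self) -> None:
        for elem, params in self.shells.items():
            for c, zeta in params:
                if c <= 0 or zeta <= 0:
                    raise ValueError(
                        f"{elem}: shell coefficients and decays must be positive"
                    )

    def supports(self, element: str) -> bool:
        return element in self.shells


@dataclass
class FieldSample:
    """Density and derivatives at one point (all a.u., position in bohr)."""

    position: np.ndarray
    rho: float
    grad: np.ndarray
    hessian: np.ndarray

    @property
    def grad_norm(self) -> float:
        return float(np.linalg.norm(self.grad))

    @property
    def laplacian(self) -> float:
        return float(np.trace(self.hessian))

    @property
    def eigenvalues(self) -> np.ndarray:
        """Hessian eigenvalues sorted lambda_1 <= lambda_2 <= lambda_3."""
        return np.linalg.eigvalsh(self.hessian)


@dataclass(frozen=True)
class NCIPoint:
    rho: float
    s: float
    signed_rho: float
    nci_class: Literal["attractive", "vdw", "repulsive"]


@dataclass(frozen=True)
class BCPRecord:
    """A (3,-1) critical point of rho with Abramov/virial energy densities."""

    position: np.ndarray
    rho: float
    laplacian: float
    g: float
    v: float
    h: float
    signature: tuple[int, int]


class PromolecularField:
    """Analytic promolecular density for a geometry (no numerics involved)."""

    def __init__(self, geometry: Geometry, model: PromolecularModel | None = None):
        model = model if model is not None else PromolecularModel()
        for sym in geometry.symbols:
            if not model.supports(sym):
                raise ValueError(f"element {sym!r} not in promolecular model")
        self.geometry = geometry
        self.model = model
        self.centers_bohr = geometry.coords() * BOHR_PER_ANGSTROM
        # flatten shells into per-shell arrays for vectorized evaluation
        cs, zetas, idx = [], [], []
        for iat, sym in enumerate(geometry.symbols):
            for c, zeta in model.shells[sym]:
                cs.append(c)
                zetas.append(zeta)
                idx.append(iat)
        self._c = np.array(cs)
        self._zeta = np.array(zetas)
        self._centers = self.centers_bohr[np.array(idx)]

    def evaluate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """rho, gradient and Hessian at points (n, 3) in bohr.

        Returns arrays of shape (n,), (n, 3) and (n, 3, 3).  Derivatives
        are analytic sums over shells; points exactly at a nucleus sit on
        the exponential cusp and are nudged by 1e-10 bohr.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        diff = pts[:, None, :] - self._centers[None, :, :]   # (n, m, 3)
        r = np.linalg.norm(diff, axis=2)                      # (n, m)
        r = np.maximum(r, 1e-10)
        f = self._c[None, :] * np.exp(-r / self._zeta[None, :])
        fp = -f / self._zeta[None, :]                        # f'(r)
        fpp = f / self._zeta[None, :] ** 2                   # f''(r)
        rho = f.sum(axis=1)
        unit = diff / r[:, :, None]
        grad = (fp[:, :, None] * unit).sum(axis=1)
        # Hessian: (f'' - f'/r) u u^T + (f'/r) I  per shell
        aniso = (fpp - fp / r)[:, :, None, None] * (
            unit[:, :, :, None] * unit[:, :, None, :]
        )
        iso = (fp / r)[:, :, None, None] * np.eye(3)[None, None, :, :]
        hess = (aniso + iso).sum(axis=1)
        return rho, grad, hess

    def sample(self, point: Sequence[float]) -> FieldSample:
        """Field sample at a single point (bohr)."""
        rho, grad, hess = self.evaluate(np.asarray(point, dtype=float)[None, :])
        return FieldSample(np.asarray(point, dtype=float), float(rho[0]),
                           grad[0], hess[0])


def promolecular_field(geometry: Geometry,
                       model: PromolecularModel | None = None) -> PromolecularField:
    """Build the analytic promolecular density evaluator for a geometry."""
    return PromolecularField(geometry, model)


def rdg(rho: float, grad_norm: float) -> float:
    """Reduced density gradient s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    return grad_norm / (C_RDG * rho ** (4.0 / 3.0))


def signed_density(sample: FieldSample, rho_cut: float = 0.01) -> NCIPoint:
    """NCI point: sign(lambda_2)*rho with the attractive/vdW/repulsive class."""
    lam2 = float(sample.eigenvalues[1])
    signed = math.copysign(sample.rho, lam2) if lam2 != 0.0 else 0.0
    if signed < -rho_cut:
        cls: Literal["attractive", "vdw", "repulsive"] = "attractive"
    elif signed > rho_cut:
        cls = "repulsive"
    else:
        cls = "vdw"
    return NCIPoint(sample.rho, rdg(sample.rho, sample.grad_norm), signed, cls)


def kinetic_density(sample: FieldSample,
                    mode: Literal["tf", "tfw"] = "tfw") -> float:
    """Thomas-Fermi (optionally + Weizsaecker) kinetic energy density."""
    if sample.rho <= 0:
        raise ValueError("rho must be positive")
    tau = C_TF * sample.rho ** (5.0 / 3.0)
    if mode == "tfw":
        tau += sample.grad_norm**2 / (8.0 * sample.rho)
    elif mode != "tf":
        raise ValueError(f"unknown kinetic-density mode: {mode!r}")
    return tau


def elf(sample: FieldSample, tau: float) -> float:
    """Becke-Edgecombe electron localization function, in [0, 1].

    The Pauli kinetic energy D = tau - |grad rho|^2/(8 rho) is clamped to
    zero when the supplied tau undershoots the Weizsaecker bound.
    """
    if sample.rho <= 0:
        raise ValueError("rho must be positive")
    d = tau - sample.grad_norm**2 / (8.0 * sample.rho)
    if d < 0.0:
        d = 0.0
    d_h = C_TF * sample.rho ** (5.0 / 3.0)
    return 1.0 / (1.0 + (d / d_h) ** 2)


def lol(sample: FieldSample, tau: float) -> float:
    """Schmider-Becke localized orbital locator nu = t/(1+t), t = tau_TF/tau."""
    if sample.rho <= 0:
        raise ValueError("rho must be positive")
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = C_TF * sample.rho ** (5.0 / 3.0) / tau
    return t / (1.0 + t)


def energy_densities(rho: float, grad_norm: float,
                     laplacian: float) -> tuple[float, float, float]:
    """Abramov kinetic G, local-virial potential V and total H = G + V."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    g = C_TF * rho ** (5.0 / 3.0) + grad_norm**2 / (72.0 * rho) + laplacian / 6.0
    v = laplacian / 4.0 - 2.0 * g
    return g, v, g + v


def total_energy_density(g: float, v: float) -> float:
    """Total electronic energy density H = G + V at a point."""
    return g + v


def _signature(eigvals: np.ndarray, tol: float = 1e-12) -> tuple[int, int]:
    rank = int(np.sum(np.abs(eigvals) > tol))
    sig = int(np.sum(np.sign(eigvals[np.abs(eigvals) > tol])))
    return rank, sig


def find_bcps(field: PromolecularField, *, pair_cutoff: float = 4.0,
              max_iter: int = 100, grad_tol: float = 1e-8,
              merge_radius: float = 1e-3) -> list[BCPRecord]:
    """Locate (3,-1) bond critical points of the field's density.

    Newton iterations on grad rho = 0 are seeded at the midpoint of every
    atom pair closer than ``pair_cutoff`` Angstroms; steps longer than
    0.5 bohr are damped by half.  Non-converging or singular-Hessian seeds
    are skipped; converged points are deduplicated within ``merge_radius``
    bohr and only saddle points of signature (3,-1) are kept.
    """
    geom = field.geometry
    n = len(geom.atoms)
    if n < 2:
        return []
    coords = geom.coords()
    seeds = []
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= pair_cutoff:
                mid = 0.5 * (field.centers_bohr[i] + field.centers_bohr[j])
                seeds.append(mid)
    found: list[BCPRecord] = []
    for seed in seeds:
        x = seed.copy()
        converged = False
        for _ in range(max_iter):
            s = field.sample(x)
            if s.grad_norm < grad_tol:
                converged = True
                break
            try:
                step = np.linalg.solve(s.hessian, -s.grad)
            except np.linalg.LinAlgError:
                break
            if np.linalg.norm(step) > 0.5:
                step *= 0.5
            x = x + step
        if not converged:
            continue
        s = field.sample(x)
        sig = _signature(s.eigenvalues)
        if sig != (3, -1):
            continue
        if any(np.linalg.norm(x - rec.position) < merge_radius for rec in found):
            continue
        g, v, h = energy_densities(s.rho, s.grad_norm, s.laplacian)
        found.append(BCPRecord(x, s.rho, s.laplacian, g, v, h, sig))
    return found


def default_grid(geometry: Geometry, pad: float = 2.5,
                 step: float = 0.1) -> GridSpec:
    """Bounding box of the geometry padded by ``pad`` Angstroms."""
    coords = geometry.coords()
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = tuple(int(math.floor((hi[i] - lo[i]) / step)) + 1 for i in range(3))
    return GridSpec(tuple(lo), shape, (step, step, step))


def evaluate_grid(field: PromolecularField, grid: GridSpec | None = None,
                  quantities: Iterable[str] = ("rho", "rdg", "signed_rho"),
                  rho_cut: float = 0.01) -> tuple[dict[str, np.ndarray], GridSpec]:
    """Evaluate requested scalar fields on a regular grid (cube-writable).

    Returns a dict of arrays shaped like the grid plus the grid spec used.
    ELF/LOL on grids use the Thomas-Fermi + Weizsaecker kinetic density
    (approximate ELF/LOL of the promolecular model).
    """
    quantities = tuple(quantities)
    if not quantities:
        raise ValueError("empty quantity set")
    unknown = set(quantities) - set(GRID_QUANTITIES)
    if unknown:
        raise ValueError(f"unknown grid quantities: {sorted(unknown)}")
    if grid is None:
        grid = default_grid(field.geometry)
    ax, ay, az = grid.axes()
    pts = np.stack(np.meshgrid(ax, ay, az, indexing="ij"), axis=-1)
    pts_bohr = pts.reshape(-1, 3) * BOHR_PER_ANGSTROM
    rho, grad, hess = field.evaluate(pts_bohr)
    gnorm = np.linalg.norm(grad, axis=1)
    out: dict[str, np.ndarray] = {}
    if "rho" in quantities:
        out["rho"] = rho
    if "rdg" in quantities:
        out["rdg"] = gnorm / (C_RDG * rho ** (4.0 / 3.0))
    if "laplacian" in quantities:
        out["laplacian"] = np.trace(hess, axis1=1, axis2=2)
    if "signed_rho" in quantities:
        lam2 = np.linalg.eigvalsh(hess)[:, 1]
        out["signed_rho"] = np.sign(lam2) * rho
    if "elf" in quantities or "lol" in quantities:
        tau_tf = C_TF * rho ** (5.0 / 3.0)
        tau_w = gnorm**2 / (8.0 * rho)
        tau = tau_tf + tau_w
        if "elf" in quantities:
            d = np.maximum(tau - tau_w, 0.0)
            out["elf"] = 1.0 / (1.0 + (d / tau_tf) ** 2)
        if "lol" in quantities:
            t = tau_tf / tau
            out["lol"] = t / (1.0 + t)
    return {k: v.reshape(grid.shape) for k, v in out.items()}, grid
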