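"""Study-level report: descriptors -> sensing -> spectra for one pair.

``run_report`` takes the sensor, sensor@analyte complex and isolated
analyte bundles and emits the study tables as CSV (reactivity, sensing,
electric-response, spectra) plus a JSON summary holding the unrounded
values, the sensing-regime label and the absorption-shift report.  CSV
bodies are deterministic for identical inputs; display rounding follows
the conventions of the reference tables (2 decimals for descriptors,
conductivity as x1e9 with 2 decimals, recovery time in scientific
notation) while the JSON keeps full precision.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd

from .bundle import ResultBundle
from .constants import NU0_DEFAULT, T_DEFAULT
from .descriptors import ect, reactivity_descriptors
from .sensing import (
    TAU_FAST_DEFAULT,
    TAU_SLOW_DEFAULT,
    classify_regime,
    conductivity,
    dipole_magnitude,
    mean_polarizability,
    recovery_time,
    adsorption_energy,
)
from .spectra import (
    FWHM_DOS_DEFAULT,
    FWHM_UVVIS_DEFAULT,
    lambda_max,
    shift_report,
    uvvis_curve,
)


class ReportError(RuntimeError):
    """A required bundle section is missing or the config is invalid."""


@dataclass
class StudyConfig:
    """Tunable parameters of a report run; unknown keys are rejected."""

    temperature: float = T_DEFAULT
    nu0: float = NU0_DEFAULT
    sigma_mode: str = "paper_compat"
    fwhm_dos: float = FWHM_DOS_DEFAULT
    fwhm_uv: float = FWHM_UVVIS_DEFAULT
    tau_fast: float = TAU_FAST_DEFAULT
    tau_slow: float = TAU_SLOW_DEFAULT

    def __post_init__(self) -> None:
        for name in ("temperature", "nu0", "fwhm_dos", "fwhm_uv",
                     "tau_fast", "tau_slow"):
            if getattr(self, name) <= 0:
                raise ReportError(f"config: {name} must be positive")
        if self.sigma_mode not in ("physical", "paper_compat"):
            raise ReportError(f"config: unknown sigma_mode {self.sigma_mode!r}")
        if self.tau_fast >= self.tau_slow:
            raise ReportError("config: tau_fast must be below tau_slow")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Read a ``key = value`` config file."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ReportError(f"config line {lineno}: expected key = value")
            key, _, value = (p.strip() for p in line.partition("="))
            if key not in known:
                raise ReportError(f"config line {lineno}: unknown key {key!r}")
            kwargs[key] = value if key == "sigma_mode" else float(value)
        return cls(**kwargs)


def _descriptor_row(label: str, bundle: ResultBundle) -> dict:
    d = reactivity_descriptors(bundle.orbitals)
    return {
        "structure": label,
        "LUMO": d.e_lumo, "HOMO": d.e_homo, "HLG": d.hlg,
        "eta": d.hardness, "mu": d.potential, "S": d.softness,
        "dNmax": d.dnmax,
    }


def run_report(sensor: ResultBundle, complex_: ResultBundle,
               drug: ResultBundle, config: StudyConfig | None = None,
               outdir: str | Path = ".") -> dict:
    """Run the full pipeline for one study pair and write the report files.

    Returns the summary dict (also written as ``summary.json``).  On a
    missing required bundle section the report aborts and removes any
    partially written outputs.
    """
    config = config if config is not None else StudyConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(sensor, complex_, drug, config, outdir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(sensor: ResultBundle, complex_: ResultBundle, drug: ResultBundle,
         config: StudyConfig, outdir: Path, written: list[Path]) -> dict:
    # --- reactivity (descriptor table layout) ---
    d_sensor = reactivity_descriptors(sensor.orbitals)
    d_complex = reactivity_descriptors(complex_.orbitals)
    rows = [_descriptor_row(sensor.label, sensor),
            _descriptor_row(complex_.label, complex_)]
    ct = ect(d_sensor, d_complex)
    rows[1]["ECT"] = ct.ect
    df = pd.DataFrame(rows).round(2)
    path = outdir / "reactivity.csv"
    df.to_csv(path, index=False)
    written.append(path)

    # --- sensing (adsorption/recovery/conductivity layout) ---
    e_ads = adsorption_energy(complex_.energies.total_energy,
                              sensor.energies.total_energy,
                              drug.energies.total_energy)
    tau = recovery_time(e_ads, config.temperature, config.nu0)
    sigma_free = conductivity(d_sensor.hlg, config.temperature,
                              mode=config.sigma_mode)
    sigma_complex = conductivity(d_complex.hlg, config.temperature,
                                 mode=config.sigma_mode)
    regime = classify_regime(tau, config.tau_fast, config.tau_slow)
    sensing_df = pd.DataFrame([
        {"structure": sensor.label, "Eads_kcal_mol": "",
         "tau_s": "", "sigma_1e9_S_m": f"{sigma_free / 1e9:.2f}"},
        {"structure": complex_.label, "Eads_kcal_mol": f"{e_ads:.2f}",
         "tau_s": f"{tau:.2e}", "sigma_1e9_S_m": f"{sigma_complex / 1e9:.2f}"},
    ])
    path = outdir / "sensing.csv"
    sensing_df.to_csv(path, index=False)
    written.append(path)

    # --- electric response (dipole/polarizability layout) ---
    elec_rows = []
    for b in (sensor, complex_):
        if b.electric is None:
            elec_rows.append({"structure": b.label, "dipole_debye": "",
                              "polarizability_au": ""})
        else:
            elec_rows.append({
                "structure": b.label,
                "dipole_debye": f"{dipole_magnitude(b.electric.dipole):.2f}",
                "polarizability_au":
                    f"{mean_polarizability(b.electric.polarizability):.2f}",
            })
    path = outdir / "electric.csv"
    pd.DataFrame(elec_rows).to_csv(path, index=False)
    written.append(path)

    # --- spectra (lambda_max/Eex layout + shift) ---
    if sensor.excitations is None or complex_.excitations is None:
        raise ReportError("missing excitations section on "
                          + (sensor.label if sensor.excitations is None
                             else complex_.label))
    lam_free = lambda_max(uvvis_curve(sensor.excitations, config.fwhm_uv))
    lam_cplx = lambda_max(uvvis_curve(complex_.excitations, config.fwhm_uv))
    shift = shift_report(lam_free, lam_cplx)
    spectra_df = pd.DataFrame([
        {"structure": sensor.label, "lambda_max_nm": f"{lam_free:.1f}",
         "Eex_eV": f"{1239.84193 / lam_free:.2f}"},
        {"structure": complex_.label, "lambda_max_nm": f"{lam_cplx:.1f}",
         "Eex_eV": f"{1239.84193 / lam_cplx:.2f}"},
    ])
    path = outdir / "spectra.csv"
    spectra_df.to_csv(path, index=False)
    written.append(path)

    summary = {
        "sensor": sensor.label,
        "complex": complex_.label,
        "descriptors": {
            sensor.label: asdict(d_sensor),
            complex_.label: asdict(d_complex),
        },
        "ect": ct.ect,
        "charge_transfer_direction": ct.direction,
        "e_ads_kcal_mol": e_ads,
        "tau_s": tau,
        "sigma_free_S_m": sigma_free,
        "sigma_complex_S_m": sigma_complex,
        "sigma_mode": config.sigma_mode,
        "regime": regime,
        "lambda_max_free_nm": lam_free,
        "lambda_max_complex_nm": lam_cplx,
        "delta_lambda_nm": shift.delta_lambda,
        "shift_direction": shift.direction,
    }
    path = outdir / "summary.json"
    path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    written.append(path)
    return summary
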