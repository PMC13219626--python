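# fullersense

Post-quantum-chemistry analysis for evaluating C60-based nanostructures
as drug sensors or adsorbents.  Given per-system quantum-chemistry
summaries (frontier orbital energies, total energies, dipole and
polarizability tensors, excitation lists, geometries), the package
computes everything a sensing study derives from them, for a worked
case: pristine C60 and its Al-/Zn-doped cages (AlC59, ZnC59) probed
against the dissociative drug eticyclidine (PCE).

It is aimed at computational chemists who already have DFT/TD-DFT
outputs and want the downstream analysis — descriptors, figures of
merit, spectra, density topology — reproducible, tested and scriptable.

## What it computes

**Conceptual-DFT reactivity** — from E_HOMO, E_LUMO (eV): gap
HLG = |E_HOMO − E_LUMO|, hardness η = HLG/2, softness S = 1/(2η),
potential µ = (E_HOMO + E_LUMO)/2, charge-transfer capacity
ΔN_max = −µ/η, and the sensor-vs-complex transfer descriptor
ECT = ΔN_max(sensor) − ΔN_max(complex).

**Sensing figures of merit** — cohesive energy (E_total − ΣE_atom)/n;
adsorption energy E_ads = E_complex − (E_sensor + E_drug); Arrhenius
recovery time τ = ν₀⁻¹ exp(−E_ads/RT); Richardson-type conductivity
σ = A·T^{3/2}·exp(−HLG/2k) (two thermal-energy conventions, see
`docs/methods.md`); and a reversible-sensor / adsorbent classifier.

**Spectra** — Gaussian-broadened DOS from orbital energies and UV-Vis
curves from oscillator-strength-weighted excitations, with λ_max
extraction and red/blue-shift reports.

**Model-density topology** — analytic promolecular densities with exact
gradients/Hessians supporting NCI/RDG (sign(λ₂)ρ classification), ELF,
LOL, Newton-search bond critical points with signature labeling, and
Abramov/virial energy densities G, V, H = G + V.  Results export to
Gaussian cube files.

**Synthetic studies** — seeded generators for sensor/complex/drug
bundle triples with controllable gap, potential, adsorption energy,
excitation lines and dimer separation, recoverable end-to-end.

## Worked example

```python
import fullersense as fs

fx = fs.paper_fixtures()          # six study systems + reference tables
b = fx["bundles"]

d = fs.reactivity_descriptors(b["C60"].orbitals)
print(d.hlg, d.hardness, d.potential, d.softness, d.dnmax)
# 1.67 0.835 -4.415 0.5988023952095809 5.287425149700599

summary = fs.run_report(b["C60"], b["C60@PCE"], b["PCE"],
                        fs.StudyConfig(), "report")
print(summary["e_ads_kcal_mol"], summary["regime"])
# -11.15 reversible-sensor
```

The pristine cage has a 1.67 eV gap, moderate hardness (0.835 eV) and a
low charge-transfer capacity (5.29) — a stable, weakly reactive sensor
surface.  The report for the C60/PCE pair writes `report/sensing.csv`:

```
structure,Eads_kcal_mol,tau_s,sigma_1e9_S_m
C60,,,2.20
C60@PCE,-11.15,1.50e-04,2.43
```

The −11.15 kcal/mol adsorption energy gives a sub-millisecond recovery
time (τ ≈ 1.5×10⁻⁴ s at 298 K), so the pair is classified
`reversible-sensor`: binding strong enough to detect, weak enough to
desorb and reuse.  The conductivity rise from 2.20 to 2.43 (×10⁹, in
the table's compatibility convention) is the detection signal.  The
same pipeline run on the Al-doped cage (E_ads = −54.08 kcal/mol,
τ ≈ 4.6×10²⁷ s) lands in the `adsorbent` regime — good for drug
capture, useless for repeated sensing.

The same operations are available from the shell:

```
fullersense descriptors sensor.json complex.json
fullersense sensing --eads -11.15 --hlg 1.18 --sigma-mode paper_compat
fullersense spectra complex.json --kind uvvis --axis nm --out uv.csv
fullersense topology dimer.xyz --bcp
fullersense simulate --n 5 --seed 1 --out scenarios/
fullersense report sensor.json complex.json drug.json --out report/
```

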