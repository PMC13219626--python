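# Methods

`fullersense` post-processes quantum-chemistry summaries ("result
bundles") for a sensor/analyte study: a fullerene-derived nanostructure
(pristine C60 or a metal-substituted cage) probed against an adsorbed
drug molecule.  Nothing in the package runs electronic-structure theory;
every analysis starts from orbital energies, total energies, tensors,
excitation lists or geometries that an upstream DFT/TD-DFT code produced.

## Reactivity descriptors

From the frontier orbital energies (eV) the global conceptual-DFT
descriptors are

- gap `HLG = |E_HOMO − E_LUMO|`,
- hardness `η = (E_LUMO − E_HOMO)/2` (eV),
- potential `µ = (E_HOMO + E_LUMO)/2` (eV),
- softness `S = 1/(2η)` (eV⁻¹),
- maximum charge-transfer capacity `ΔN_max = −µ/η` (dimensionless),

and for a sensor/complex pair the electrophilicity-based charge transfer
`ECT = ΔN_max(sensor) − ΔN_max(complex)`; negative values read as charge
flowing from the analyte into the sensor.  The HOMO is the highest
orbital with occupation > 0.5 and the LUMO the lowest with ≤ 0.5;
degenerate ties break by index.  A degenerate frontier (η = 0) leaves S
and ΔN_max `None` rather than infinite.  All values are unrounded; the
report layer applies 2-decimal display rounding, because the reference
tables mix rounding and truncation (e.g. a printed hardness of 0.83
against a computed 0.835) — descriptor comparisons therefore use an
absolute band of 0.015.

## Sensing figures of merit

With molar energies in kcal/mol:

- cohesive energy `E_coh = (E_total − ΣE_atom)/n` per atom;
- adsorption energy `E_ads = E_complex − (E_sensor + E_drug)`
  (negative = favorable);
- recovery time `τ = ν₀⁻¹ exp(−E_ads/RT)` with ν₀ = 10¹² s⁻¹ and
  `RT` in kcal/mol (0.5922 at 298 K) since `E_ads` is molar;
- conductivity proxy `σ = A T^{3/2} exp(−HLG/2k)` with the Richardson
  constant A = 6×10⁵ A·m⁻²·K⁻².

The conductivity exponent ships in two conventions.  `physical` uses
`k = k_B T` in eV, dimensionally matched to the gap; a 1.67 eV gap then
gives σ ≈ 2×10⁻⁵ S/m at 298 K.  `paper_compat` pairs the bare eV numeral
of the gap with `k = RT` in kJ/mol (2.4777 at 298 K); this unit mix is
not dimensionally consistent, but it is the only reading that reproduces
the reference conductivity table (~2.2–2.9 ×10⁹ S/m), established by
solving `ln(σ_i/σ_j)` against gap differences across the table's rows
(consistent k ≈ 2.46–2.48).  Both modes are exposed and labelled; the
compat mode exists for reproducing the published table, not as an
endorsement of the convention.

A recovery-time classifier labels pairs `reversible-sensor` (τ ≤ 1 s),
`adsorbent` (τ ≥ 10⁶ s) or `intermediate`; thresholds are configurable.
The reference values place the pristine-cage complex (τ ~ 10⁻⁴ s) firmly
in the reusable-sensor regime and the Al-doped complex (τ ~ 10²⁷ s) in
the capture regime.  τ values beyond float range saturate to infinity.

## Spectrum synthesis

DOS curves broaden each orbital energy with a unit-area Gaussian (peak
height `2√(ln2/π)/w` for FWHM `w`); UV-Vis curves weight each Gaussian
by the oscillator strength.  Defaults: FWHM 0.3 eV (DOS) and 0.333 eV
(UV-Vis) — the common post-processing defaults, since the upstream
plotting widths are not stated — on grids −15…0 eV step 0.01 (DOS) and
0.5…6.5 eV step 0.005 (UV-Vis).  Gap readings off a DOS plot use the
filled/virtual split so each frontier peak is a single Gaussian and the
peak-to-peak distance equals the orbital gap exactly on the grid.
`lambda_max` ties break toward longer wavelength.  Wavelength-axis views
resample the energy-domain curve through `λ = hc/E` without the `dE/dλ`
Jacobian, matching common plotting practice.  The reference absorption
table's pristine-C60 row pairs 360 nm with 2.78 eV, which is not
hc-consistent; it is stored verbatim and excluded from conversion tests.

## Model-density topology

The real-space analyses run on promolecular model densities: each atom
contributes spherical shells `c_i exp(−r/ζ_i)` and the molecule is their
unrelaxed superposition.  The built-in shell table is authored from
Slater screening rules: per shell, exponent ξ from the 1930 rules, decay
`ζ = 1/(2ξ)` bohr, amplitude `c = N_shell/(8πζ³)` so each shell
integrates to its electron population (H, C, N, O, Al, Zn).  These are
deliberately simple model atoms — adequate for the qualitative NCI/ELF
/LOL/QTAIM machinery, not for quantitative densities.

Gradients and Hessians are analytic (no numerical differentiation), so
critical-point searches and the derived indicators are exact up to float
arithmetic; a finite-difference oracle in the tests confirms agreement
to 1e−6.  Implemented indicators:

- reduced density gradient `s = |∇ρ| / (2(3π²)^{1/3} ρ^{4/3})` and the
  NCI signed density `sign(λ₂)ρ` with class thresholds ±0.01 a.u.;
- ELF (Becke–Edgecombe) `1/(1+(D/D_h)²)` and LOL (Schmider–Becke)
  `t/(1+t)`, `t = τ_TF/τ`.  On promolecular grids the kinetic density is
  Thomas–Fermi + Weizsäcker ("approximate ELF/LOL"): with that τ the
  Pauli term reduces to the TF value and grid ELF is 0.5 everywhere,
  which is the correct degenerate limit of the model — orbital-based τ
  is out of scope.  Point-wise `elf()`/`lol()` accept any caller τ;
- Abramov kinetic density `G = (3/10)(3π²)^{2/3}ρ^{5/3} + |∇ρ|²/(72ρ)
  + ∇²ρ/6`, local-virial `V = ∇²ρ/4 − 2G`, total `H = G + V`.  The
  reference BCP table's "VIR" column equals G + V in every row and is
  implemented as the total energy density; its printed G values come
  from wavefunction-based evaluation and are *not* reproducible from
  printed ρ and ∇²ρ via Abramov, so they are fixtures only.

BCP search: Newton iterations on ∇ρ = 0 seeded at midpoints of atom
pairs within 4 Å, steps > 0.5 bohr damped by half, convergence at
|∇ρ| < 1e−8 a.u., duplicates merged within 1e−3 bohr, and only
signature (3,−1) saddles kept.  Coordinates enter in Å and convert once
to bohr (1.8897259886); all field outputs are atomic units.

## Synthetic study sets

`ScenarioSpec`/`make_pair` build sensor/complex/drug bundle triples
whose knobs — frontier gap, chemical potential, adsorption energy,
excitation lines, dimer separation, orbital jitter — are exactly
recoverable by the pipeline when `noise_sd = 0`, because the frontier is
constructed as `µ ± gap/2` and the totals satisfy the adsorption-energy
identity by inversion.  Filler orbitals sit ≥ 1 eV away from the
frontier so Gaussian jitter (default 0, tests use 0.05 eV) cannot
reorder it; jittered gaps are unbiased.  Geometries are two-center C–N
dimers, not cages: the topology analyses only need two-center models
with closed-form critical points.  `scenario_grid` alternates
physisorption (E_ads ∈ [−15, −5]) and chemisorption ([−60, −30])
windows with gaps 0.3–2.0 eV, everything derived from one integer seed
through a local generator.  What the generator does *not* emulate:
realistic fullerene orbital manifolds, TD-DFT line shapes, solvent
effects — passing tests demonstrate pipeline correctness and parameter
recovery, not predictive accuracy for real sensors.

## Numerical/reporting choices

- Constants are CODATA 2018, pinned in `constants.py`.
- Hartree→kcal/mol 627.5094740631; `hc` = 1239.84193 eV·nm.
- Fixture bundles reconstruct what the reference tables do not print:
  dipole vectors along z with the printed magnitude, isotropic
  polarizability with the printed mean, and arbitrary fragment total
  energies anchored so adsorption-energy differences are exact.  The
  verbatim printed cells live in the keyed tables.
- Report CSVs are byte-deterministic for identical inputs; raw
  unrounded values always accompany them in `summary.json`.
- Problem sizes in the tests (grids of a few thousand points, 200
  jitter replicates) are chosen so the whole suite runs in seconds while
  still exercising every code path at meaningful resolution.

## Known limitations

- The promolecular density has cusps at nuclei; evaluation nudges
  on-nucleus points by 1e−10 bohr and grid extrema are reported at the
  nearest grid point.
- No basin integration, ring/cage critical points, or interaction-energy
  correlations from ρ_BCP.
- The compat conductivity convention and the sign of the reference ECT
  value for the Al-doped complex (printed −0.26 vs +0.27 from the
  printed ΔN_max difference) are reproduced/recorded as found, not
  reinterpreted.
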