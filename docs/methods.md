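# Methods

## Scope and data model

The package analyses particle trajectories in orthorhombic periodic boxes
(coordinates in Å, frame times in fs) and per-temperature thermodynamic
tables (solvation free energy in kJ/mol, solvent mass density in g/cm³).
Running the underlying molecular dynamics is out of scope: solvation free
energies are consumed as inputs, and trajectories are either read from disk
(extended XYZ, LAMMPS text dump) or produced by the synthetic generators
below. Unit conversions to SI happen only inside the analysis functions,
never in the data types.

The XYZ dialect stores `box=Lx,Ly,Lz t=<fs> wrapped=<0|1>` in each frame's
comment line because plain XYZ has no box record and the RDF needs one;
coordinates are written with 6 decimals, and the reader/writer pair is the
identity at that precision. The dump reader accepts the
`ITEM: ATOMS id type x y z` dialect only, re-orders atoms by id so particle
identity is stable across frames, and rejects triclinic `BOX BOUNDS`
loudly — supporting only the orthorhombic cells the analyses assume.

## Radial distribution function

For species selections a and b, minimum-image pair distances are binned
(default bin width 0.05 Å, configurable) and normalised per frame by

g(bin) = m·C(bin) / (N_a · ρ_y · V_shell),

with C the unordered pair count, m = 2 for a like pair and 1 otherwise,
V_shell = (4/3)π[(r+dr)³ − r³] the **exact** shell volume rather than its
differential 4πr²dr approximation, and ρ_y = N_b/V (or (N_a−1)/V for a like
pair). These conventions make two identities exact at any bin width: the
ideal-gas limit g ≡ 1, and number conservation
ρ_y·Σ g·V_shell = mean partner count within r_max. `r_max` is capped at
half the smallest box edge (minimum-image validity); unwrapped inputs are
wrapped before binning.

Peak calls return the first local maximum past a minimum position whose
prominence exceeds 0.05 — a floor that suppresses single-count Poisson
spikes in small shells at the default synthetic sampling. Peak positions
are reported as bin centres: binned estimates cannot localise a peak below
the bin width, so tests pin the bin containing the truth, not a float. The
trend analysis tabulates first-peak position/intensity against temperature
and issues a strict-monotonicity verdict (increasing/decreasing/neither);
ties are "neither" by design since noise-level differences should not be
read as a trend.

## Mean square displacement and diffusion

MSD(k·Δt) averages |r(t₀+kΔt) − r(t₀)|² over all selected particles and all
time origins t₀ on a stride grid (default stride 1, overlapping windows).
With stride 1 the all-origins average is computed by the standard FFT
autocorrelation decomposition, which is algebraically identical to the
direct double loop (a brute-force comparison is part of the test suite) at
O(n log n) per particle. Wrapped trajectories are rejected rather than
silently unwrapped: without image flags, unwrapping is ambiguous whenever a
particle may cross half a box edge between frames.

The Einstein fit is ordinary least squares of MSD on lag time over lags in
a fractional window of the maximum lag, default 10–50%: short lags are
dominated by the intercept c, long lags average few origins and are noisy.
D = slope/6 with the slope's standard error propagated. Lags are converted
fs→s and displacements Å→m before fitting, so D is in m²/s directly.

## Solubility chain

y₂ = P₂ˢᵃᵗ·exp[(ϑˢ/RT)(P−P₂ˢᵃᵗ)] / (ρₙ·k_B·T·exp(ΔG_solv/RT)).

Design choices, where the inputs left the design open:

* **ρ is a number density.** ρ·k_B·T must carry pressure units for y₂ to be
  dimensionless, so the solvent density is converted from the mass density
  given at the interface (g/cm³ → m⁻³ via the molar mass).
* **Molar throughout.** ΔG_solv arrives in kJ/mol and is paired with R;
  this is algebraically identical to a per-particle β = 1/k_BT treatment.
* **Sublimation pressure** uses the integrated Clausius–Clapeyron form
  P(T) = P_ref·exp[(ΔH_sub/R)(1/T_ref − 1/T)] with constant ΔH_sub. For
  curcumin the reference point is 3.08×10⁻¹² mmHg at 298.15 K (133.322
  Pa/mmHg fixed), but no published sublimation enthalpy is available, so
  ΔH_sub is a **required parameter with no default**; the analysis driver
  uses a nominal 115 kJ/mol and flags the absolute y₂ values as conditional
  on it. The quantity labelled a "molar mass" of 3.961×10⁻⁴ m³/mol in the
  source data is dimensionally a molar volume and is treated as ϑˢ.
* **Out-of-range y₂ warns, not raises**, so parameter sweeps can traverse
  unphysical corners without crashing.
* **AARD** puts the reference (literature) densities in the denominator and
  uses only temperatures with both values — four of the five study
  temperatures, the hottest having no literature density. Recomputing on
  those four rows gives 6.50%, against a reported rounding of 6.45%; the
  0.05-point gap is consistent with unstated rounding conventions and the
  validation test tolerates 0.1 percentage point.

## Synthetic generators and what they do (not) show

All generators take an explicit integer seed (one RNG stream per call) and
are deterministic given it.

* **Brownian walks** draw independent Gaussian steps with per-axis variance
  exactly 2DΔt and are left **unwrapped** (the MSD precondition), while the
  configuration generators below emit **wrapped** coordinates (the RDF
  precondition). Defaults for the recovery study follow the study
  conditions: 500 particles, 1 ps frame spacing, 5000 frames, with the five
  literature diffusion coefficients (4.4–11.2 ×10⁻⁹ m²/s) as ground truths.
* **Ideal gas**: i.i.d. uniform positions per frame; the g ≡ 1 null.
* **Dimer gas**: one member uniform, the partner at a fixed separation in a
  random direction. Dimer centres are placed independently, so chance
  overlaps add a thin uniform background to the cross histogram; the global
  maximum, not every local bump, is the fixture's guarantee.
* **Lennard-Jones liquid**: Metropolis Monte Carlo in reduced units (σ=ε=1,
  cutoff 2.5σ, trial displacement tuned for ~40% acceptance at liquid
  density), returning 10 configurations spaced 10 sweeps apart after the
  requested equilibration. It supplies realistically structured g(r) —
  first peak near r=σ, intensity falling with temperature — and makes no
  claim to model water.
* **Thermo truth**: builds a table from linear ΔG(T) and ρ(T) models and
  records the y₂ curve obtained by direct forward evaluation, so the
  table→solubility pipeline must return it exactly (a plumbing round trip,
  not an independent physics check).

Passing on these fixtures establishes estimator correctness — binning,
normalisation, origin averaging, unit handling — under known ground truth.
It does not certify behaviour on real MD data, which adds correlated
motion, finite-size and force-field effects, and (for the original study's
absolute RDF intensities and solubilities) inputs that were never
published: those quantities are validated here only at the level of the
formulas and trends.

## Numerical choices and problem sizes

Minimum-image displacement maps each component into (−L/2, L/2]; the exact
boundary is assigned to the positive side. RDF pair counting is vectorised
O(N²) per frame, exact-match tested against an explicit double loop.
The recovery study uses 500×5000-frame trajectories (≈7.5M steps per
condition), where the 10–50% window puts the fitted D within ~2–5% of
truth; statistical checks in the tests use fixed seeds and tolerance bands
derived from the corresponding counting statistics (chi-square for step
variances, Poisson for bin counts). Pipeline runs write CSV/JSON through a
temp-file/atomic-rename so a failing stage cannot leave a half-written
report, and reports embed the seed and full config echo for provenance.

## Known limitations

Orthorhombic boxes only; no velocity/force records; no Green–Kubo route to
D; no activity-coefficient or pressure-dependent-ΔG corrections; the
Clausius–Clapeyron step assumes a temperature-independent sublimation
enthalpy across a 155 K span, which is the dominant systematic in absolute
y₂ values.
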