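# swextract

Post-molecular-dynamics analysis chain for the extraction of a sparingly
soluble solute — curcumin, the main bioactive of *Curcuma longa* — into
subcritical water (liquid water between ~90 °C and the critical point kept
under pressure). As temperature rises, water's dielectric constant falls and
it behaves increasingly like an organic solvent, so extraction efficiency is
expected to climb. The package quantifies that picture along three axes,
with synthetic trajectory generators of known ground truth standing in for
force-field MD runs:

* **Structure** — radial distribution functions between species selections
  in a periodic orthorhombic box,

  g(r) = N_y(r, r+dr) / (ρ_y · 4πr²dr),

  with exact-shell-volume normalisation, first-peak extraction (position and
  intensity, a hydrogen-bond-strength proxy for O–H selections) and
  intensity-vs-temperature trend verdicts.
* **Transport** — time-origin-averaged mean square displacement and the
  Einstein relation MSD = 6Dt + c, fitted by ordinary least squares over a
  10–50% lag window to give the diffusion coefficient D in m²/s.
* **Thermodynamics** — mole-fraction solubility from solvation free energy,

  y₂ = P₂ˢᵃᵗ · exp[βϑˢ(P − P₂ˢᵃᵗ)] / (ρ · k_B · T · exp(βΔG_solv)),

  with P₂ˢᵃᵗ from an integrated Clausius–Clapeyron extrapolation,
  ρ the solvent *number* density (so ρk_BT is a pressure), the Poynting
  exponential correcting to system pressure P, and AARD
  (100/n · Σ|sim−ref|/|ref|) as the density-validation statistic.

It is aimed at molecular-simulation practitioners who want these estimators
as tested, composable functions rather than one-off scripts.

## Layout

* `src/swextract/` — the library: trajectory/thermo types and I/O
  (extended XYZ, a LAMMPS text-dump dialect, CSV tables), synthetic
  generators (`synth`), RDF (`rdf`), MSD/diffusion (`msd`), the solubility
  chain (`thermo`), literature reference values (`reference`), and a
  pipeline + `swextract` CLI (`pipeline`, `cli` — subcommands `simulate`,
  `rdf`, `msd`, `solubility`, `report`).
* `analysis/01_simulate.py … 04_solubility.py` — numbered drivers that run
  each stage of the study and write tables under `results/`.
* `scripts/acceptance.py` — recomputes the headline numbers from scratch.

## Worked example

Recovering diffusion coefficients from Brownian trajectories generated at
the five literature ground truths (`python analysis/02_diffusion.py`):

```
T= 363.15 K  D_true= 4.40  D_fit= 4.614  err=4.86%
T= 393.15 K  D_true= 8.10  D_fit= 8.219  err=1.47%
T= 413.15 K  D_true= 8.50  D_fit= 8.685  err=2.18%
T= 423.15 K  D_true= 9.60  D_fit= 9.800  err=2.09%
T= 453.15 K  D_true=11.20  D_fit=11.184  err=0.15%
temperature ranking preserved: True
```

Each line is one synthetic study condition: a 500-particle random walk with
per-step variance 2DΔt is analysed blind by the MSD/Einstein estimator, and
the fitted D (×10⁹ m²/s) lands within 5% of the value used to generate it,
preserving the rise of D with temperature. The solubility driver
(`python analysis/04_solubility.py`) prints

```
density AARD vs literature: 6.50% (reported rounding: 6.45%)
y2 monotonicity across temperature: increasing
generator round-trip max |Δy2|: 0 (trend: increasing)
```

i.e. the simulated water densities deviate from literature values by 6.5% on
average over the four temperatures with both values, the mole-fraction
solubility rises with temperature across 363–453 K at 2 MPa, and running the
solubility chain on a table constructed from a known y₂ curve returns that
curve exactly.

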