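#!/usr/bin/env python
"""Generate the synthetic study inputs and write inspectable samples.

Produces small extended-XYZ samples of each generator (Brownian walk,
ideal gas, dimer gas, LJ liquid) plus the thermo-truth table used by the
solubility round trip, under results/inputs/.  The full-size trajectories
used by the later stages are regenerated in those scripts from the same
seeds rather than stored.
"""

from pathlib import Path

import swextract as sw
from swextract import reference
from swextract.io import write_thermo_table
from swextract.thermo import MMHG_TO_PA

SEED = 20260930
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    brownian = sw.gen_brownian(
        sw.BrownianSpec(
            n_particles=10,
            diffusion_coefficient=reference.DIFFUSION_M2_S[363.15],
            timestep=1000.0,
            n_frames=100,
            box=sw.PeriodicBox.cubic(100.0),
            seed=SEED,
        )
    )
    sw.write_xyz(brownian, OUT / "brownian_sample.xyz")

    gas = sw.gen_ideal_gas(200, sw.PeriodicBox.cubic(30.0), 5, seed=SEED + 1)
    sw.write_xyz(gas, OUT / "ideal_gas_sample.xyz")

    dimers = sw.gen_pair_gas(50, 1.75, sw.PeriodicBox.cubic(60.0), seed=SEED + 2)
    sw.write_xyz(dimers, OUT / "dimer_gas_sample.xyz")

    lj = sw.gen_lj_fluid(128, 0.8, 0.9, 500, seed=SEED + 3, n_frames=3)
    sw.write_xyz(lj, OUT / "lj_liquid_sample.xyz")
    print(f"LJ equilibration acceptance rate: {lj.acceptance_rate:.2f}")

    solute = sw.SoluteParams(
        molar_volume=reference.CURCUMIN_MOLAR_VOLUME_M3_MOL,
        reference_vapor_pressure=reference.CURCUMIN_VAPOR_PRESSURE_MMHG * MMHG_TO_PA,
        reference_temperature=reference.CURCUMIN_REFERENCE_TEMPERATURE_K,
        sublimation_enthalpy=115.0,
    )
    truth = sw.gen_thermo_truth(
        list(reference.TEMPERATURES_K),
        (20.0, -0.15),
        (1.25, -0.001),
        solute,
        reference.SYSTEM_PRESSURE_PA,
    )
    write_thermo_table(truth.table, OUT / "thermo_truth.csv")
    print(f"wrote samples for 4 generators and a {len(truth.table)}-row thermo table to {OUT}")


if __name__ == "__main__":
    main()
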