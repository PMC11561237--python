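"""Literature reference data for the curcumin / subcritical-water system.

These published values are the fixed inputs and ground truths the analysis
chain consumes: per-temperature solvation free energies and water densities,
reported diffusion coefficients used as Brownian-generator ground truths,
first-shell RDF peak data for pure water and for the curcumin hydroxyl
oxygen–water hydrogen contact, and the curcumin solid-phase reference point
(molar volume, vapor pressure at 25 °C).

All studies were run at a system pressure of 2 MPa over 363.15–453.15 K.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SoluteParams, ThermoTable
from .thermo import MMHG_TO_PA

#: system pressure, Pa
SYSTEM_PRESSURE_PA = 2.0e6

#: study temperatures, K
TEMPERATURES_K = (363.15, 393.15, 413.15, 423.15, 453.15)

#: solvation free energy of curcumin in subcritical water, kJ/mol, per temperature
SOLVATION_FREE_ENERGY_KJ_MOL = {
    363.15: -35.848,
    393.15: -35.246,
    413.15: -35.600,
    423.15: -35.400,
    453.15: -35.590,
}

#: water mass density, g/cm³: MD-simulated vs calculated (literature) values;
#: no literature value is available at 453.15 K
WATER_DENSITY_G_CM3 = pd.DataFrame(
    {
        "temperature_K": [363.15, 393.15, 413.15, 423.15, 453.15],
        "simulated": [0.902, 0.896, 0.874, 0.855, 0.781],
        "calculated": [0.962, 0.946, 0.935, 0.929, np.nan],
    }
)

#: reported AARD between simulated and calculated water densities, percent
REPORTED_DENSITY_AARD_PCT = 6.45

#: curcumin diffusion coefficients in subcritical water, m²/s, per temperature
DIFFUSION_M2_S = {
    363.15: 4.4e-9,
    393.15: 8.1e-9,
    413.15: 8.5e-9,
    423.15: 9.6e-9,
    453.15: 11.2e-9,
}

#: first-shell peak positions in pure water, Å
WATER_FIRST_PEAK_POSITIONS_A = {"O-H": 1.75, "H-H": 2.25, "O-O": 2.75}

#: O(water)–H(water) first-peak intensity versus temperature (falls as the
#: water hydrogen-bond network weakens)
WATER_OH_PEAK_INTENSITY = {
    363.15: 1.10,
    393.15: 1.08,
    413.15: 1.07,
    423.15: 1.01,
    453.15: 0.90,
}

#: O(OH curcumin)–H(water) first-peak intensity at 1.75 Å versus temperature
#: (rises as extraction strengthens)
CURCUMIN_OH_WATER_PEAK_INTENSITY = {
    363.15: 1.03,
    393.15: 1.34,
    413.15: 1.42,
    423.15: 1.45,
    453.15: 1.56,
}

#: curcumin molar volume ϑ^s, m³/mol
CURCUMIN_MOLAR_VOLUME_M3_MOL = 3.961e-4
#: curcumin vapor pressure at 25 °C, mmHg
CURCUMIN_VAPOR_PRESSURE_MMHG = 3.08e-12
CURCUMIN_REFERENCE_TEMPERATURE_K = 298.15


def curcumin_params(sublimation_enthalpy_kJ_mol: float | None = None) -> SoluteParams:
    """Curcumin solid-phase reference parameters.

    The sublimation enthalpy is not available in the literature set used here
    and must be supplied by the caller to enable the Clausius–Clapeyron step.
    """
    return SoluteParams(
        molar_volume=CURCUMIN_MOLAR_VOLUME_M3_MOL,
        reference_vapor_pressure=CURCUMIN_VAPOR_PRESSURE_MMHG * MMHG_TO_PA,
        reference_temperature=CURCUMIN_REFERENCE_TEMPERATURE_K,
        sublimation_enthalpy=sublimation_enthalpy_kJ_mol,
        solvent_molar_mass=18.015,
    )


def thermo_table() -> ThermoTable:
    """ΔG_solv and simulated water density per study temperature as a ThermoTable."""
    temps = list(TEMPERATURES_K)
    return ThermoTable(
        pd.DataFrame(
            {
                "temperature_K": temps,
                "dG_solv_kJ_mol": [SOLVATION_FREE_ENERGY_KJ_MOL[t] for t in temps],
                "density_g_cm3": WATER_DENSITY_G_CM3["simulated"].tolist(),
            }
        )
    )


def density_validation_aard() -> float:
    """AARD (%) of simulated vs calculated water densities.

    Only temperatures with both values enter (453.15 K has no calculated
    density); the calculated value is the denominator.
    """
    from .thermo import aard

    both = WATER_DENSITY_G_CM3.dropna()
    return aard(both["simulated"].to_numpy(), both["calculated"].to_numpy())
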