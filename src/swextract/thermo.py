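"""Mole-fraction solubility from solvation free energy.

The chain implemented here converts a per-temperature table of solvation free
energies ΔG_solv and solvent densities into mole-fraction solubilities y₂ of a
sparingly-soluble solid solute:

    y₂ = P₂ˢᵃᵗ · exp[(ϑˢ/RT)(P − P₂ˢᵃᵗ)] / (ρₙ · k_B · T · exp(ΔG_solv/RT))

where P₂ˢᵃᵗ is the solute sublimation pressure (Clausius–Clapeyron
extrapolation from a reference point with constant sublimation enthalpy),
exp[(ϑˢ/RT)(P−P₂ˢᵃᵗ)] the Poynting correction for the system pressure P, and
ρₙ the solvent **number** density, so that ρₙ·k_B·T carries pressure units.
ΔG_solv is molar (kJ/mol) and is paired with R; the per-particle β=1/k_BT form
is algebraically identical.

Model validation uses the absolute average relative deviation
AARD = (100/n)·Σ|sim−ref|/|ref|, the standard statistic for comparing
simulated against literature solvent densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants

from .core import SoluteParams, SwextractError, ThermoTable, ValidationError

R = constants.R  # J/(mol K)
K_B = constants.k  # J/K
N_A = constants.Avogadro  # 1/mol
#: Pa per mmHg, fixed conversion
MMHG_TO_PA = 133.322


class ConfigurationError(SwextractError):
    """A required physical parameter is missing."""


class OutOfRangeWarning(UserWarning):
    """A computed mole fraction fell outside (0, 1)."""


def sublimation_pressure(temperature: float, solute: SoluteParams) -> float:
    """Sublimation pressure by integrated Clausius–Clapeyron at constant ΔH_sub.

        P(T) = P_ref · exp[(ΔH_sub/R)(1/T_ref − 1/T)]

    ΔH_sub has no literature default for most solutes and must be supplied on
    the SoluteParams; a missing value raises ConfigurationError.
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    if solute.sublimation_enthalpy is None:
        raise ConfigurationError(
            "sublimation enthalpy is required for the Clausius-Clapeyron "
            "extrapolation but was not provided; set "
            "SoluteParams.sublimation_enthalpy (kJ/mol)"
        )
    dh = solute.sublimation_enthalpy * 1e3  # kJ/mol -> J/mol
    exponent = (dh / R) * (1.0 / solute.reference_temperature - 1.0 / temperature)
    return solute.reference_vapor_pressure * np.exp(exponent)


def number_density(mass_density: float, molar_mass: float) -> float:
    """Convert a mass density (g/cm³) and molar mass (g/mol) to number density (m⁻³)."""
    if mass_density <= 0 or molar_mass <= 0:
        raise ValidationError("mass density and molar mass must be positive")
    rho_si = mass_density * 1e3  # g/cm3 -> kg/m3
    m_si = molar_mass * 1e-3  # g/mol -> kg/mol
    return rho_si / m_si * N_A


def poynting_factor(
    temperature: float, pressure: float, sat_pressure: float, molar_volume: float
) -> float:
    """exp[(ϑˢ/RT)(P − P₂ˢᵃᵗ)]; the exponent may be of either sign."""
    return float(np.exp(molar_volume * (pressure - sat_pressure) / (R * temperature)))


def mole_fraction_solubility(
    temperature: float,
    pressure: float,
    dG_solv: float,
    solvent_mass_density: float,
    solute: SoluteParams,
    sat_pressure: float | None = None,
) -> float:
    """Evaluate the solubility relation in SI units.

    Parameters
    ----------
    temperature : K
    pressure : Pa, system pressure P
    dG_solv : kJ/mol, solvation free energy (negative = favourable)
    solvent_mass_density : g/cm³
    solute
        Supplies ϑˢ, the vapor-pressure reference point, ΔH_sub and the
        solvent molar mass.
    sat_pressure
        Override for P₂ˢᵃᵗ in Pa; by default it is extrapolated with
        :func:`sublimation_pressure`.

    A result outside (0, 1) emits :class:`OutOfRangeWarning` but is returned,
    so parameter sweeps do not abort.
    """
    if sat_pressure is None:
        sat_pressure = sublimation_pressure(temperature, solute)
    rho_n = number_density(solvent_mass_density, solute.solvent_molar_mass)
    poynting = poynting_factor(temperature, pressure, sat_pressure, solute.molar_volume)
    solvation = np.exp(dG_solv * 1e3 / (R * temperature))
    y2 = sat_pressure * poynting / (rho_n * K_B * temperature * solvation)
    if not (0.0 < y2 < 1.0):
        warnings.warn(
            f"mole fraction {y2:.3g} at T={temperature} K lies outside (0, 1)",
            OutOfRangeWarning,
            stacklevel=2,
        )
    return float(y2)


def aard(simulated, reference) -> float:
    """Absolute average relative deviation in percent.

    100/n · Σᵢ |simᵢ − refᵢ| / |refᵢ|, with the reference values in the
    denominator.
    """
    sim = np.asarray(simulated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if sim.shape != ref.shape or sim.ndim != 1:
        raise ValidationError(
            f"simulated and reference must be equal-length vectors, got "
            f"{sim.shape} vs {ref.shape}"
        )
    if sim.size == 0:
        raise ValidationError("aard needs at least one value pair")
    if np.any(ref == 0):
        raise ValidationError("reference values must be nonzero")
    return float(100.0 * np.mean(np.abs(sim - ref) / np.abs(ref)))


@dataclass
class SolubilityResult:
    """Per-temperature solubility chain output.

    ``rows`` has columns temperature_K, sublimation_pressure_Pa,
    poynting_factor, number_density_m3, mole_fraction; ``monotonicity`` is
    "increasing" / "decreasing" / "neither" / "undefined" on y₂ versus T.
    """

    rows: pd.DataFrame
    system_pressure: float
    monotonicity: str

    COLUMNS = (
        "temperature_K",
        "sublimation_pressure_Pa",
        "poynting_factor",
        "number_density_m3",
        "mole_fraction",
    )


def _monotonicity(values: np.ndarray) -> str:
    if len(values) < 2:
        return "undefined"
    diffs = np.diff(values)
    if np.all(diffs > 0):
        return "increasing"
    if np.all(diffs < 0):
        return "decreasing"
    return "neither"


def solubility_table(
    table: ThermoTable, solute: SoluteParams, pressure: float
) -> SolubilityResult:
    """Run the full solubility chain over every row of a thermo table."""
    records = []
    for _, row in table.data.iterrows():
        t = float(row["temperature_K"])
        psat = sublimation_pressure(t, solute)
        rho_n = number_density(float(row["density_g_cm3"]), solute.solvent_molar_mass)
        poynting = poynting_factor(t, pressure, psat, solute.molar_volume)
        y2 = mole_fraction_solubility(
            t,
            pressure,
            float(row["dG_solv_kJ_mol"]),
            float(row["density_g_cm3"]),
            solute,
            sat_pressure=psat,
        )
        records.append(
            {
                "temperature_K": t,
                "sublimation_pressure_Pa": psat,
                "poynting_factor": poynting,
                "number_density_m3": rho_n,
                "mole_fraction": y2,
            }
        )
    rows = pd.DataFrame.from_records(records, columns=list(SolubilityResult.COLUMNS))
    verdict = _monotonicity(rows["mole_fraction"].to_numpy())
    return SolubilityResult(rows=rows, system_pressure=pressure, monotonicity=verdict)
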