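"""End-to-end synthetic study driver: simulate → msd/rdf → solubility → report.

A single configuration (YAML file or dict) describes the synthetic study:
Brownian trajectories at per-temperature ground-truth diffusion coefficients,
RDF fixtures (ideal gas null, dimer gases at set separations), and a thermo
table built from a prescribed solubility curve.  ``run_pipeline`` executes the
requested stages in dependency order, writes one CSV per stage plus a JSON
report with a provenance block (config echo, seed, package version), and is
byte-deterministic under a fixed seed.  All file writes go through a
temp-file/atomic-rename so a failing stage leaves no half-written report.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, reference
from .core import PeriodicBox, SoluteParams, SwextractError, ValidationError
from .msd import compute_msd, fit_diffusion
from .rdf import compute_rdf
from .synth import BrownianSpec, gen_brownian, gen_ideal_gas, gen_pair_gas, gen_thermo_truth
from .thermo import solubility_table

logger = logging.getLogger("swextract")

_STAGES = ("simulate", "msd", "rdf", "solubility", "report")


class ConfigError(SwextractError):
    """Invalid or unknown configuration keys."""


_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "output_dir", "log_level", "stages", "brownian", "msd", "rdf", "solubility"},
    "brownian": {"diffusion_coefficients", "n_particles", "timestep_fs", "n_frames", "box_edge"},
    "msd": {"max_lag_fraction", "fit_window"},
    "rdf": {"n_particles", "box_edge", "n_frames", "r_max", "bin_width", "pair_separations"},
    "solubility": {
        "pressure_Pa",
        "temperatures",
        "dG_model",
        "density_model",
        "molar_volume_m3_mol",
        "reference_vapor_pressure_Pa",
        "reference_temperature_K",
        "sublimation_enthalpy_kJ_mol",
        "solvent_molar_mass_g_mol",
    },
}


def default_config() -> dict[str, Any]:
    """Full synthetic demo: Brownian walks at the five reference diffusion
    coefficients plus a solubility round-trip fixture at 2 MPa."""
    return {
        "seed": 0,
        "output_dir": "results/pipeline",
        "log_level": "INFO",
        "stages": list(_STAGES),
        "brownian": {
            "diffusion_coefficients": {
                str(t): d for t, d in reference.DIFFUSION_M2_S.items()
            },
            "n_particles": 500,
            "timestep_fs": 1000.0,
            "n_frames": 5000,
            "box_edge": 100.0,
        },
        "msd": {"max_lag_fraction": 0.5, "fit_window": [0.1, 0.5]},
        "rdf": {
            "n_particles": 1000,
            "box_edge": 30.0,
            "n_frames": 50,
            "r_max": 14.0,
            "bin_width": 0.05,
            "pair_separations": [1.75, 2.25, 2.75],
        },
        "solubility": {
            "pressure_Pa": reference.SYSTEM_PRESSURE_PA,
            "temperatures": list(reference.TEMPERATURES_K),
            "dG_model": [-20.0, -0.05],
            "density_model": [1.25, -0.001],
            "molar_volume_m3_mol": reference.CURCUMIN_MOLAR_VOLUME_M3_MOL,
            "reference_vapor_pressure_Pa": reference.curcumin_params().reference_vapor_pressure,
            "reference_temperature_K": reference.CURCUMIN_REFERENCE_TEMPERATURE_K,
            "sublimation_enthalpy_kJ_mol": 115.0,
            "solvent_molar_mass_g_mol": 18.015,
        },
    }


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected up front."""

    raw: dict[str, Any]
    seed: int
    output_dir: Path
    log_level: str
    stages: tuple[str, ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        merged = default_config()
        unknown = set(d) - _SCHEMA[""]
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        for key, value in d.items():
            if key in _SCHEMA and isinstance(value, Mapping):
                bad = set(value) - _SCHEMA[key]
                if bad:
                    raise ConfigError(f"unknown key(s) in section {key!r}: {sorted(bad)}")
                merged[key].update(value)
            else:
                merged[key] = value
        stages = tuple(merged["stages"])
        bad_stages = set(stages) - set(_STAGES)
        if bad_stages:
            raise ConfigError(f"unknown stage(s): {sorted(bad_stages)}")
        level = str(merged["log_level"]).upper()
        if level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"invalid log_level {level!r}")
        return cls(
            raw=merged,
            seed=int(merged["seed"]),
            output_dir=Path(merged["output_dir"]),
            log_level=level,
            stages=stages,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(loaded)


@dataclass
class Report:
    """Per-stage tables with trend verdicts and a provenance block."""

    diffusion: pd.DataFrame | None = None
    rdf_peaks: pd.DataFrame | None = None
    solubility: pd.DataFrame | None = None
    verdicts: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _solute_from_config(sol: Mapping[str, Any]) -> SoluteParams:
    return SoluteParams(
        molar_volume=float(sol["molar_volume_m3_mol"]),
        reference_vapor_pressure=float(sol["reference_vapor_pressure_Pa"]),
        reference_temperature=float(sol["reference_temperature_K"]),
        sublimation_enthalpy=float(sol["sublimation_enthalpy_kJ_mol"]),
        solvent_molar_mass=float(sol["solvent_molar_mass_g_mol"]),
    )


def run_pipeline(config: RunConfig) -> Report:
    """Execute the configured stages and write their artifacts atomically."""
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(name)s: %(message)s")
    seedseq = np.random.SeedSequence(config.seed)
    report = Report(
        provenance={
            "seed": config.seed,
            "version": __version__,
            "config": config.raw,
        }
    )
    outputs: dict[Path, str] = {}
    outdir = config.output_dir

    want = set(config.stages)
    need_sim = bool(want & {"simulate", "msd", "rdf"})

    # --- simulate + msd: Brownian walks at the configured ground truths ----
    if need_sim and ("msd" in want or "simulate" in want):
        bcfg = config.raw["brownian"]
        mcfg = config.raw["msd"]
        temps = sorted(bcfg["diffusion_coefficients"], key=float)
        child_seeds = seedseq.spawn(len(temps))
        records = []
        for t_key, child in zip(temps, child_seeds):
            d_true = float(bcfg["diffusion_coefficients"][t_key])
            spec = BrownianSpec(
                n_particles=int(bcfg["n_particles"]),
                diffusion_coefficient=d_true,
                timestep=float(bcfg["timestep_fs"]),
                n_frames=int(bcfg["n_frames"]),
                box=PeriodicBox.cubic(float(bcfg["box_edge"])),
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            traj = gen_brownian(spec)
            row = {"temperature_K": float(t_key), "D_true_m2_s": d_true}
            if "msd" in want:
                series = compute_msd(
                    traj, "solute", max_lag_fraction=float(mcfg["max_lag_fraction"])
                )
                est = fit_diffusion(series, tuple(mcfg["fit_window"]))
                row.update(
                    {
                        "D_fit_m2_s": est.diffusion_coefficient,
                        "intercept_m2": est.intercept,
                        "rel_error": abs(est.diffusion_coefficient - d_true) / d_true
                        if d_true > 0
                        else np.nan,
                    }
                )
            records.append(row)
            logger.info("brownian stage done for T=%s K", t_key)
        report.diffusion = pd.DataFrame.from_records(records)
        if "msd" in want:
            fits = report.diffusion["D_fit_m2_s"].to_numpy()
            report.verdicts["diffusion_rank_preserved"] = bool(
                np.all(np.diff(fits) > 0)
            )
            outputs[outdir / "diffusion.csv"] = report.diffusion.to_csv(index=False)

    # --- rdf: ideal-gas null + dimer peaks ---------------------------------
    if "rdf" in want:
        rcfg = config.raw["rdf"]
        box = PeriodicBox.cubic(float(rcfg["box_edge"]))
        rdf_seed = int(seedseq.spawn(1)[0].generate_state(1)[0] % (2**31))
        gas = gen_ideal_gas(
            int(rcfg["n_particles"]), box, int(rcfg["n_frames"]), seed=rdf_seed
        )
        prof = compute_rdf(
            gas, "gas", "gas", r_max=float(rcfg["r_max"]), bin_width=float(rcfg["bin_width"])
        )
        centers = prof.bin_centers
        sel = (centers > 2.0) & (centers < float(rcfg["r_max"]))
        report.verdicts["ideal_gas_max_abs_dev"] = float(
            np.max(np.abs(prof.values[sel] - 1.0))
        )
        peak_rows = []
        pair_box = PeriodicBox.cubic(60.0)
        for j, sep in enumerate(rcfg["pair_separations"]):
            pg = gen_pair_gas(200, float(sep), pair_box, seed=rdf_seed + 1 + j)
            # 0.1 Å grid centres the conventional water peak positions
            # (1.75/2.25/2.75 Å) inside bins instead of on edges
            pprof = compute_rdf(pg, "A", "B", r_max=10.0, bin_width=0.1)
            # dimer fixture guarantees the *global* maximum at the set
            # separation; tiny shells elsewhere carry single-count spikes
            imax = int(np.argmax(pprof.values))
            peak_rows.append(
                {
                    "set_separation_A": float(sep),
                    "peak_position_A": float(pprof.bin_centers[imax]),
                    "peak_intensity": float(pprof.values[imax]),
                }
            )
        report.rdf_peaks = pd.DataFrame.from_records(peak_rows)
        outputs[outdir / "rdf_peaks.csv"] = report.rdf_peaks.to_csv(index=False)
        logger.info("rdf stage done")

    # --- solubility: round-trip fixture ------------------------------------
    if "solubility" in want:
        scfg = config.raw["solubility"]
        solute = _solute_from_config(scfg)
        truth = gen_thermo_truth(
            [float(t) for t in scfg["temperatures"]],
            tuple(scfg["dG_model"]),
            tuple(scfg["density_model"]),
            solute,
            float(scfg["pressure_Pa"]),
        )
        result = solubility_table(truth.table, solute, truth.system_pressure)
        df = result.rows.copy()
        df["y2_true"] = truth.true_solubility
        report.solubility = df
        report.verdicts["solubility_monotonicity"] = result.monotonicity
        report.verdicts["solubility_roundtrip_max_abs_err"] = float(
            np.max(np.abs(df["mole_fraction"].to_numpy() - truth.true_solubility))
        )
        outputs[outdir / "solubility.csv"] = df.to_csv(index=False)
        logger.info("solubility stage done")

    # --- report -------------------------------------------------------------
    if "report" in want:
        payload = {
            "provenance": report.provenance,
            "verdicts": report.verdicts,
            "tables": {
                name: (tbl.to_dict(orient="records") if tbl is not None else None)
                for name, tbl in (
                    ("diffusion", report.diffusion),
                    ("rdf_peaks", report.rdf_peaks),
                    ("solubility", report.solubility),
                )
            },
        }
        outputs[outdir / "report.json"] = json.dumps(payload, indent=2, sort_keys=True) + "\n"

    for path, text in outputs.items():
        _atomic_write(path, text)
        logger.info("wrote %s", path)
    return report
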