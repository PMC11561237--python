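"""Domain types for periodic-box particle trajectories and thermodynamic tables.

Unit conventions: coordinates and box edges in Å, times in fs, thermodynamic
quantities in the units stated per field (kJ/mol for free energies, g/cm³ for
mass densities, SI elsewhere).  Conversions happen only at the boundaries of
the analysis functions, never inside the data types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class SwextractError(Exception):
    """Base class for all package errors."""


class ValidationError(SwextractError):
    """Invariant violation in a domain type or table."""


class ParseError(SwextractError):
    """Malformed trajectory or table file."""


class UnsupportedFormatError(ParseError):
    """Recognised format but unsupported dialect (e.g. triclinic box)."""


@dataclass(frozen=True)
class PeriodicBox:
    """Orthorhombic periodic box with edge lengths in Å."""

    edge_lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edge_lengths)
        if len(edges) != 3:
            raise ValidationError("box needs exactly three edge lengths")
        if not all(np.isfinite(edges)) or any(e <= 0 for e in edges):
            raise ValidationError(f"box edges must be positive and finite, got {edges}")
        object.__setattr__(self, "edge_lengths", edges)

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(self.edge_lengths, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def min_edge(self) -> float:
        return float(min(self.edge_lengths))

    @classmethod
    def cubic(cls, edge: float) -> "PeriodicBox":
        return cls((edge, edge, edge))


def minimum_image(displacement: np.ndarray, box: PeriodicBox) -> np.ndarray:
    """Map displacement component(s) into (-L/2, L/2] per axis.

    Accepts a single 3-vector or an (..., 3) array of displacements.
    """
    disp = np.asarray(displacement, dtype=float)
    lengths = box.lengths
    # floor-based wrap puts each component in [-L/2, L/2); shift the lower
    # closed edge to the upper one so the interval is (-L/2, L/2]
    wrapped = disp - lengths * np.floor(disp / lengths + 0.5)
    wrapped = np.where(wrapped == -lengths / 2.0, lengths / 2.0, wrapped)
    return wrapped


def wrap_coordinates(coords: np.ndarray, box: PeriodicBox) -> np.ndarray:
    """Wrap absolute coordinates into [0, L) per axis."""
    coords = np.asarray(coords, dtype=float)
    lengths = box.lengths
    return coords - lengths * np.floor(coords / lengths)


@dataclass
class Frame:
    """One stored configuration: per-particle species labels and coordinates (Å)."""

    time: float  # fs
    species: tuple[str, ...]
    coordinates: np.ndarray  # (n, 3) Å
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.species = tuple(str(s) for s in self.species)
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError(f"coordinates must be (n, 3), got {coords.shape}")
        if len(self.species) != coords.shape[0]:
            raise ValidationError(
                f"{len(self.species)} species labels but {coords.shape[0]} coordinates"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")
        self.coordinates = coords

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered frames in a shared periodic box with a constant stored-frame spacing."""

    box: PeriodicBox
    frames: list[Frame]
    timestep: float  # fs between stored frames

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValidationError("trajectory needs at least one frame")
        if self.timestep <= 0:
            raise ValidationError("timestep must be positive")
        first = self.frames[0]
        for i, fr in enumerate(self.frames):
            if fr.species != first.species:
                raise ValidationError(
                    f"frame {i} species ordering differs from frame 0"
                )
        times = np.array([fr.time for fr in self.frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_particles(self) -> int:
        return self.frames[0].n_particles

    @property
    def species(self) -> tuple[str, ...]:
        return self.frames[0].species

    @property
    def wrapped(self) -> bool:
        return all(fr.wrapped for fr in self.frames)

    def species_indices(self, label: str) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.species) if s == label], dtype=int)
        return idx

    def positions(self, label: Optional[str] = None) -> np.ndarray:
        """Stack coordinates into an (n_frames, n_sel, 3) array, optionally by species."""
        if label is None:
            return np.stack([fr.coordinates for fr in self.frames])
        idx = self.species_indices(label)
        if idx.size == 0:
            raise ValidationError(f"species {label!r} not present in trajectory")
        return np.stack([fr.coordinates[idx] for fr in self.frames])


@dataclass
class ThermoTable:
    """Per-temperature solvation free energy and solvent mass density.

    Columns: temperature (K), solvation free energy ΔG_solv (kJ/mol), solvent
    mass density ρ (g/cm³).  Rows are kept sorted by temperature.
    """

    data: pd.DataFrame  # columns: temperature_K, dG_solv_kJ_mol, density_g_cm3

    REQUIRED_COLUMNS = ("temperature_K", "dG_solv_kJ_mol", "density_g_cm3")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"thermo table missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("thermo table has no rows")
        for col in self.REQUIRED_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna()]
            if len(bad):
                raise ValidationError(f"non-numeric value in column {col}, row {bad[0]}")
            df[col] = vals.astype(float)
        temps = df["temperature_K"].to_numpy()
        if np.any(temps <= 0):
            raise ValidationError("temperatures must be strictly positive")
        if len(np.unique(temps)) != len(temps):
            dup = temps[pd.Series(temps).duplicated()][0]
            raise ValidationError(f"duplicate temperature {dup} K")
        if np.any(df["density_g_cm3"].to_numpy() <= 0):
            raise ValidationError("densities must be strictly positive")
        self.data = df.sort_values("temperature_K").reset_index(drop=True)

    @property
    def temperatures(self) -> np.ndarray:
        return self.data["temperature_K"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class SoluteParams:
    """Solute reference properties for the solubility chain.

    molar_volume           ϑ^s, m³/mol
    reference_vapor_pressure  P_ref, Pa (sublimation pressure at T_ref)
    reference_temperature  T_ref, K
    sublimation_enthalpy   ΔH_sub, kJ/mol; required for the Clausius–Clapeyron
                           extrapolation and deliberately without default
    solvent_molar_mass     g/mol (the solvent the solute dissolves in)
    """

    molar_volume: float
    reference_vapor_pressure: float
    reference_temperature: float
    sublimation_enthalpy: Optional[float] = None
    solvent_molar_mass: float = 18.015

    def __post_init__(self) -> None:
        positives = {
            "molar_volume": self.molar_volume,
            "reference_vapor_pressure": self.reference_vapor_pressure,
            "reference_temperature": self.reference_temperature,
            "solvent_molar_mass": self.solvent_molar_mass,
        }
        if self.sublimation_enthalpy is not None:
            positives["sublimation_enthalpy"] = self.sublimation_enthalpy
        for name, value in positives.items():
            if not (np.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be strictly positive, got {value}")


def trajectories_equal(a: Trajectory, b: Trajectory, atol: float = 5e-7) -> bool:
    """Structural equality of two trajectories at coordinate tolerance `atol` Å."""
    if a.n_frames != b.n_frames or a.species != b.species:
        return False
    if not np.allclose(a.box.lengths, b.box.lengths, atol=atol):
        return False
    if not np.isclose(a.timestep, b.timestep, atol=atol):
        return False
    for fa, fb in zip(a.frames, b.frames):
        if fa.wrapped != fb.wrapped:
            return False
        if not np.isclose(fa.time, fb.time, atol=atol):
            return False
        if not np.allclose(fa.coordinates, fb.coordinates, atol=atol):
            return False
    return True
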