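"""Synthetic trajectory and thermo-table generators with known ground truth.

The original MD trajectories behind the analysis (curcumin in subcritical
water, class-II force field) are not reproducible here, so every estimator is
exercised on synthetic inputs whose true answer is known by construction:

* Brownian trajectories with a prescribed diffusion coefficient (unwrapped,
  for the MSD/Einstein estimator),
* uniform ideal-gas configurations (g(r) = 1 null model for the RDF),
* fixed-separation dimer gases (delta-peak fixture for peak finding),
* Metropolis Monte-Carlo Lennard-Jones liquids (realistic structured g(r)),
* thermo tables built from a prescribed mole-fraction solubility curve.

All generators take an explicit integer seed and are deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, PeriodicBox, SoluteParams, ThermoTable, Trajectory, ValidationError
from .thermo import mole_fraction_solubility

#: Å per metre
_M_TO_ANG = 1e10
#: seconds per femtosecond
_FS_TO_S = 1e-15


@dataclass(frozen=True)
class BrownianSpec:
    """Parameters of a free-diffusion trajectory.

    diffusion_coefficient is in m²/s, timestep in fs; generated coordinates
    are in Å and left unwrapped so mean-square displacements are meaningful.
    """

    n_particles: int
    diffusion_coefficient: float
    timestep: float
    n_frames: int
    box: PeriodicBox
    seed: int
    species_label: str = "solute"

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValidationError("n_particles must be >= 1")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.diffusion_coefficient < 0:
            raise ValidationError("diffusion coefficient must be >= 0")
        if self.timestep <= 0:
            raise ValidationError("timestep must be positive")


def gen_brownian(spec: BrownianSpec) -> Trajectory:
    """Independent Gaussian random walks with per-axis step variance 2·D·Δt.

    Positions start uniformly in the box and are NOT wrapped afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    dt_s = spec.timestep * _FS_TO_S
    sigma_ang = np.sqrt(2.0 * spec.diffusion_coefficient * dt_s) * _M_TO_ANG
    start = rng.uniform(0.0, spec.box.lengths, size=(spec.n_particles, 3))
    steps = rng.normal(0.0, 1.0, size=(spec.n_frames - 1, spec.n_particles, 3))
    paths = np.empty((spec.n_frames, spec.n_particles, 3))
    paths[0] = start
    np.cumsum(steps, axis=0, out=steps)
    paths[1:] = start[None] + sigma_ang * steps
    species = (spec.species_label,) * spec.n_particles
    frames = [
        Frame(time=k * spec.timestep, species=species, coordinates=paths[k], wrapped=False)
        for k in range(spec.n_frames)
    ]
    return Trajectory(box=spec.box, frames=frames, timestep=spec.timestep)


def gen_ideal_gas(
    n_particles: int,
    box: PeriodicBox,
    n_frames: int,
    seed: int,
    species_label: str = "gas",
    timestep: float = 1.0,
) -> Trajectory:
    """Uncorrelated uniform configurations: the unit-pair-correlation null model."""
    if n_particles < 2:
        raise ValidationError("ideal gas needs at least 2 particles")
    rng = np.random.default_rng(seed)
    species = (species_label,) * n_particles
    frames = []
    for k in range(n_frames):
        coords = rng.uniform(0.0, box.lengths, size=(n_particles, 3))
        frames.append(Frame(time=k * timestep, species=species, coordinates=coords, wrapped=True))
    return Trajectory(box=box, frames=frames, timestep=timestep)


def gen_pair_gas(
    n_pairs: int,
    separation: float,
    box: PeriodicBox,
    seed: int,
    species: tuple[str, str] = ("A", "B"),
    timestep: float = 1.0,
) -> Trajectory:
    """Dimer gas: one member uniform in the box, its partner at a fixed
    separation in a uniform random direction.

    Gives the cross-species RDF a delta peak at ``separation``.  Dimer centres
    are placed independently, so nothing prevents two dimers from overlapping;
    the cross histogram therefore has a small uniform background in addition
    to the n_pairs counts at the set separation.
    """
    if separation >= box.min_edge / 2.0:
        raise ValidationError(
            f"separation {separation} must be < half the smallest box edge "
            f"({box.min_edge / 2.0})"
        )
    rng = np.random.default_rng(seed)
    first = rng.uniform(0.0, box.lengths, size=(n_pairs, 3))
    # uniform random unit vectors
    vec = rng.normal(size=(n_pairs, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    second = first + separation * vec
    second -= box.lengths * np.floor(second / box.lengths)
    coords = np.concatenate([first, second])
    labels = (species[0],) * n_pairs + (species[1],) * n_pairs
    frame = Frame(time=0.0, species=labels, coordinates=coords, wrapped=True)
    return Trajectory(box=box, frames=[frame], timestep=timestep)


def _lj_move_delta(i: int, old: np.ndarray, new: np.ndarray, coords: np.ndarray,
                   lengths: np.ndarray, rc2: float) -> float:
    """Energy change of moving particle i old→new (σ=ε=1, truncated at rc)."""
    disp = np.stack([new, old])[:, None, :] - coords[None, :, :]
    disp -= lengths * np.round(disp / lengths)
    r2 = np.einsum("kij,kij->ki", disp, disp)
    r2[:, i] = np.inf
    r2 = np.where(r2 < rc2, r2, np.inf)
    inv6 = 1.0 / r2**3
    u_new, u_old = np.sum(4.0 * (inv6 * inv6 - inv6), axis=1)
    return float(u_new - u_old)


def gen_lj_fluid(
    n_particles: int,
    reduced_density: float,
    reduced_temperature: float,
    n_sweeps: int,
    seed: int,
    species_label: str = "LJ",
    n_frames: int = 10,
    frame_spacing_sweeps: int = 10,
) -> Trajectory:
    """Metropolis Monte-Carlo Lennard-Jones liquid in reduced units.

    σ = ε = 1, potential truncated at 2.5σ, minimum-image convention, cubic
    box with edge (N/ρ*)^{1/3}.  After ``n_sweeps`` equilibration sweeps the
    last ``n_frames`` configurations, spaced ``frame_spacing_sweeps`` sweeps
    apart, are returned (reduced lengths occupy the Å slots of Trajectory —
    this fixture provides realistic liquid structure, not a model of water).

    The final acceptance fraction is stored as ``trajectory.acceptance_rate``.
    """
    if not (0.0 < reduced_density < 1.2):
        raise ValidationError("reduced density must be in (0, 1.2)")
    rng = np.random.default_rng(seed)
    L = (n_particles / reduced_density) ** (1.0 / 3.0)
    box = PeriodicBox.cubic(L)
    lengths = box.lengths
    rc2 = 2.5**2
    beta = 1.0 / reduced_temperature
    # trial displacement tuned for ~40% acceptance at liquid density, larger
    # moves in the dilute regime where almost everything is accepted
    max_disp = min(0.15 / max(reduced_density, 0.3), L / 4.0)

    coords = rng.uniform(0.0, L, size=(n_particles, 3))
    n_accept = 0
    n_trial = 0
    frames: list[Frame] = []
    species = (species_label,) * n_particles
    total_sweeps = n_sweeps + (n_frames - 1) * frame_spacing_sweeps

    def sweep() -> None:
        nonlocal n_accept, n_trial
        order = rng.integers(0, n_particles, size=n_particles)
        moves = rng.uniform(-max_disp, max_disp, size=(n_particles, 3))
        accept_u = rng.uniform(size=n_particles)
        for k in range(n_particles):
            i = int(order[k])
            old = coords[i].copy()
            new = old + moves[k]
            new -= lengths * np.floor(new / lengths)
            de = _lj_move_delta(i, old, new, coords, lengths, rc2)
            n_trial += 1
            if de <= 0.0 or accept_u[k] < np.exp(-beta * de):
                coords[i] = new
                n_accept += 1

    frame_sweeps = {n_sweeps + j * frame_spacing_sweeps for j in range(n_frames)}
    for s in range(1, total_sweeps + 1):
        sweep()
        if s in frame_sweeps:
            frames.append(
                Frame(
                    time=float(s),
                    species=species,
                    coordinates=coords.copy(),
                    wrapped=True,
                )
            )
    traj = Trajectory(box=box, frames=frames, timestep=float(frame_spacing_sweeps))
    traj.acceptance_rate = n_accept / n_trial  # type: ignore[attr-defined]
    return traj


@dataclass
class ThermoTruth:
    """A thermo table together with the mole-fraction solubility it encodes."""

    table: ThermoTable
    solute: SoluteParams
    true_solubility: np.ndarray  # y2 per row of table, sorted by temperature
    system_pressure: float  # Pa

    def __post_init__(self) -> None:
        y2 = np.asarray(self.true_solubility, dtype=float)
        if len(y2) != len(self.table):
            raise ValidationError("true_solubility length must match table rows")
        if np.any((y2 <= 0) | (y2 >= 1)):
            raise ValidationError(
                "ground-truth mole fractions must lie in (0, 1); choose different "
                "generator parameters"
            )
        self.true_solubility = y2


def gen_thermo_truth(
    temperatures: list[float],
    dG_model: tuple[float, float],
    density_model: tuple[float, float],
    solute: SoluteParams,
    pressure: float,
) -> ThermoTruth:
    """Build a thermo table whose solubility curve is known by construction.

    ΔG_solv(T) = dG_model[0] + dG_model[1]·T  (kJ/mol), and the solvent mass
    density ρ(T) = density_model[0] + density_model[1]·T (g/cm³).  The ground
    truth y₂ is the direct forward evaluation of the solubility relation, so
    the table → solubility pipeline must reproduce it exactly.
    """
    temps = np.sort(np.asarray(temperatures, dtype=float))
    dG = dG_model[0] + dG_model[1] * temps
    rho = density_model[0] + density_model[1] * temps
    if np.any(rho <= 0):
        raise ValidationError("density model yields non-positive densities")
    import pandas as pd

    table = ThermoTable(
        pd.DataFrame(
            {"temperature_K": temps, "dG_solv_kJ_mol": dG, "density_g_cm3": rho}
        )
    )
    y2 = np.array(
        [
            mole_fraction_solubility(t, pressure, g, r, solute)
            for t, g, r in zip(temps, dG, rho)
        ]
    )
    return ThermoTruth(table=table, solute=solute, true_solubility=y2, system_pressure=pressure)
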