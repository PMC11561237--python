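"""Radial distribution functions between species selections, with peak analysis.

g(r) is estimated by binning minimum-image pair distances into spherical
shells and normalising by the exact shell volume (4/3)π[(r+dr)³−r³] and the
partner density, so a uniform fluid gives g(r)=1 up to counting noise.  Peak
positions/intensities of the first coordination shell — for O–H selections a
proxy for hydrogen-bond strength — are extracted per temperature and compared
across a temperature series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .core import SwextractError, Trajectory, ValidationError, minimum_image, wrap_coordinates
from .thermo import _monotonicity


class NoPeakError(SwextractError):
    """Profile contains no qualifying local maximum."""


@dataclass
class RDFProfile:
    """Binned pair correlation g(r) for one species pair.

    ``raw_counts`` holds the per-bin pair counts summed over frames (each
    unordered pair counted once); ``target_density`` is the partner number
    density ρ_y used in the normalisation (Å⁻³): N_b/V for distinct species,
    (N_a−1)/V for a like pair so the ideal-gas limit is exactly 1.
    """

    bin_edges: np.ndarray  # Å, len nbins+1
    values: np.ndarray  # g(r) per bin
    pair: tuple[str, str]
    n_frames_averaged: int
    target_density: float  # particles / Å^3
    raw_counts: np.ndarray  # summed over frames
    n_reference: int  # count of species_a particles

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if len(edges) != len(vals) + 1:
            raise ValidationError("bin_edges must have one more entry than values")
        if not np.all(np.diff(edges) > 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(vals < 0):
            raise ValidationError("g(r) values must be non-negative")
        self.bin_edges = edges
        self.values = vals
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * (self.bin_edges[1:] ** 3 - self.bin_edges[:-1] ** 3)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_center": self.bin_centers, "g": self.values})


@dataclass(frozen=True)
class PeakInfo:
    """First-shell peak: position (bin centre, Å) and g value there."""

    position: float
    intensity: float


def pair_distance_counts(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    box,
    bin_edges: np.ndarray,
    same_species: bool,
) -> np.ndarray:
    """Histogram of minimum-image a–b distances; unordered pairs counted once."""
    if same_species:
        n = coords_a.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        disp = coords_a[iu] - coords_a[ju]
    else:
        disp = coords_a[:, None, :] - coords_b[None, :, :]
        disp = disp.reshape(-1, 3)
    disp = minimum_image(disp, box)
    dist = np.sqrt(np.einsum("ij,ij->i", disp, disp))
    counts, _ = np.histogram(dist, bins=bin_edges)
    return counts


def compute_rdf(
    trajectory: Trajectory,
    species_a: str,
    species_b: str,
    r_max: float,
    bin_width: float = 0.05,
) -> RDFProfile:
    """Frame-averaged radial distribution function between two species.

    Unwrapped inputs are wrapped into the box before binning.  ``r_max`` must
    not exceed half the smallest box edge (minimum-image validity).
    """
    box = trajectory.box
    if r_max > box.min_edge / 2.0 + 1e-12:
        raise ValidationError(
            f"r_max {r_max} exceeds half the smallest box edge ({box.min_edge / 2.0})"
        )
    if bin_width <= 0:
        raise ValidationError("bin width must be positive")
    idx_a = trajectory.species_indices(species_a)
    idx_b = trajectory.species_indices(species_b)
    if idx_a.size == 0:
        raise ValidationError(f"species {species_a!r} not present")
    if idx_b.size == 0:
        raise ValidationError(f"species {species_b!r} not present")
    same = species_a == species_b
    n_a, n_b = idx_a.size, idx_b.size
    if (same and n_a < 2) or (not same and n_a + n_b < 2):
        raise ValidationError("need at least two particles in the selection")

    n_bins = int(np.ceil(r_max / bin_width - 1e-9))
    bin_edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for fr in trajectory.frames:
        coords = fr.coordinates if fr.wrapped else wrap_coordinates(fr.coordinates, box)
        counts += pair_distance_counts(
            coords[idx_a], coords[idx_b], box, bin_edges, same
        )

    volume = box.volume
    rho_y = (n_a - 1) / volume if same else n_b / volume
    shell_vol = 4.0 / 3.0 * np.pi * (bin_edges[1:] ** 3 - bin_edges[:-1] ** 3)
    pair_multiplicity = 2.0 if same else 1.0
    n_frames = trajectory.n_frames
    values = pair_multiplicity * counts / (n_frames * n_a * rho_y * shell_vol)
    return RDFProfile(
        bin_edges=bin_edges,
        values=values,
        pair=(species_a, species_b),
        n_frames_averaged=n_frames,
        target_density=rho_y,
        raw_counts=counts,
        n_reference=n_a,
    )


#: minimum height above the higher neighbouring valley for a peak call;
#: suppresses Poisson-noise wiggles at default synthetic sampling
DEFAULT_PROMINENCE = 0.05


def first_peak(
    profile: RDFProfile,
    min_position: float = 0.0,
    prominence: float = DEFAULT_PROMINENCE,
) -> PeakInfo:
    """First local maximum at position ≥ min_position exceeding the prominence floor.

    Raises NoPeakError when no bin qualifies (monotone or flat profiles),
    ValidationError when the profile is empty.
    """
    values = profile.values
    if values.size == 0:
        raise ValidationError("empty profile")
    idx, _ = find_peaks(values)
    if idx.size:
        proms = peak_prominences(values, idx)[0]
        centers = profile.bin_centers[idx]
        keep = (proms > prominence) & (centers >= min_position)
        idx = idx[keep]
    if idx.size == 0:
        raise NoPeakError(
            f"no local maximum with prominence > {prominence} at r >= {min_position}"
        )
    i = int(idx[0])
    return PeakInfo(position=float(profile.bin_centers[i]), intensity=float(values[i]))


@dataclass
class PeakTrend:
    """First-peak position/intensity versus temperature with a trend verdict."""

    rows: pd.DataFrame  # columns: temperature_K, peak_position_A, peak_intensity
    pair_label: str
    verdict: str  # monotonicity of intensity: increasing / decreasing / neither


def peak_trend(
    profiles: Mapping[float, RDFProfile],
    pair_label: str,
    min_position: float = 0.0,
    prominence: float = DEFAULT_PROMINENCE,
) -> PeakTrend:
    """Tabulate the first peak across temperatures and judge the intensity trend."""
    if len(profiles) < 2:
        raise ValidationError("peak trend needs profiles at >= 2 temperatures")
    edges = None
    records = []
    for t in sorted(profiles):
        prof = profiles[t]
        if edges is None:
            edges = prof.bin_edges
        elif len(edges) != len(prof.bin_edges) or not np.allclose(edges, prof.bin_edges):
            raise ValidationError("profiles have inconsistent binning")
        peak = first_peak(prof, min_position=min_position, prominence=prominence)
        records.append(
            {
                "temperature_K": float(t),
                "peak_position_A": peak.position,
                "peak_intensity": peak.intensity,
            }
        )
    rows = pd.DataFrame.from_records(records)
    verdict = _monotonicity(rows["peak_intensity"].to_numpy())
    return PeakTrend(rows=rows, pair_label=pair_label, verdict=verdict)
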