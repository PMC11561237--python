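"""Time-origin-averaged mean square displacement and Einstein-relation fits.

For a diffusing species the MSD grows linearly with lag time,
MSD(t) = 6·D·t + c in three dimensions, so the diffusion coefficient D is
one sixth of the slope of the MSD curve.  The MSD is averaged over all
particles of the selected species and over all time origins on a stride grid;
with stride 1 the average uses the FFT autocorrelation algorithm, which gives
the identical all-origins result in O(n log n) per particle instead of O(n²).

Trajectories must be unwrapped: displacements across periodic images cannot
be reconstructed from wrapped coordinates alone, so wrapped inputs are
rejected rather than silently unwrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import stats

from .core import SwextractError, Trajectory, ValidationError

_ANG_TO_M = 1e-10
_FS_TO_S = 1e-15


class WrappedTrajectoryError(SwextractError):
    """MSD requested on wrapped coordinates."""


@dataclass
class MSDSeries:
    """MSD versus lag time in SI units (lag 0 is implied zero and excluded)."""

    lag_times: np.ndarray  # s, strictly increasing from one frame spacing
    msd_values: np.ndarray  # m^2
    n_origins_used: np.ndarray  # time origins averaged per lag

    def __post_init__(self) -> None:
        t = np.asarray(self.lag_times, dtype=float)
        m = np.asarray(self.msd_values, dtype=float)
        if t.shape != m.shape or t.ndim != 1 or t.size == 0:
            raise ValidationError("lag_times and msd_values must be equal-length vectors")
        if not np.all(np.diff(t) > 0) or t[0] <= 0:
            raise ValidationError("lag times must be strictly increasing and positive")
        if np.any(m < -1e-30):
            raise ValidationError("MSD values must be non-negative")
        self.lag_times = t
        self.msd_values = np.maximum(m, 0.0)
        self.n_origins_used = np.asarray(self.n_origins_used, dtype=int)


@dataclass(frozen=True)
class DiffusionEstimate:
    """Einstein-relation fit: D = slope/6 of the MSD over the fit window."""

    diffusion_coefficient: float  # m^2/s
    intercept: float  # m^2
    slope_stderr: float  # m^2/s, standard error of the fitted slope
    fit_window: tuple[float, float]  # fractions of the series' max lag


def _msd_fft_all_origins(paths: np.ndarray, max_lag: int, chunk: int = 64) -> np.ndarray:
    """Stride-1 MSD for paths (P, n, 3); returns lags 1..max_lag averaged over P.

    Uses MSD(k) = <|r(t+k)|² + |r(t)|²> − 2<r(t)·r(t+k)> with the dot-product
    term from an FFT autocorrelation.
    """
    n_particles, n, _ = paths.shape
    nfft = sp_fft.next_fast_len(2 * n)
    total = np.zeros(max_lag)
    ks = np.arange(1, max_lag + 1)
    for lo in range(0, n_particles, chunk):
        r = paths[lo : lo + chunk]
        sq = np.einsum("pnk,pnk->pn", r, r)  # |r(t)|^2 per particle
        f = sp_fft.rfft(r, n=nfft, axis=1)
        acf = sp_fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, :n]
        s2 = acf.sum(axis=2)  # sum over axes of sum_t r(t)·r(t+k)
        csum = np.concatenate([np.zeros((r.shape[0], 1)), np.cumsum(sq, axis=1)], axis=1)
        s_total = csum[:, -1:]
        # sum_{t=0}^{n-k-1} |r(t)|^2 and sum_{t=k}^{n-1} |r(t)|^2, vectorised over k
        head = csum[:, n - ks]
        tail = s_total - csum[:, ks]
        msd = (head + tail - 2.0 * s2[:, 1 : max_lag + 1]) / (n - ks)
        total += msd.sum(axis=0)
    return total / n_particles


def _msd_strided(paths: np.ndarray, max_lag: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Direct strided-origin MSD for paths (P, n, 3); lags 1..max_lag."""
    _, n, _ = paths.shape
    msd = np.empty(max_lag)
    n_origins = np.empty(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        origins = np.arange(0, n - k, stride)
        disp = paths[:, origins + k, :] - paths[:, origins, :]
        msd[k - 1] = np.mean(np.einsum("pok,pok->po", disp, disp))
        n_origins[k - 1] = origins.size
    return msd, n_origins


def compute_msd(
    trajectory: Trajectory,
    species: str,
    max_lag_fraction: float = 0.5,
    origin_stride: int = 1,
) -> MSDSeries:
    """MSD of one species averaged over particles and stride-grid time origins.

    ``max_lag_fraction`` bounds the largest lag as a fraction of the
    trajectory length; long lags average few origins and are noisy.
    """
    if any(fr.wrapped for fr in trajectory.frames):
        raise WrappedTrajectoryError(
            "trajectory is wrapped: mean square displacements need unwrapped "
            "coordinates; regenerate or unwrap with image flags first"
        )
    if trajectory.n_frames < 3:
        raise ValidationError("MSD needs at least 3 frames")
    if not (0.0 < max_lag_fraction <= 1.0):
        raise ValidationError("max_lag_fraction must be in (0, 1]")
    if origin_stride < 1:
        raise ValidationError("origin_stride must be >= 1")
    paths = trajectory.positions(species)  # (n_frames, n_sel, 3)
    paths = np.ascontiguousarray(np.swapaxes(paths, 0, 1))  # (P, n, 3)
    n = paths.shape[1]
    max_lag = max(1, int(np.floor(max_lag_fraction * (n - 1))))
    if origin_stride == 1:
        msd_ang2 = _msd_fft_all_origins(paths, max_lag)
        n_origins = n - np.arange(1, max_lag + 1)
    else:
        msd_ang2, n_origins = _msd_strided(paths, max_lag, origin_stride)
    lag_times = np.arange(1, max_lag + 1) * trajectory.timestep * _FS_TO_S
    msd_m2 = msd_ang2 * _ANG_TO_M**2
    return MSDSeries(lag_times=lag_times, msd_values=msd_m2, n_origins_used=n_origins)


def fit_diffusion(
    series: MSDSeries, fit_window: tuple[float, float] = (0.1, 0.5)
) -> DiffusionEstimate:
    """Ordinary least squares of MSD on lag time over a fractional window.

    The default 10–50% window of the maximum lag excludes both short-lag
    intercept effects and poorly-averaged long lags.
    """
    lo, hi = fit_window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValidationError("fit window must satisfy 0 <= lo < hi <= 1")
    t_max = series.lag_times[-1]
    mask = (series.lag_times >= lo * t_max) & (series.lag_times <= hi * t_max)
    if int(mask.sum()) < 2:
        raise ValidationError(
            f"fit window {fit_window} contains {int(mask.sum())} lag(s); need >= 2"
        )
    res = stats.linregress(series.lag_times[mask], series.msd_values[mask])
    return DiffusionEstimate(
        diffusion_coefficient=res.slope / 6.0,
        intercept=res.intercept,
        slope_stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        fit_window=(lo, hi),
    )
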