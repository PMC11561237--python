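"""RDF estimator against a brute-force oracle, plus peak extraction and trends."""

import numpy as np
import pytest

import swextract as sw
from swextract.rdf import DEFAULT_PROMINENCE, RDFProfile

from conftest import brute_force_pair_counts


def _random_config(rng, n, box, species_pool=("A", "B")):
    species = tuple(rng.choice(species_pool, size=n))
    coords = rng.uniform(0, box.lengths, size=(n, 3))
    frame = sw.Frame(time=0.0, species=species, coordinates=coords, wrapped=True)
    return sw.Trajectory(box=box, frames=[frame], timestep=1.0)


class TestComputeRdf:
    @pytest.mark.parametrize("same_species", [False, True])
    def test_raw_counts_match_brute_force(self, same_species):
        """Binned pair counts equal an explicit O(N²) double loop, exactly."""
        rng = np.random.default_rng(2024)
        for _ in range(10):
            n = int(rng.integers(10, 80))
            box = sw.PeriodicBox(tuple(rng.uniform(8, 20, 3)))
            traj = _random_config(rng, n, box)
            a, b = ("A", "A") if same_species else ("A", "B")
            if len(traj.species_indices(a)) < 2 or len(traj.species_indices(b)) < 1:
                continue
            bin_width = float(rng.uniform(0.05, 0.5))
            r_max = box.min_edge / 2
            prof = sw.compute_rdf(traj, a, b, r_max=r_max, bin_width=bin_width)
            coords = traj.frames[0].coordinates
            ref = brute_force_pair_counts(
                coords[traj.species_indices(a)],
                coords[traj.species_indices(b)],
                box,
                prof.bin_edges,
                same_species,
            )
            np.testing.assert_array_equal(prof.raw_counts, ref)

    def test_single_pair_at_three_angstroms(self):
        box = sw.PeriodicBox.cubic(60.0)
        coords = np.array([[10.0, 10.0, 10.0], [13.0, 10.0, 10.0]])
        frame = sw.Frame(time=0.0, species=("A", "B"), coordinates=coords, wrapped=True)
        traj = sw.Trajectory(box=box, frames=[frame], timestep=1.0)
        prof = sw.compute_rdf(traj, "A", "B", r_max=10.0, bin_width=0.4)
        nonzero = np.nonzero(prof.raw_counts)[0]
        assert len(nonzero) == 1
        i = nonzero[0]
        assert prof.bin_edges[i] <= 3.0 < prof.bin_edges[i + 1]
        assert prof.raw_counts[i] == 1

    def test_ideal_gas_unit_correlation(self):
        """Uniform fluid: g(r) = 1 within Poisson noise, mean within 3 SE of 1."""
        gas = sw.gen_ideal_gas(500, sw.PeriodicBox.cubic(25.0), 30, seed=42)
        prof = sw.compute_rdf(gas, "gas", "gas", r_max=12.0, bin_width=0.1)
        c = prof.bin_centers
        sel = (c > 2.0) & (c < 12.0)
        g = prof.values[sel]
        assert np.all(np.abs(g - 1.0) < 0.2)
        # mean over bins vs its standard error from the raw counts
        se = np.sqrt(np.sum(prof.raw_counts[sel])) / np.sum(prof.raw_counts[sel])
        assert abs(np.mean(g) - 1.0) < 3 * max(se, 1e-6) + 3e-3

    def test_number_conservation(self):
        """ρ_y·Σ g·V_shell equals the mean partner count within r_max, exactly."""
        rng = np.random.default_rng(5)
        box = sw.PeriodicBox.cubic(15.0)
        traj = _random_config(rng, 60, box)
        for a, b in (("A", "B"), ("A", "A")):
            prof = sw.compute_rdf(traj, a, b, r_max=7.0, bin_width=0.25)
            lhs = prof.target_density * np.sum(prof.values * prof.shell_volumes)
            mult = 2.0 if a == b else 1.0
            n_a = len(traj.species_indices(a))
            rhs = mult * prof.raw_counts.sum() / (traj.n_frames * n_a)
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_symmetry_under_pair_exchange(self):
        rng = np.random.default_rng(6)
        traj = _random_config(rng, 50, sw.PeriodicBox.cubic(14.0))
        ab = sw.compute_rdf(traj, "A", "B", r_max=6.0, bin_width=0.2)
        ba = sw.compute_rdf(traj, "B", "A", r_max=6.0, bin_width=0.2)
        np.testing.assert_allclose(ab.values, ba.values, rtol=1e-12)

    def test_wraps_unwrapped_input(self):
        box = sw.PeriodicBox.cubic(10.0)
        coords = np.array([[0.5, 0.5, 0.5], [12.5, 0.5, 0.5], [25.0, 3.0, 3.0]])
        frame = sw.Frame(time=0.0, species=("A", "A", "A"), coordinates=coords, wrapped=False)
        traj = sw.Trajectory(box=box, frames=[frame], timestep=1.0)
        prof = sw.compute_rdf(traj, "A", "A", r_max=5.0, bin_width=0.5)
        # particles 0 and 1 are 2 Å apart after wrapping
        i = int(np.nonzero(prof.raw_counts)[0][0])
        assert prof.bin_edges[i] <= 2.0 < prof.bin_edges[i + 1]

    def test_errors(self, small_trajectory):
        with pytest.raises(sw.ValidationError, match="r_max"):
            sw.compute_rdf(small_trajectory, "O_water", "H_water", r_max=9.0)
        with pytest.raises(sw.ValidationError, match="not present"):
            sw.compute_rdf(small_trajectory, "Xe", "H_water", r_max=4.0)
        with pytest.raises(sw.ValidationError, match="two particles"):
            sw.compute_rdf(small_trajectory, "O_water", "O_water", r_max=4.0)


def _profile_from_values(values, bin_width=0.5):
    values = np.asarray(values, dtype=float)
    edges = bin_width * np.arange(len(values) + 1)
    return RDFProfile(
        bin_edges=edges,
        values=values,
        pair=("O_OHcurcumin", "H_water"),
        n_frames_averaged=1,
        target_density=0.03,
        raw_counts=np.zeros_like(values),
        n_reference=10,
    )


class TestFirstPeak:
    def test_peak_at_first_shell(self):
        # bin width 0.5: the 4th bin centre is 1.75 Å, the conventional O–H
        # first-shell distance in water
        prof = _profile_from_values([0.0, 0.2, 0.7, 1.10, 0.9, 0.95, 1.0])
        peak = sw.first_peak(prof)
        assert peak.position == pytest.approx(1.75)
        assert peak.intensity == pytest.approx(1.10)

    def test_strictly_increasing_has_no_peak(self):
        prof = _profile_from_values(np.linspace(0, 1.5, 12))
        with pytest.raises(sw.NoPeakError):
            sw.first_peak(prof)

    def test_flat_profile_has_no_peak(self):
        prof = _profile_from_values(np.ones(15))
        with pytest.raises(sw.NoPeakError):
            sw.first_peak(prof)

    def test_prominence_floor_suppresses_noise_bumps(self):
        values = np.ones(15)
        values[4] = 1.0 + DEFAULT_PROMINENCE * 0.8  # below the floor
        with pytest.raises(sw.NoPeakError):
            sw.first_peak(_profile_from_values(values))

    def test_min_position_skips_early_peaks(self):
        prof = _profile_from_values([0.0, 1.2, 0.3, 0.8, 1.5, 0.9, 1.0])
        early = sw.first_peak(prof)
        later = sw.first_peak(prof, min_position=1.0)
        assert early.position < 1.0
        assert later.position == pytest.approx(2.25)

    def test_empty_profile_is_distinct_error(self):
        prof = _profile_from_values([1.0, 2.0, 1.0])
        prof.values = np.array([])
        prof.bin_edges = np.array([0.0])
        with pytest.raises(sw.ValidationError):
            sw.first_peak(prof)


def _peaked_profile(intensity, center_bin=3, n_bins=10, bin_width=0.5):
    values = np.full(n_bins, 0.6)
    values[: center_bin + 1] = np.linspace(0.1, intensity, center_bin + 1)
    values[center_bin + 1 :] = np.linspace(intensity - 0.4, 1.0, n_bins - center_bin - 1)
    return _profile_from_values(values, bin_width)


class TestPeakTrend:
    TEMPS = (363.15, 393.15, 413.15, 423.15, 453.15)

    def test_rising_first_shell_reported_increasing(self):
        # solute(OH)–water-H contact strengthening with temperature
        intensities = (1.03, 1.34, 1.42, 1.45, 1.56)
        profiles = {t: _peaked_profile(i) for t, i in zip(self.TEMPS, intensities)}
        trend = sw.peak_trend(profiles, "O_OHcurcumin:H_water")
        assert trend.verdict == "increasing"
        np.testing.assert_allclose(trend.rows["peak_intensity"], intensities)
        assert trend.rows["temperature_K"].is_monotonic_increasing

    def test_weakening_water_network_reported_decreasing(self):
        intensities = (1.10, 1.08, 1.07, 1.01, 0.90)
        profiles = {t: _peaked_profile(i) for t, i in zip(self.TEMPS, intensities)}
        trend = sw.peak_trend(profiles, "O_water:H_water")
        assert trend.verdict == "decreasing"

    def test_tied_profiles_are_neither(self):
        profiles = {300.0: _peaked_profile(1.2), 400.0: _peaked_profile(1.2)}
        assert sw.peak_trend(profiles, "A:B").verdict == "neither"

    def test_inconsistent_binning_rejected(self):
        profiles = {
            300.0: _peaked_profile(1.2, bin_width=0.5),
            400.0: _peaked_profile(1.3, bin_width=0.25),
        }
        with pytest.raises(sw.ValidationError, match="binning"):
            sw.peak_trend(profiles, "A:B")

    def test_needs_two_temperatures(self):
        with pytest.raises(sw.ValidationError):
            sw.peak_trend({300.0: _peaked_profile(1.2)}, "A:B")
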