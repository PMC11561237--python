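"""Solubility chain: closed-form spot checks and thermodynamic monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import swextract as sw
from swextract import reference
from swextract.thermo import MMHG_TO_PA

CURCUMIN = sw.SoluteParams(
    molar_volume=3.961e-4,
    reference_vapor_pressure=3.08e-12 * MMHG_TO_PA,
    reference_temperature=298.15,
    sublimation_enthalpy=115.0,
)


class TestSublimationPressure:
    def test_reference_point_is_exact(self):
        p = sw.sublimation_pressure(CURCUMIN.reference_temperature, CURCUMIN)
        assert p == CURCUMIN.reference_vapor_pressure

    def test_curcumin_reference_pressure_in_pascal(self):
        assert CURCUMIN.reference_vapor_pressure == pytest.approx(4.106e-10, rel=1e-3)

    def test_integrated_form_spot_value(self):
        # frozen from an independent evaluation of
        # P_ref·exp[(ΔH/R)(1/T_ref − 1/T)] at ΔH=100 kJ/mol, 298.15→350 K
        solute = sw.SoluteParams(
            molar_volume=1e-4,
            reference_vapor_pressure=1.0,
            reference_temperature=298.15,
            sublimation_enthalpy=100.0,
        )
        assert sw.sublimation_pressure(350.0, solute) == pytest.approx(393.87, rel=1e-3)

    def test_missing_enthalpy_is_configuration_error(self):
        solute = sw.SoluteParams(
            molar_volume=1e-4, reference_vapor_pressure=1.0, reference_temperature=298.15
        )
        with pytest.raises(sw.ConfigurationError, match="sublimation enthalpy"):
            sw.sublimation_pressure(350.0, solute)

    @given(
        t=st.floats(250, 600),
        dh=st.floats(10, 300),
    )
    def test_increasing_in_temperature_above_reference(self, t, dh):
        solute = sw.SoluteParams(
            molar_volume=1e-4,
            reference_vapor_pressure=1e-6,
            reference_temperature=298.15,
            sublimation_enthalpy=dh,
        )
        p_lo = sw.sublimation_pressure(t, solute)
        p_hi = sw.sublimation_pressure(t + 5.0, solute)
        assert p_hi > p_lo


class TestNumberDensity:
    def test_water_spot_value(self):
        # 0.962 g/cm³ over 18.015 g/mol, hand-checked by dimensional analysis
        assert sw.number_density(0.962, 18.015) == pytest.approx(3.2158e28, rel=1e-4)

    def test_linearity_in_density(self):
        assert sw.number_density(1.8, 18.0) == pytest.approx(
            2 * sw.number_density(0.9, 18.0), rel=1e-12
        )

    def test_vanishes_for_heavy_molecules(self):
        assert sw.number_density(1.0, 1e12) < 1e18  # → 0 as M → ∞

    def test_rejects_non_positive(self):
        with pytest.raises(sw.ValidationError):
            sw.number_density(-1.0, 18.0)
        with pytest.raises(sw.ValidationError):
            sw.number_density(1.0, 0.0)


class TestMoleFractionSolubility:
    def test_worked_example_at_lowest_temperature(self):
        """Forward SI evaluation at 363.15 K / 2 MPa with a fixed P₂ˢᵃᵗ.

        Expected value frozen from an independent step-by-step evaluation
        (number density → Poynting factor → solvation factor → ratio).
        """
        y2 = sw.mole_fraction_solubility(
            363.15, 2e6, -35.848, 0.962, CURCUMIN, sat_pressure=2.86e-3
        )
        assert y2 == pytest.approx(3.304e-6, rel=1e-3)

    def test_poynting_factor_is_one_at_saturation(self):
        assert sw.poynting_factor(363.15, 5.0, 5.0, 3.961e-4) == 1.0

    def test_zero_solvation_energy_reduces_to_pressure_ratio(self):
        t, p, rho = 400.0, 2e6, 0.9
        psat = 1e-3
        y2 = sw.mole_fraction_solubility(t, p, 0.0, rho, CURCUMIN, sat_pressure=psat)
        rho_n = sw.number_density(rho, CURCUMIN.solvent_molar_mass)
        expected = (
            psat
            * sw.poynting_factor(t, p, psat, CURCUMIN.molar_volume)
            / (rho_n * 1.380649e-23 * t)
        )
        assert y2 == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_warns_but_returns(self):
        with pytest.warns(sw.OutOfRangeWarning):
            y2 = sw.mole_fraction_solubility(
                363.15, 2e6, -80.0, 0.962, CURCUMIN, sat_pressure=1e5
            )
        assert y2 > 1.0

    @given(
        dg=st.floats(-60, 20),
        delta=st.floats(0.1, 20),
        t=st.floats(300, 500),
    )
    def test_strictly_decreasing_in_solvation_free_energy(self, dg, delta, t):
        lo = sw.mole_fraction_solubility(t, 2e6, dg, 0.9, CURCUMIN)
        hi = sw.mole_fraction_solubility(t, 2e6, dg + delta, 0.9, CURCUMIN)
        assert hi < lo

    def test_increasing_in_sublimation_pressure(self):
        # dominant linear regime: P₂ˢᵃᵗ ≪ RT/ϑ^s always holds at these magnitudes
        y = [
            sw.mole_fraction_solubility(363.15, 2e6, -35.0, 0.9, CURCUMIN, sat_pressure=p)
            for p in (1e-4, 1e-3, 1e-2)
        ]
        assert y[0] < y[1] < y[2]


class TestAard:
    def test_identical_vectors_zero(self):
        assert sw.aard([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_single_pair(self):
        assert sw.aard([1.1], [1.0]) == pytest.approx(10.0)

    def test_density_validation_value(self):
        """Simulated vs calculated water densities over the four complete rows.

        Recomputation gives ≈6.50%; the published rounding is 6.45%.
        """
        both = reference.WATER_DENSITY_G_CM3.dropna()
        value = sw.aard(both["simulated"], both["calculated"])
        assert value == pytest.approx(6.503, abs=0.01)
        assert abs(value - reference.REPORTED_DENSITY_AARD_PCT) <= 0.1

    def test_errors(self):
        with pytest.raises(sw.ValidationError):
            sw.aard([1.0, 2.0], [1.0])
        with pytest.raises(sw.ValidationError):
            sw.aard([1.0], [0.0])
        with pytest.raises(sw.ValidationError):
            sw.aard([], [])

    @given(
        values=st.lists(
            st.tuples(
                st.floats(-100, 100),
                st.floats(0.01, 100),
            ),
            min_size=1,
            max_size=20,
        ),
        k=st.floats(0.01, 1000),
    )
    def test_scale_invariance_and_non_negativity(self, values, k):
        sim = np.array([v[0] for v in values])
        ref = np.array([v[1] for v in values])
        a = sw.aard(sim, ref)
        assert a >= 0.0
        assert sw.aard(k * sim, k * ref) == pytest.approx(a, rel=1e-9)
        if np.array_equal(sim, ref):
            assert a == 0.0


class TestSolubilityTable:
    def test_round_trip_with_generated_truth(self):
        truth = sw.gen_thermo_truth(
            [363.15, 393.15, 413.15, 423.15, 453.15],
            (-30.0, -0.01),
            (1.2, -0.0008),
            CURCUMIN,
            2e6,
        )
        result = sw.solubility_table(truth.table, CURCUMIN, 2e6)
        np.testing.assert_array_equal(
            result.rows["mole_fraction"].to_numpy(), truth.true_solubility
        )

    def test_single_row_monotonicity_undefined(self):
        table = sw.ThermoTable(
            pd.DataFrame(
                {"temperature_K": [363.15], "dG_solv_kJ_mol": [-35.0], "density_g_cm3": [0.9]}
            )
        )
        result = sw.solubility_table(table, CURCUMIN, 2e6)
        assert len(result.rows) == 1
        assert result.monotonicity == "undefined"

    def test_increasing_fixture_flagged_increasing(self):
        truth = sw.gen_thermo_truth(
            [363.15, 393.15, 413.15, 423.15, 453.15],
            (20.0, -0.15),
            (1.25, -0.001),
            CURCUMIN,
            2e6,
        )
        result = sw.solubility_table(truth.table, CURCUMIN, 2e6)
        assert result.monotonicity == "increasing"

    def test_reference_table_runs_end_to_end(self):
        """The published ΔG/density rows produce finite positive solubilities."""
        table = reference.thermo_table()
        result = sw.solubility_table(table, reference.curcumin_params(115.0), 2e6)
        y2 = result.rows["mole_fraction"].to_numpy()
        assert np.all(y2 > 0) and np.all(np.isfinite(y2))
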