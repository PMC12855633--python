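"""Flux aggregation: period fluxes, year splitting, interpolation, balances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ionbudget.fluxes import (
    annual_fluxes,
    cation_anion_balance,
    dry_deposition_estimate,
    period_flux,
)

from conftest import constant_water, make_dataset


class TestPeriodFlux:
    def test_direct_arithmetic(self):
        assert period_flux(100.0, [2.0] * 14) == pytest.approx(2.8)

    def test_zero_water(self):
        assert period_flux(50.0, [0.0, 0.0]) == 0.0

    @given(
        conc=st.floats(0, 1e3),
        mm=st.lists(st.floats(0, 50), min_size=1, max_size=30),
        c=st.floats(0.1, 10),
    )
    def test_linear_in_both_arguments(self, conc, mm, c):
        base = period_flux(conc, mm)
        assert period_flux(c * conc, mm) == pytest.approx(c * base, rel=1e-9, abs=1e-12)
        assert period_flux(conc, [c * x for x in mm]) == pytest.approx(
            c * base, rel=1e-9, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            period_flux(-1.0, [1.0])
        with pytest.raises(ValueError):
            period_flux(1.0, [])
        with pytest.raises(ValueError):
            period_flux(1.0, [-1.0])


class TestYearBoundarySplit:
    def test_pro_rata_by_water(self):
        """A 10-day period with 6 water-days in December and 4 in January
        splits its flux 60/40 under equal daily fluxes."""
        ds = make_dataset(
            periods=[("2000-12-26", "2001-01-04", "bulk", "SO4", 100.0, np.nan)],
            daily_water=constant_water("2000-12-26", "2001-01-04", "bulk", 1.0),
        )
        ann = annual_fluxes(ds, include_h_from_ph=False)
        total = 100.0 * 10 * 1e-3
        by_year = ann.set_index("year")["flux_mmol_ie_m2"]
        assert by_year[2000] == pytest.approx(0.6 * total)
        assert by_year[2001] == pytest.approx(0.4 * total)

    def test_unequal_water_splits_by_water(self):
        water = [("2000-12-30", "bulk", 3.0), ("2000-12-31", "bulk", 1.0),
                 ("2001-01-01", "bulk", 0.0), ("2001-01-02", "bulk", 4.0)]
        ds = make_dataset(
            periods=[("2000-12-30", "2001-01-02", "bulk", "NO3", 10.0, np.nan)],
            daily_water=water,
        )
        ann = annual_fluxes(ds, include_h_from_ph=False)
        by_year = ann.set_index("year")["flux_mmol_ie_m2"]
        assert by_year[2000] == pytest.approx(10.0 * 4.0 * 1e-3)
        assert by_year[2001] == pytest.approx(10.0 * 4.0 * 1e-3)


class TestMissingConcentrations:
    def test_gap_between_equal_neighbours_filled_with_same_value(self):
        periods = [
            ("2000-01-01", "2000-01-10", "bulk", "SO4", 20.0, np.nan),
            ("2000-01-11", "2000-01-20", "bulk", "SO4", np.nan, np.nan),
            ("2000-01-21", "2000-01-30", "bulk", "SO4", 20.0, np.nan),
        ]
        ds = make_dataset(periods, constant_water("2000-01-01", "2000-01-30", "bulk", 1.0))
        ann = annual_fluxes(ds, include_h_from_ph=False)
        assert ann["flux_mmol_ie_m2"].iloc[0] == pytest.approx(20.0 * 30 * 1e-3)
        assert ann["interpolated_fraction"].iloc[0] == pytest.approx(10 / 30)
        assert bool(ann["low_confidence"].iloc[0])  # 33% > 25%

    def test_endpoint_gap_takes_nearest_value(self):
        periods = [
            ("2000-01-01", "2000-01-10", "bulk", "SO4", np.nan, np.nan),
            ("2000-01-11", "2000-01-20", "bulk", "SO4", 30.0, np.nan),
            ("2000-01-21", "2000-01-30", "bulk", "SO4", 60.0, np.nan),
        ]
        ds = make_dataset(periods, constant_water("2000-01-01", "2000-01-30", "bulk", 1.0))
        ann = annual_fluxes(ds, include_h_from_ph=False)
        assert ann["flux_mmol_ie_m2"].iloc[0] == pytest.approx(
            (30.0 + 30.0 + 60.0) * 10 * 1e-3)

    def test_all_missing_is_an_error(self):
        periods = [("2000-01-01", "2000-01-10", "bulk", "SO4", np.nan, np.nan)]
        ds = make_dataset(periods, constant_water("2000-01-01", "2000-01-10", "bulk", 1.0))
        with pytest.raises(ValueError, match="no non-missing"):
            annual_fluxes(ds, include_h_from_ph=False)


class TestLinearityAndAdditivity:
    def test_scaling_water_scales_annual_flux(self):
        periods = [
            ("2000-01-01", "2000-06-30", "bulk", "SO4", 10.0, np.nan),
            ("2000-07-01", "2000-12-31", "bulk", "SO4", 30.0, np.nan),
        ]
        water = constant_water("2000-01-01", "2000-12-31", "bulk", 2.0)
        ds = make_dataset(periods, water)
        base = annual_fluxes(ds, include_h_from_ph=False)["flux_mmol_ie_m2"].iloc[0]
        ds.water["water_mm"] *= 3.0
        scaled = annual_fluxes(ds, include_h_from_ph=False)["flux_mmol_ie_m2"].iloc[0]
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_annual_flux_is_sum_of_period_contributions(self):
        periods = [
            ("2000-01-01", "2000-03-31", "bulk", "NO3", 5.0, np.nan),
            ("2000-04-01", "2000-12-31", "bulk", "NO3", 15.0, np.nan),
        ]
        water = constant_water("2000-01-01", "2000-12-31", "bulk", 1.5)
        ds = make_dataset(periods, water)
        ann = annual_fluxes(ds, include_h_from_ph=False)
        expected = period_flux(5.0, [1.5] * 91) + period_flux(15.0, [1.5] * 275)
        assert ann["flux_mmol_ie_m2"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_h_flux_derived_from_ph(self):
        periods = [("2000-01-01", "2000-12-31", "throughfall", "SO4", 10.0, 4.0)]
        water = constant_water("2000-01-01", "2000-12-31", "throughfall", 1.0)
        ann = annual_fluxes(make_dataset(periods, water))
        h = ann[ann.species == "H"]["flux_mmol_ie_m2"].iloc[0]
        # 10⁻⁴ mol L⁻¹ × 366 L m⁻² (leap year) × 10³ mmol/mol = 36.6 mmol_IE m⁻²
        assert h == pytest.approx(1e-4 * 366 * 1000)


class TestDryDeposition:
    def test_throughfall_minus_bulk(self, default_annual):
        dd = dry_deposition_estimate(default_annual, "SO4").set_index("year")
        ann = default_annual
        tf85 = ann[(ann.year == 1985) & (ann.compartment == "throughfall")
                   & (ann.species == "SO4")]["flux_mmol_ie_m2"].iloc[0]
        b85 = ann[(ann.year == 1985) & (ann.compartment == "bulk")
                  & (ann.species == "SO4")]["flux_mmol_ie_m2"].iloc[0]
        assert dd.loc[1985, "dry_deposition_mmol_ie_m2"] == pytest.approx(tf85 - b85)
        # early series: dry deposition dominates; late series: nearly gone
        assert dd.loc[1985, "dry_deposition_mmol_ie_m2"] > 50
        assert abs(dd.loc[2020, "dry_deposition_mmol_ie_m2"]) < 20

    def test_missing_compartment_is_error(self):
        table = pd.DataFrame({
            "year": [2000], "compartment": ["bulk"], "species": ["SO4"],
            "flux_mmol_ie_m2": [10.0]})
        with pytest.raises(ValueError):
            dry_deposition_estimate(table, "SO4")


class TestChargeBalance:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["year", "compartment", "species",
                                           "flux_mmol_ie_m2"])

    def test_constructed_balanced_year(self):
        t = self.table([
            (2000, "seepage40", "NO3", 100.0), (2000, "seepage40", "SO4", 100.0),
            (2000, "seepage40", "Al", 84.0), (2000, "seepage40", "Ca", 80.0),
            (2000, "seepage40", "H", 36.0),
        ])
        bal = cation_anion_balance(t, 2000, "seepage40")
        assert bal.relative_imbalance == pytest.approx(0.0)
        assert bal.cation_shares["Al"] == pytest.approx(0.42)

    def test_anion_only_is_error(self):
        t = self.table([(2000, "seepage40", "NO3", 100.0)])
        with pytest.raises(ValueError):
            cation_anion_balance(t, 2000, "seepage40")

    def test_default_scenario_aluminium_dominates_cations(self, default_annual):
        bal = cation_anion_balance(default_annual, 1990, "seepage40")
        assert max(bal.cation_shares, key=bal.cation_shares.get) == "Al"
        assert 0.3 < bal.cation_shares["Al"] < 0.55
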