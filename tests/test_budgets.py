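"""Proton and sulfur budgets: closed form vs process-level oracle, storage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ionbudget.budgets import (
    annual_s_balance,
    livestock_units,
    n_transformation_proton_load,
    proton_budget,
    proton_budget_series,
    s_balance_series,
    storage_trajectory,
    surplus_factor,
)


def rule_level_proton_sum(n, u_a, u_n, m):
    """Independent oracle: count protons per process.

    Nitrification releases two protons per NH₄⁺ (one for the conversion of
    ammonium, one more for the nitrate formed); plant NH₄⁺ uptake releases
    one; NO₃⁻ uptake/denitrification consumes one; ammonification consumes
    one per NH₄⁺ formed.
    """
    return 2 * n + u_a - u_n - m


def draw_consistent_rates(rng, size):
    """Random nonnegative process rates with consistent N mass balances."""
    n = rng.integers(0, 200, size)
    u_a = rng.integers(0, 200, size)
    m = rng.integers(0, 200, size)
    u_n = rng.integers(0, 200, size)
    nh4_in = n + u_a + rng.integers(0, 200, size)  # keeps nh4_out >= 0
    no3_in = u_n + rng.integers(0, 200, size)      # keeps no3_out >= 0
    nh4_out = nh4_in + m - n - u_a
    no3_out = no3_in + n - u_n
    return n, u_a, u_n, m, nh4_in, nh4_out, no3_in, no3_out


class TestNTransformationLoad:
    def test_oracle_equivalence_exact_over_random_rates(self):
        """Closed form equals rule-level accounting for 10⁴ random consistent
        process-rate vectors, in exact integer arithmetic."""
        rng = np.random.default_rng(42)
        n, u_a, u_n, m, nh4_in, nh4_out, no3_in, no3_out = draw_consistent_rates(
            rng, 10_000)
        assert (nh4_out >= 0).all() and (no3_out >= 0).all()
        closed = (nh4_in - nh4_out) + (no3_out - no3_in)
        assert (closed == rule_level_proton_sum(n, u_a, u_n, m)).all()
        # and the implementation returns the same closed form
        for i in range(0, 10_000, 997):
            assert n_transformation_proton_load(
                int(nh4_in[i]), int(nh4_out[i]), int(no3_in[i]), int(no3_out[i])
            ) == closed[i]

    @pytest.mark.parametrize(
        "nh4_in, nh4_out, no3_in, no3_out, expected",
        [
            (150, 0, 70, 300, 380),
            (100, 100, 50, 50, 0),
            (100, 100, 50, 30, -20),  # net nitrate consumption
        ],
    )
    def test_worked_examples(self, nh4_in, nh4_out, no3_in, no3_out, expected):
        assert n_transformation_proton_load(nh4_in, nh4_out, no3_in, no3_out) == expected

    def test_negative_flux_rejected(self):
        with pytest.raises(ValueError):
            n_transformation_proton_load(-1, 0, 0, 0)


class TestProtonBudget:
    @staticmethod
    def table(direct, nh4_in, nh4_out, no3_in, no3_out, h_out, year=2000):
        rows = [
            (year, "throughfall", "H", direct),
            (year, "throughfall", "NH4", nh4_in),
            (year, "throughfall", "NO3", no3_in),
            (year, "seepage40", "NH4", nh4_out),
            (year, "seepage40", "NO3", no3_out),
            (year, "seepage40", "H", h_out),
        ]
        return pd.DataFrame(rows, columns=["year", "compartment", "species",
                                           "flux_mmol_ie_m2"])

    @pytest.mark.parametrize("h_out, expected_buffered", [
        (3.0, 97.0),   # first-5-year-like buffering
        (6.6, 93.4),   # last-5-year-like buffering
        (0.0, 100.0),
    ])
    def test_buffered_percent(self, h_out, expected_buffered):
        # direct 10 + N load 90 -> total 100
        t = self.table(direct=10.0, nh4_in=100.0, nh4_out=10.0,
                       no3_in=50.0, no3_out=50.0, h_out=h_out)
        b = proton_budget(t, 2000)
        assert b.total_load == pytest.approx(100.0)
        assert b.buffered_percent == pytest.approx(expected_buffered)

    def test_total_is_direct_plus_n_load(self):
        t = self.table(5.0, 120.0, 8.0, 60.0, 200.0, 4.0)
        b = proton_budget(t, 2000)
        assert b.total_load == pytest.approx(b.direct_input + b.n_transformation_load)
        assert b.n_transformation_load == pytest.approx((120 - 8) + (200 - 60))

    def test_missing_species_is_error(self):
        t = self.table(5.0, 120.0, 8.0, 60.0, 200.0, 4.0).iloc[:-1]
        with pytest.raises(KeyError):
            proton_budget(t, 2000)

    def test_buffered_at_most_100_with_nonnegative_output(self, default_annual):
        series = proton_budget_series(default_annual)
        assert (series["buffered_percent"] <= 100.0).all()
        assert (series["seepage_output"] >= 0.0).all()


class TestSBalance:
    @staticmethod
    def table(tf, seep, year=2000):
        return pd.DataFrame(
            [(year, "throughfall", "SO4", tf), (year, "seepage40", "SO4", seep)],
            columns=["year", "compartment", "species", "flux_mmol_ie_m2"])

    @pytest.mark.parametrize("tf, seep, expected", [
        (160.0, 160.0, 0.0), (40.0, 200.0, -160.0), (10.0, 0.0, 10.0)])
    def test_delta(self, tf, seep, expected):
        assert annual_s_balance(self.table(tf, seep), 2000) == pytest.approx(expected)

    def test_missing_flux_is_error(self):
        with pytest.raises(KeyError):
            annual_s_balance(self.table(10.0, 5.0).iloc[:1], 2000)


class TestStorageTrajectory:
    def test_remaining_fraction_worked_example(self):
        """36 equal equivalent deltas summing to −2012.3 on the element basis
        leave 269.0 of 2281.3 mmol m⁻², i.e. 11.8%."""
        deltas = {1985 + i: 2 * (-2012.3 / 36) for i in range(36)}
        traj = storage_trajectory(deltas, initial_stock_mmol_m2=2281.3)
        assert traj.cumulative_change_mmol_m2 == pytest.approx(-2012.3)
        assert traj.remaining_stock_mmol_m2 == pytest.approx(269.0)
        assert traj.remaining_fraction_percent == pytest.approx(11.79, abs=0.01)
        assert not traj.stock_exhausted

    def test_zero_deltas_and_exhaustion(self):
        traj = storage_trajectory({2000: 0.0, 2001: 0.0}, 100.0)
        assert traj.remaining_fraction_percent == pytest.approx(100.0)
        traj2 = storage_trajectory({2000: -200.0}, 100.0)  # −100 element-mol
        assert traj2.remaining_fraction_percent == pytest.approx(0.0)
        assert traj2.stock_exhausted

    def test_uptake_term_shifts_every_delta(self):
        base = storage_trajectory({2000: 10.0, 2001: 10.0}, 100.0)
        with_uptake = storage_trajectory({2000: 10.0, 2001: 10.0}, 100.0,
                                         uptake_mmol_ie_m2_yr=5.5)
        shift = 2 * 5.5 / 2  # years × uptake / charge
        assert (base.cumulative_change_mmol_m2 - with_uptake.cumulative_change_mmol_m2
                ) == pytest.approx(shift)

    @given(
        c=st.floats(-50, 50),
        n_years=st.integers(2, 20),
    )
    def test_translation_consistency(self, c, n_years):
        """Adding c to every equivalent delta moves the cumulative endpoint by
        c × n_years on the element basis (÷ charge)."""
        deltas = {2000 + i: 10.0 * ((-1) ** i) for i in range(n_years)}
        shifted = {y: v + c for y, v in deltas.items()}
        a = storage_trajectory(deltas, 500.0)
        b = storage_trajectory(shifted, 500.0)
        assert (b.cumulative_change_mmol_m2 - a.cumulative_change_mmol_m2
                ) == pytest.approx(c * n_years / 2, rel=1e-9, abs=1e-9)

    def test_invalid_stock_rejected(self):
        with pytest.raises(ValueError):
            storage_trajectory({2000: 1.0}, 0.0)


class TestSurplusAndLivestock:
    def test_surplus_examples(self):
        assert surplus_factor(9.7, 9.7) == pytest.approx(1.0)
        assert surplus_factor(19.4, 9.7) == pytest.approx(2.0)
        assert surplus_factor(1.26, 0.9) == pytest.approx(1.4)
        with pytest.raises(ValueError):
            surplus_factor(1.0, 0.0)

    def test_livestock_units_district_totals(self):
        assert int(livestock_units(1_069_900, 642_540)) == 1_172_706
        assert int(livestock_units(605_700, 512_840)) == 687_754
        assert livestock_units(0, 0) == 0.0
        decrease = 1 - livestock_units(605_700, 512_840) / livestock_units(
            1_069_900, 642_540)
        assert round(100 * decrease) == 41

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            livestock_units(-1, 0)


class TestScenarioProperties:
    def test_proton_load_tracks_nitrate_discharge(self, default_annual):
        """Year-to-year variation of the total proton load is dominated by
        nitrate discharge (high linear correlation on the default scenario)."""
        from ionbudget.trends import correlation_r2
        proton = proton_budget_series(default_annual)
        no3 = default_annual[(default_annual.compartment == "seepage40")
                             & (default_annual.species == "NO3")]
        merged = proton.merge(no3[["year", "flux_mmol_ie_m2"]], on="year")
        assert correlation_r2(merged["total_load"],
                              merged["flux_mmol_ie_m2"]) > 0.9

    def test_s_balance_series_matches_per_year_calls(self, default_annual):
        series = s_balance_series(default_annual)
        assert series[1985] == pytest.approx(annual_s_balance(default_annual, 1985))
        assert series[2020] == pytest.approx(annual_s_balance(default_annual, 2020))
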