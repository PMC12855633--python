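from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ionbudget import annual_fluxes, default_registry
from ionbudget.synthetic import MonitoringDataset, generate_scenario, hoeglwald_like


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded default-scenario dataset shared across tests."""
    return generate_scenario(hoeglwald_like(seed=1))


@pytest.fixture(scope="session")
def default_annual(default_dataset):
    return annual_fluxes(default_dataset)


def make_dataset(periods, daily_water, ground_truth=None) -> MonitoringDataset:
    """Build a small hand-specified dataset.

    ``periods``: list of (start, end, compartment, species, conc, pH);
    ``daily_water``: list of (date, compartment, mm).
    """
    chem = pd.DataFrame(
        periods,
        columns=["period_start", "period_end", "compartment", "species",
                 "concentration_ueq_per_L", "pH"],
    )
    chem["period_start"] = pd.to_datetime(chem["period_start"])
    chem["period_end"] = pd.to_datetime(chem["period_end"])
    water = pd.DataFrame(daily_water, columns=["date", "compartment", "water_mm"])
    water["date"] = pd.to_datetime(water["date"])
    return MonitoringDataset(chemistry=chem, water=water, ground_truth=ground_truth)


def constant_water(start, end, compartment, mm) -> list[tuple]:
    return [(d, compartment, mm) for d in pd.date_range(start, end, freq="D")]


def cubic_delta_series(x1=1988.2, x2=2016.4, x3=2030.0, a=-0.02,
                       years=np.arange(1985, 2021)):
    """A cubic delta-S trend crossing −50 downward at x1 and upward at x2."""
    years = np.asarray(years, dtype=float)
    values = -50.0 + a * (years - x1) * (years - x2) * (years - x3)
    return years, values
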