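"""Proton and sulfur budgets of the topsoil from annual input/output fluxes.

Proton budget
-------------
Nitrogen turnover dominates the acid load of the topsoil. Counting protons
per transformed mol of N — one consumed per nitrate taken up or denitrified,
one consumed per ammonium formed by ammonification, one released per
ammonium taken up or nitrified, and one additional released per nitrate
formed from ammonium — and eliminating the unobservable process rates via
the two N mass balances leaves a closed form in the four measured fluxes::

    H⁺(N) = (NH₄⁺_in − NH₄⁺_out) + (NO₃⁻_out − NO₃⁻_in)

with inputs in throughfall and outputs in seepage, all in mmol_IE m⁻² yr⁻¹.
Net proton consumption (negative values) is possible and reported as-is.
The total proton load adds the direct H⁺ input with throughfall; the
buffered percentage compares it with the H⁺ output at 40 cm.

Sulfur storage
--------------
The topsoil sulfur balance is throughfall sulfate input minus seepage
sulfate output. Cumulative deltas run against an initial stock measured in
mmol of element, so charge-equivalent deltas are divided by |z| = 2 before
summation; both unit labels are kept in the outputs to keep this auditable.
Net tree S uptake (≈5.5 mmol_IE m⁻² yr⁻¹) and litterfall are excluded by
default (they cancel in the long run) but an optional uptake term exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fluxes import _flux_lookup

__all__ = [
    "ProtonBudget",
    "StorageTrajectory",
    "n_transformation_proton_load",
    "proton_budget",
    "proton_budget_series",
    "annual_s_balance",
    "s_balance_series",
    "storage_trajectory",
    "surplus_factor",
    "livestock_units",
    "DEFAULT_LIVESTOCK_COEFFICIENTS",
]


@dataclass(frozen=True)
class ProtonBudget:
    """One year of the topsoil proton budget (mmol_IE m⁻² yr⁻¹)."""

    year: int
    direct_input: float            # H⁺ in throughfall
    n_transformation_load: float   # protons from N turnover (closed form)
    seepage_output: float          # H⁺ at 40 cm
    total_load: float = field(init=False)
    buffered_percent: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.direct_input + self.n_transformation_load
        object.__setattr__(self, "total_load", total)
        buffered = (100.0 * (total - self.seepage_output) / total
                    if total > 0 else math.nan)
        object.__setattr__(self, "buffered_percent", buffered)


def n_transformation_proton_load(
    nh4_in: float, nh4_out: float, no3_in: float, no3_out: float
) -> float:
    """Net proton production by N transformations (mmol_IE m⁻² yr⁻¹).

    Closed form ``(nh4_in − nh4_out) + (no3_out − no3_in)``. For any
    nonnegative process rates n (nitrification), u_a (NH₄ uptake), u_n
    (NO₃ uptake + denitrification) and m (ammonification) consistent with
    the mass balances ``nh4_out = nh4_in + m − n − u_a`` and
    ``no3_out = no3_in + n − u_n``, the rule-level sum
    ``2n + u_a − u_n − m`` equals this closed form identically — the
    process rates cancel. Negative results mean net proton consumption.
    """
    for name, v in (("nh4_in", nh4_in), ("nh4_out", nh4_out),
                    ("no3_in", no3_in), ("no3_out", no3_out)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0 (got {v})")
    return (nh4_in - nh4_out) + (no3_out - no3_in)


def proton_budget(table: pd.DataFrame, year: int) -> ProtonBudget:
    """Assemble the proton budget of one year from an annual-flux table."""
    return ProtonBudget(
        year=year,
        direct_input=_flux_lookup(table, year, "throughfall", "H"),
        n_transformation_load=n_transformation_proton_load(
            nh4_in=_flux_lookup(table, year, "throughfall", "NH4"),
            nh4_out=_flux_lookup(table, year, "seepage40", "NH4"),
            no3_in=_flux_lookup(table, year, "throughfall", "NO3"),
            no3_out=_flux_lookup(table, year, "seepage40", "NO3"),
        ),
        seepage_output=_flux_lookup(table, year, "seepage40", "H"),
    )


def proton_budget_series(table: pd.DataFrame) -> pd.DataFrame:
    """Proton budgets for every year present in the table, as a DataFrame."""
    years = sorted(table["year"].unique())
    rows = []
    for year in years:
        b = proton_budget(table, int(year))
        rows.append({
            "year": b.year, "direct_input": b.direct_input,
            "n_transformation_load": b.n_transformation_load,
            "total_load": b.total_load, "seepage_output": b.seepage_output,
            "buffered_percent": b.buffered_percent,
        })
    return pd.DataFrame(rows)


def annual_s_balance(table: pd.DataFrame, year: int) -> float:
    """delta_S of one year: throughfall SO₄ − seepage SO₄ (mmol_IE m⁻²).

    Negative values mean the soil is losing sulfur with the seepage water.
    """
    return (_flux_lookup(table, year, "throughfall", "SO4")
            - _flux_lookup(table, year, "seepage40", "SO4"))


def s_balance_series(table: pd.DataFrame) -> pd.Series:
    """delta_S for every year in the table (mmol_IE m⁻², indexed by year)."""
    years = sorted(table["year"].unique())
    return pd.Series({int(y): annual_s_balance(table, int(y)) for y in years},
                     name="delta_s_mmol_ie_m2")


@dataclass(frozen=True)
class StorageTrajectory:
    """Cumulative topsoil sulfur storage against an initial element stock.

    ``table`` columns: year, delta_mmol_ie_m2, delta_mmol_m2 (element basis,
    = delta_IE / |z|), cumulative_mmol_m2, remaining_stock_mmol_m2,
    remaining_fraction_percent.
    """

    table: pd.DataFrame
    initial_stock_mmol_m2: float
    stock_exhausted: bool

    @property
    def cumulative_change_mmol_m2(self) -> float:
        return float(self.table["cumulative_mmol_m2"].iloc[-1])

    @property
    def remaining_stock_mmol_m2(self) -> float:
        return float(self.table["remaining_stock_mmol_m2"].iloc[-1])

    @property
    def remaining_fraction_percent(self) -> float:
        return float(self.table["remaining_fraction_percent"].iloc[-1])


def storage_trajectory(
    deltas_mmol_ie_m2: Mapping[int, float] | pd.Series,
    initial_stock_mmol_m2: float,
    charge: int = 2,
    uptake_mmol_ie_m2_yr: float = 0.0,
) -> StorageTrajectory:
    """Cumulative S storage from annual charge-equivalent deltas.

    Deltas (mmol_IE m⁻²) are divided by ``charge`` (2 for sulfate) to the
    element-molar basis before summation against ``initial_stock_mmol_m2``
    (mmol element m⁻²). An optional net tree uptake (mmol_IE m⁻² yr⁻¹) is
    subtracted from every delta. The stock is never clamped: a remaining
    stock below zero is reported and flagged ``stock_exhausted``.
    """
    if initial_stock_mmol_m2 <= 0:
        raise ValueError("initial stock must be > 0")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    deltas = pd.Series(dict(deltas_mmol_ie_m2)).sort_index().astype(float)
    if deltas.empty:
        raise ValueError("need at least one annual delta")
    delta_ie = deltas - uptake_mmol_ie_m2_yr
    delta_mol = delta_ie / charge
    cumulative = delta_mol.cumsum()
    remaining = initial_stock_mmol_m2 + cumulative
    table = pd.DataFrame({
        "year": deltas.index.astype(int),
        "delta_mmol_ie_m2": delta_ie.to_numpy(),
        "delta_mmol_m2": delta_mol.to_numpy(),
        "cumulative_mmol_m2": cumulative.to_numpy(),
        "remaining_stock_mmol_m2": remaining.to_numpy(),
        "remaining_fraction_percent": 100.0 * remaining.to_numpy() / initial_stock_mmol_m2,
    })
    return StorageTrajectory(
        table=table,
        initial_stock_mmol_m2=float(initial_stock_mmol_m2),
        stock_exhausted=bool((remaining <= 0).any()),
    )


def surplus_factor(annual_deposition: float, annual_demand: float) -> float:
    """Deposition ÷ stand demand, both in one unit (dimensionless).

    A factor above 1 means atmospheric input exceeds what the stand can
    incorporate; e.g. a late-series sulfur deposition of 1.26 kg ha⁻¹ yr⁻¹
    against a demand of 0.9 kg ha⁻¹ yr⁻¹ is a surplus factor of 1.4.
    """
    if annual_demand <= 0:
        raise ValueError("demand must be > 0")
    if annual_deposition < 0:
        raise ValueError("deposition must be >= 0")
    return annual_deposition / annual_demand


DEFAULT_LIVESTOCK_COEFFICIENTS: Mapping[str, float] = {"cattle": 1.0, "pigs": 0.16}


def livestock_units(
    cattle: float,
    pigs: float,
    coefficients: Mapping[str, float] | Sequence[float] | None = None,
) -> float:
    """Livestock units: Σ head count × per-head coefficient.

    Default coefficients weight cattle 1.0 and pigs 0.16 — the values that
    reproduce published district totals from the head counts to < 1 unit.
    """
    if cattle < 0 or pigs < 0:
        raise ValueError("head counts must be >= 0")
    if coefficients is None:
        coefficients = DEFAULT_LIVESTOCK_COEFFICIENTS
    if isinstance(coefficients, Mapping):
        c_cattle, c_pigs = coefficients["cattle"], coefficients["pigs"]
    else:
        c_cattle, c_pigs = coefficients
    if c_cattle <= 0 or c_pigs <= 0:
        raise ValueError("coefficients must be > 0")
    return cattle * c_cattle + pigs * c_pigs
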