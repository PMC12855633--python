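"""Annual ion fluxes from sampling-period chemistry and daily water fluxes.

The flux model of intensive forest monitoring: per sampling period, the ion
flux is the mean solute concentration of the period multiplied by the sum of
the daily water fluxes of that period. Annual fluxes are the sum of the
period fluxes assigned to the calendar year; a period spanning a year
boundary is split pro-rata by the water falling in each year, which keeps
annual fluxes exactly additive in their period contributions.

Missing concentrations are filled by linear interpolation in time between
neighbouring periods of the same compartment/species (nearest value at the
endpoints); water fluxes are never interpolated. Years whose water-weighted
interpolated share exceeds 25% are flagged low-confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .species import SpeciesRegistry, default_registry
from .synthetic import COMPARTMENTS, MonitoringDataset

__all__ = [
    "period_flux",
    "annual_fluxes",
    "dry_deposition_estimate",
    "cation_anion_balance",
    "ChargeBalance",
]

LOW_CONFIDENCE_INTERPOLATED_FRACTION = 0.25


def period_flux(mean_concentration_ueq_l: float, daily_water_mm: Sequence[float]) -> float:
    """Ion flux of one sampling period in mmol_IE m⁻².

    concentration (µmol_IE L⁻¹) × Σ daily water (mm = L m⁻²) × 10⁻³.
    Linear in both arguments.
    """
    if mean_concentration_ueq_l < 0:
        raise ValueError("concentration must be >= 0")
    water = np.asarray(daily_water_mm, dtype=float)
    if water.size == 0:
        raise ValueError("period must contain at least one day")
    if (water < 0).any():
        raise ValueError("daily water fluxes must be >= 0")
    return float(mean_concentration_ueq_l * water.sum() * 1e-3)


def _h_rows_from_ph(chem: pd.DataFrame) -> pd.DataFrame:
    """Derive per-period H⁺ concentration rows (µmol_IE L⁻¹) from pH."""
    per_period = chem.drop_duplicates(["compartment", "period_start"])[
        ["period_start", "period_end", "compartment", "pH"]
    ].copy()
    per_period = per_period[per_period.groupby("compartment")["pH"].transform(
        lambda s: s.notna().any())]
    per_period["species"] = "H"
    per_period["concentration_ueq_per_L"] = 10.0 ** (-per_period["pH"]) * 1e6
    return per_period.drop(columns="pH")


def annual_fluxes(
    dataset: MonitoringDataset,
    include_h_from_ph: bool = True,
) -> pd.DataFrame:
    """Annual ion fluxes per (year, compartment, species).

    Returns a table with columns ``year, compartment, species,
    flux_mmol_ie_m2, n_periods, interpolated_fraction, low_confidence``.
    If ``include_h_from_ph`` is set, H⁺ is derived from the pH column
    (activity = concentration) for every compartment that reports pH.
    """
    chem = dataset.chemistry.copy()
    if chem.empty:
        raise ValueError("empty chemistry table")
    chem["period_start"] = pd.to_datetime(chem["period_start"])
    chem["period_end"] = pd.to_datetime(chem["period_end"])

    parts = [chem[["period_start", "period_end", "compartment", "species",
                   "concentration_ueq_per_L"]]]
    if include_h_from_ph and "pH" in chem.columns:
        h_rows = _h_rows_from_ph(chem)
        if not h_rows.empty:
            parts.append(h_rows[["period_start", "period_end", "compartment",
                                 "species", "concentration_ueq_per_L"]])
    chem = pd.concat(parts, ignore_index=True)

    water = dataset.water.copy()
    water["date"] = pd.to_datetime(water["date"])
    if water.duplicated(["date", "compartment"]).any():
        raise ValueError("duplicate (date, compartment) rows in water fluxes")
    if (water["water_mm"] < 0).any():
        raise ValueError("daily water fluxes must be >= 0")

    records: list[dict] = []
    for (comp, sp), grp in chem.groupby(["compartment", "species"], sort=True):
        grp = grp.sort_values("period_start").reset_index(drop=True)
        starts = grp["period_start"]
        ends = grp["period_end"]
        if (starts.iloc[1:].values <= ends.iloc[:-1].values).any():
            raise ValueError(f"{comp}/{sp}: overlapping or unsorted sampling periods")

        conc = grp["concentration_ueq_per_L"].to_numpy(dtype=float)
        missing = ~np.isfinite(conc)
        if missing.all():
            raise ValueError(f"{comp}/{sp}: no non-missing concentrations in the series")
        if (conc[~missing] < 0).any():
            raise ValueError(f"{comp}/{sp}: negative concentration")
        if missing.any():
            mid = (starts + (ends - starts) / 2).astype("int64").to_numpy(dtype=float)
            conc = conc.copy()
            conc[missing] = np.interp(mid[missing], mid[~missing], conc[~missing])

        w = water[water["compartment"] == comp]
        if w.empty:
            raise ValueError(f"no water fluxes for compartment {comp!r}")
        dates = w["date"].to_numpy()
        mm = w["water_mm"].to_numpy(dtype=float)
        # Map each water day onto its sampling period (contiguous coverage).
        idx = np.searchsorted(starts.to_numpy(), dates, side="right") - 1
        in_span = (dates >= starts.iloc[0].to_numpy()) & (dates <= ends.iloc[-1].to_numpy())
        if not in_span.all():
            warnings.warn(
                f"{comp}/{sp}: {int((~in_span).sum())} water days outside the "
                "chemistry span were ignored", stacklevel=2)
        covered = in_span & (dates <= ends.to_numpy()[np.clip(idx, 0, len(grp) - 1)])
        if (in_span & ~covered).any():
            raise ValueError(f"{comp}/{sp}: water days fall in a gap between periods")

        idx_c = idx[covered]
        mm_c = mm[covered]
        years = pd.DatetimeIndex(dates[covered]).year.to_numpy()
        day_flux = conc[idx_c] * mm_c * 1e-3
        interp_day = missing[idx_c]

        df = pd.DataFrame({
            "year": years, "flux": day_flux, "water": mm_c,
            "interp_water": np.where(interp_day, mm_c, 0.0),
            "period": idx_c,
        })
        agg = df.groupby("year").agg(
            flux_mmol_ie_m2=("flux", "sum"),
            water=("water", "sum"),
            interp_water=("interp_water", "sum"),
            n_periods=("period", "nunique"),
        ).reset_index()
        agg["interpolated_fraction"] = np.where(
            agg["water"] > 0, agg["interp_water"] / agg["water"], 0.0)
        for row in agg.itertuples():
            records.append({
                "year": int(row.year), "compartment": comp, "species": sp,
                "flux_mmol_ie_m2": float(row.flux_mmol_ie_m2),
                "n_periods": int(row.n_periods),
                "interpolated_fraction": float(row.interpolated_fraction),
            })

    out = pd.DataFrame(records).sort_values(
        ["year", "compartment", "species"]).reset_index(drop=True)
    out["low_confidence"] = out["interpolated_fraction"] > LOW_CONFIDENCE_INTERPOLATED_FRACTION
    return out


def _flux_lookup(table: pd.DataFrame, year: int, compartment: str, species: str) -> float:
    sel = table[(table["year"] == year) & (table["compartment"] == compartment)
                & (table["species"] == species)]
    if sel.empty:
        raise KeyError(f"no flux for year={year}, compartment={compartment!r}, "
                       f"species={species!r}")
    return float(sel["flux_mmol_ie_m2"].iloc[0])


def dry_deposition_estimate(table: pd.DataFrame, species: str) -> pd.DataFrame:
    """Per-year dry deposition proxy: throughfall − bulk flux (mmol_IE m⁻² yr⁻¹).

    For ions that are not exchanged with the canopy (sulfate, largely also
    ammonium in polluted conditions) the excess of throughfall over bulk
    precipitation is attributable to dry deposition of gases, aerosols and
    dust. Negative differences are reported as-is and flagged.
    """
    tf = table[(table["compartment"] == "throughfall") & (table["species"] == species)]
    bulk = table[(table["compartment"] == "bulk") & (table["species"] == species)]
    if tf.empty or bulk.empty:
        raise ValueError(f"{species}: need both throughfall and bulk fluxes")
    merged = pd.merge(
        tf[["year", "flux_mmol_ie_m2"]], bulk[["year", "flux_mmol_ie_m2"]],
        on="year", suffixes=("_throughfall", "_bulk"))
    merged["dry_deposition_mmol_ie_m2"] = (
        merged["flux_mmol_ie_m2_throughfall"] - merged["flux_mmol_ie_m2_bulk"])
    merged["negative"] = merged["dry_deposition_mmol_ie_m2"] < 0
    return merged[["year", "dry_deposition_mmol_ie_m2", "negative"]]


@dataclass(frozen=True)
class ChargeBalance:
    """Cation/anion sums (mmol_IE) and each cation's share of the cation sum."""

    cation_sum: float
    anion_sum: float
    relative_imbalance: float  # (Σcat − Σan)/(Σcat + Σan), the usual balance error
    cation_shares: Mapping[str, float]


def cation_anion_balance(
    table: pd.DataFrame,
    year: int,
    compartment: str,
    registry: SpeciesRegistry | None = None,
) -> ChargeBalance:
    """Charge balance of one compartment-year: anions leaving with seepage
    must be accompanied by an equivalent cation load."""
    registry = registry or default_registry()
    sel = table[(table["year"] == year) & (table["compartment"] == compartment)]
    if sel.empty:
        raise ValueError(f"no fluxes for year={year}, compartment={compartment!r}")
    cat = {}
    an = {}
    for row in sel.itertuples():
        sp = registry[row.species]
        if sp.charge > 0:
            cat[sp.name] = float(row.flux_mmol_ie_m2)
        elif sp.charge < 0:
            an[sp.name] = float(row.flux_mmol_ie_m2)
    if not cat or not an:
        raise ValueError(
            f"year={year}, compartment={compartment!r}: need both cations and "
            f"anions (got cations={sorted(cat)}, anions={sorted(an)})")
    cat_sum = sum(cat.values())
    an_sum = sum(an.values())
    shares = {name: v / cat_sum for name, v in cat.items()} if cat_sum > 0 else {}
    return ChargeBalance(
        cation_sum=cat_sum,
        anion_sum=an_sum,
        relative_imbalance=(cat_sum - an_sum) / (cat_sum + an_sum),
        cation_shares=shares,
    )
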