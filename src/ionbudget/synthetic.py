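"""Seeded synthetic monitoring data with known ground truth.

No public archive holds a 36-year record of biweekly solution chemistry plus
daily water fluxes for one forest stand, so the package ships a generator
that emulates the *structure* of such a record: three compartments (bulk
precipitation on an open plot, throughfall under the canopy, seepage at
40 cm), ~biweekly sampling periods covering every day, strongly declining
sulfate and ammonium throughfall, roughly flat nitrate, high inter-annual
seepage variability, and drought years with sharply reduced seepage.

Every dataset carries the ground-truth annual fluxes it was built from, so
downstream modules can be tested by parameter recovery instead of against
unavailable observations. The generator is fully deterministic: one seed and
one config give a bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("bulk", "throughfall", "seepage40")

__all__ = [
    "COMPARTMENTS",
    "TrendSpec",
    "ScenarioConfig",
    "MonitoringDataset",
    "hoeglwald_like",
    "generate_scenario",
    "inject_dry_years",
    "generate_emission_series",
]


@dataclass(frozen=True)
class TrendSpec:
    """Annual-flux trend for one (compartment, species): start → end value.

    ``shape`` is ``"linear"`` or ``"exponential-decay"`` (geometric
    interpolation between the endpoints; requires both > 0).
    """

    start: float
    end: float
    shape: str = "linear"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValueError("trend endpoints must be >= 0")
        if self.shape not in ("linear", "exponential-decay"):
            raise ValueError(f"unknown trend shape {self.shape!r}")
        if self.shape == "exponential-decay" and (self.start <= 0 or self.end <= 0):
            raise ValueError("exponential-decay needs strictly positive endpoints")

    def value(self, frac: float) -> float:
        """Trend value at fractional position ``frac`` in [0, 1] of the span."""
        if self.shape == "linear":
            return self.start + (self.end - self.start) * frac
        return self.start * (self.end / self.start) ** frac


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines a synthetic monitoring scenario.

    Noise enters in two seeded places, both proportional to
    ``concentration_cv`` so that cv = 0 gives an exactly noise-free record:
    a multiplicative lognormal per sampling period (concentrations are
    positive and right-skewed) and a yearly lognormal factor per compartment
    scaled by ``annual_variability_factor`` (seepage chemistry varies far
    more between years than deposition does).
    """

    start_year: int = 1985
    end_year: int = 2020
    sampling_interval_days: int = 14
    trends: Mapping[tuple[str, str], TrendSpec] = field(default_factory=dict)
    concentration_cv: float = 0.25
    annual_precip_mean_mm: float = 752.0
    annual_precip_cv: float = 0.15
    throughfall_fraction: float = 0.75
    seepage_fraction_normal: float = 0.35
    seepage_fraction_dry: float = 0.10
    dry_years: tuple[int, ...] = ()
    ph: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    ph_noise_factor: float = 0.4  # pH noise sd = factor * concentration_cv
    annual_variability_factor: Mapping[str, float] = field(
        default_factory=lambda: {"bulk": 0.2, "throughfall": 0.2, "seepage40": 0.8}
    )
    correlated_bulk_throughfall: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must be > start_year")
        if self.sampling_interval_days < 1:
            raise ValueError("sampling_interval_days must be >= 1")
        if self.concentration_cv < 0 or self.annual_precip_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if not 0 < self.throughfall_fraction <= 1:
            raise ValueError("throughfall_fraction must be in (0, 1]")
        for frac in (self.seepage_fraction_normal, self.seepage_fraction_dry):
            if not 0 < frac <= 1:
                raise ValueError("seepage fractions must be in (0, 1]")
        for year in self.dry_years:
            if not self.start_year <= year <= self.end_year:
                raise ValueError(f"dry year {year} outside span "
                                 f"{self.start_year}-{self.end_year}")
        for (comp, _sp), _trend in self.trends.items():
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r}")
        for comp in self.ph:
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r} in ph config")

    def year_frac(self, year: int) -> float:
        return (year - self.start_year) / (self.end_year - self.start_year)


def hoeglwald_like(seed: int = 0, **overrides) -> ScenarioConfig:
    """Default scenario: a 1985–2020 spruce-stand record.

    Deposition trends follow the reported endpoint fluxes (mmol_IE m⁻² yr⁻¹):
    throughfall SO₄ 160→10 and NH₄ 150→70 (exponential decline), NO₃ 70→60;
    bulk SO₄ 60→10, NH₄ 40→30, NO₃ 40→20. Seepage carries declining nitrate
    and sulfate plus the accompanying cation load dominated by aluminium.
    Precipitation averages 752 mm yr⁻¹ (cv 0.15, spanning roughly
    520–1050 mm); the drought years 1997, 2003 and 2018–2020 reduce the
    seepage fraction from 0.35 to 0.10 of bulk precipitation.
    """
    trends = {
        ("throughfall", "SO4"): TrendSpec(160.0, 10.0, "exponential-decay"),
        ("throughfall", "NH4"): TrendSpec(150.0, 70.0, "exponential-decay"),
        ("throughfall", "NO3"): TrendSpec(70.0, 60.0, "linear"),
        ("bulk", "SO4"): TrendSpec(60.0, 10.0, "exponential-decay"),
        ("bulk", "NH4"): TrendSpec(40.0, 30.0, "linear"),
        ("bulk", "NO3"): TrendSpec(40.0, 20.0, "linear"),
        ("seepage40", "SO4"): TrendSpec(150.0, 70.0, "linear"),
        ("seepage40", "NO3"): TrendSpec(250.0, 100.0, "linear"),
        ("seepage40", "NH4"): TrendSpec(8.0, 3.0, "linear"),
        ("seepage40", "Cl"): TrendSpec(120.0, 40.0, "linear"),
        ("seepage40", "Al"): TrendSpec(200.0, 80.0, "linear"),
        ("seepage40", "Ca"): TrendSpec(150.0, 60.0, "linear"),
        ("seepage40", "Mg"): TrendSpec(60.0, 25.0, "linear"),
        ("seepage40", "K"): TrendSpec(40.0, 20.0, "linear"),
    }
    ph = {
        "bulk": (4.4, 5.1),
        "throughfall": (4.6, 5.6),
        "seepage40": (4.45, 4.6),
    }
    cfg = ScenarioConfig(
        trends=trends,
        ph=ph,
        dry_years=(1997, 2003, 2018, 2019, 2020),
        seed=seed,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


@dataclass
class MonitoringDataset:
    """Synthetic (or loaded) monitoring data plus generator ground truth.

    ``chemistry``: period_start, period_end (inclusive dates), compartment,
    species, concentration_ueq_per_L, pH (repeated per species row of a
    period; NaN where not measured).

    ``water``: date, compartment, water_mm (daily).

    ``ground_truth``: year, compartment, species, flux_mmol_ie_m2 (realized
    annual flux the data were constructed to carry — what flux aggregation
    must reproduce exactly) and trend_mmol_ie_m2 (the configured noise-free
    trend; NaN for pH-derived H⁺). ``None`` for user-loaded data.
    """

    chemistry: pd.DataFrame
    water: pd.DataFrame
    ground_truth: pd.DataFrame | None = None

    def copy(self) -> "MonitoringDataset":
        return MonitoringDataset(
            self.chemistry.copy(),
            self.water.copy(),
            None if self.ground_truth is None else self.ground_truth.copy(),
        )


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _period_grid(year: int, interval: int) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Contiguous sampling periods covering the calendar year exactly."""
    start = pd.Timestamp(year=year, month=1, day=1)
    year_end = pd.Timestamp(year=year, month=12, day=31)
    periods = []
    while start <= year_end:
        end = min(start + pd.Timedelta(days=interval - 1), year_end)
        periods.append((start, end))
        start = end + pd.Timedelta(days=1)
    return periods


def generate_scenario(config: ScenarioConfig) -> MonitoringDataset:
    """Build the full synthetic dataset for ``config`` (deterministic in seed).

    Per year the annual precipitation is drawn, spread over rain-day weights,
    and partitioned into the three compartments; per-period concentrations
    are then set so their water-weighted sum reproduces the (noisy) annual
    flux. Drought years are applied afterwards via :func:`inject_dry_years`,
    which scales seepage water only — exactly as a dry summer cuts seepage
    without touching solution chemistry.
    """
    config.validate()
    years = range(config.start_year, config.end_year + 1)
    ss = np.random.SeedSequence(config.seed)
    children = dict(zip(("water", "bulk", "throughfall", "seepage40", "ph"), ss.spawn(5)))
    streams = {name: np.random.default_rng(child) for name, child in children.items()}
    if config.correlated_bulk_throughfall:
        # Bulk replays the throughfall stream from the start, so paired
        # species draw identical noise in the two compartments.
        streams["bulk"] = np.random.default_rng(children["throughfall"])

    comp_fraction = {
        "bulk": 1.0,
        "throughfall": config.throughfall_fraction,
        "seepage40": config.seepage_fraction_normal,
    }

    water_rows: list[dict] = []
    chem_rows: list[dict] = []
    gt_rows: list[dict] = []

    wrng = streams["water"]
    for year in years:
        frac = config.year_frac(year)
        periods = _period_grid(year, config.sampling_interval_days)
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        ndays = len(dates)
        precip = config.annual_precip_mean_mm * _lognormal_factors(
            wrng, config.annual_precip_cv, 1)[0]
        weights = wrng.gamma(shape=0.5, scale=1.0, size=ndays)
        daily_bulk = precip * weights / weights.sum()

        period_water: dict[str, np.ndarray] = {}
        day_period = np.searchsorted(
            [p[0].dayofyear for p in periods], dates.dayofyear, side="right") - 1
        for comp in COMPARTMENTS:
            daily = daily_bulk * comp_fraction[comp]
            for d, mm in zip(dates, daily):
                water_rows.append({"date": d, "compartment": comp, "water_mm": mm})
            sums = np.zeros(len(periods))
            np.add.at(sums, day_period, daily)
            period_water[comp] = sums

        prng = streams["ph"]
        for comp in COMPARTMENTS:
            rng = streams[comp]
            w_year = period_water[comp].sum()
            npd = len(periods)

            # pH per period (if configured for this compartment)
            ph_vals = np.full(npd, np.nan)
            if comp in config.ph:
                ph_start, ph_end = config.ph[comp]
                base = ph_start + (ph_end - ph_start) * frac
                noise_sd = config.ph_noise_factor * config.concentration_cv
                ph_vals = base + (prng.normal(0.0, noise_sd, npd) if noise_sd > 0
                                  else np.zeros(npd))
                ph_vals = np.clip(ph_vals, 2.5, 9.0)

            species_here = [sp for (c, sp) in config.trends if c == comp]
            annual_cv = config.concentration_cv * config.annual_variability_factor.get(comp, 0.0)
            for sp in species_here:
                trend = config.trends[(comp, sp)]
                target = trend.value(frac)
                a = _lognormal_factors(rng, annual_cv, 1)[0]
                m = _lognormal_factors(rng, config.concentration_cv, npd)
                conc = target * 1000.0 / w_year * a * m  # µmol_IE L⁻¹
                realized = float(np.sum(conc * period_water[comp]) * 1e-3)
                for (p0, p1), c, ph_v in zip(periods, conc, ph_vals):
                    chem_rows.append({
                        "period_start": p0, "period_end": p1, "compartment": comp,
                        "species": sp, "concentration_ueq_per_L": c,
                        "pH": ph_v,
                    })
                gt_rows.append({
                    "year": year, "compartment": comp, "species": sp,
                    "flux_mmol_ie_m2": realized, "trend_mmol_ie_m2": target,
                })

            if comp in config.ph:
                h_conc = 10.0 ** (-ph_vals) * 1e6  # µmol_IE L⁻¹
                h_flux = float(np.sum(h_conc * period_water[comp]) * 1e-3)
                gt_rows.append({
                    "year": year, "compartment": comp, "species": "H",
                    "flux_mmol_ie_m2": h_flux, "trend_mmol_ie_m2": np.nan,
                })

    dataset = MonitoringDataset(
        chemistry=pd.DataFrame(chem_rows),
        water=pd.DataFrame(water_rows),
        ground_truth=pd.DataFrame(gt_rows),
    )
    if config.dry_years:
        multiplier = config.seepage_fraction_dry / config.seepage_fraction_normal
        dataset = inject_dry_years(dataset, config.dry_years, multiplier)
    return dataset


def inject_dry_years(
    dataset: MonitoringDataset,
    years: Sequence[int],
    seepage_multiplier: float,
) -> MonitoringDataset:
    """Scale daily seepage water in ``years`` by ``seepage_multiplier`` (< 1).

    Chemistry is untouched, so every seepage ion flux of those years scales
    by exactly the multiplier (the period flux is linear in water).
    """
    if not 0 <= seepage_multiplier < 1:
        raise ValueError("seepage_multiplier must be in [0, 1)")
    out = dataset.copy()
    data_years = out.water["date"].dt.year
    span = (int(data_years.min()), int(data_years.max()))
    for year in years:
        if not span[0] <= year <= span[1]:
            raise ValueError(f"dry year {year} outside data span {span}")
    mask = (out.water["compartment"] == "seepage40") & data_years.isin(list(years))
    out.water.loc[mask, "water_mm"] *= seepage_multiplier
    if out.ground_truth is not None:
        gmask = (out.ground_truth["compartment"] == "seepage40") & (
            out.ground_truth["year"].isin(list(years)))
        out.ground_truth.loc[gmask, "flux_mmol_ie_m2"] *= seepage_multiplier
    return out


def generate_emission_series(
    nodes: Mapping[str, Sequence[tuple[int, float]]],
    source: str = "synthetic",
) -> pd.DataFrame:
    """Annual emission series (Gmol yr⁻¹) interpolating piecewise-linear nodes.

    ``nodes`` maps gas → ordered (year, Gmol) breakpoints; the output hits
    every node exactly and interpolates linearly between them. A single node
    yields a constant (one-year) series.
    """
    rows: list[dict] = []
    for gas, pts in nodes.items():
        if len(pts) == 0:
            raise ValueError(f"{gas}: need at least one node")
        yrs = [int(y) for y, _ in pts]
        vals = [float(v) for _, v in pts]
        if any(b <= a for a, b in zip(yrs, yrs[1:])):
            raise ValueError(f"{gas}: node years must be strictly increasing")
        if any(v < 0 for v in vals):
            raise ValueError(f"{gas}: amounts must be >= 0")
        grid = np.arange(yrs[0], yrs[-1] + 1)
        interp = np.interp(grid, yrs, vals)
        for y, v in zip(grid, interp):
            rows.append({"year": int(y), "gas": gas, "amount_gmol": float(v),
                         "source": source})
    return pd.DataFrame(rows)
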