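"""CSV schemas, pipeline configuration and the end-to-end pipeline.

Interchange format: comma-separated UTF-8 with "." decimals, ISO-8601
dates, and concentrations in µeq L⁻¹ (= µmol_IE L⁻¹, the package's internal
charge-equivalent currency). Every table written by the package starts with
a schema-version comment line (``# ionbudget-schema: <name>-<version>``);
readers tolerate and skip such comment lines.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import budgets, fluxes, trends
from .species import SpeciesRegistry, default_registry
from .synthetic import (
    COMPARTMENTS,
    MonitoringDataset,
    ScenarioConfig,
    TrendSpec,
    generate_scenario,
    hoeglwald_like,
)

logger = logging.getLogger("ionbudget")

__all__ = [
    "SCHEMA_VERSIONS",
    "write_table",
    "read_table",
    "read_chemistry_csv",
    "read_waterflux_csv",
    "write_dataset",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]

SCHEMA_VERSIONS: Mapping[str, str] = {
    "chemistry": "chemistry-1",
    "water": "water-1",
    "ground_truth": "ground-truth-1",
    "annual_flux": "annual-flux-1",
    "proton_budget": "proton-budget-1",
    "s_trajectory": "s-trajectory-1",
    "trend_report": "trend-report-1",
    "emissions": "emissions-1",
}

_CHEM_COLUMNS = ["period_start", "period_end", "compartment", "species",
                 "concentration_ueq_per_L", "pH"]
_WATER_COLUMNS = ["date", "compartment", "water_mm"]


def write_table(df: pd.DataFrame, path, schema: str) -> Path:
    """Write a CSV with the schema-version header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# ionbudget-schema: {SCHEMA_VERSIONS[schema]}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path, schema: str | None = None, **kwargs) -> pd.DataFrame:
    """Read a package CSV, skipping schema comment lines (and checking the
    schema name when one is expected)."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if schema is not None and first.startswith("# ionbudget-schema:"):
        found = first.split(":", 1)[1].strip()
        expected = SCHEMA_VERSIONS[schema]
        if found != expected:
            raise ValueError(f"{path}: schema {found!r}, expected {expected!r}")
    return pd.read_csv(path, comment="#", **kwargs)


def _data_row_offset(path: Path) -> int:
    """CSV line number (1-based) of the first data row, past comments+header."""
    offset = 1
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            offset += 1
            if not line.startswith("#"):
                return offset  # this line was the header
    return offset


def read_chemistry_csv(path, registry: SpeciesRegistry | None = None) -> pd.DataFrame:
    """Read and validate a sampling-chemistry CSV.

    Columns: period_start, period_end (ISO dates), compartment, species,
    concentration_ueq_per_L, pH (nullable). Errors name the offending CSV
    row. An empty file with a valid header yields an empty table with a
    warning.
    """
    path = Path(path)
    registry = registry or default_registry()
    df = read_table(path, schema="chemistry")
    missing = [c for c in _CHEM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: chemistry file has a valid header but no rows",
                      stacklevel=2)
        df["period_start"] = pd.to_datetime(df["period_start"])
        df["period_end"] = pd.to_datetime(df["period_end"])
        return df[_CHEM_COLUMNS]

    offset = _data_row_offset(path)

    def _bad_row(mask: pd.Series, reason: str) -> None:
        if mask.any():
            row = int(mask.idxmax()) + offset
            raise ValueError(f"{path}, row {row}: {reason}")

    for col in ("period_start", "period_end"):
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        _bad_row(parsed.isna() & df[col].notna(), f"non-ISO date in {col!r}")
        _bad_row(df[col].isna(), f"missing {col!r}")
        df[col] = parsed
    _bad_row(~df["compartment"].isin(COMPARTMENTS),
             f"unknown compartment (expected one of {COMPARTMENTS})")
    known = set(registry)
    _bad_row(~df["species"].isin(known), "unknown species")
    conc = pd.to_numeric(df["concentration_ueq_per_L"], errors="coerce")
    _bad_row(conc.notna() & (conc < 0), "negative concentration")
    df["concentration_ueq_per_L"] = conc
    df["pH"] = pd.to_numeric(df["pH"], errors="coerce")
    return df[_CHEM_COLUMNS]


def read_waterflux_csv(path) -> pd.DataFrame:
    """Read and validate a daily water-flux CSV (date, compartment, water_mm)."""
    path = Path(path)
    df = read_table(path, schema="water")
    missing = [c for c in _WATER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    offset = _data_row_offset(path)
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        row = int(parsed.isna().idxmax()) + offset
        raise ValueError(f"{path}, row {row}: non-ISO date")
    df["date"] = parsed
    dup = df.duplicated(["date", "compartment"])
    if dup.any():
        row = int(dup.idxmax()) + offset
        raise ValueError(f"{path}, row {row}: duplicate (date, compartment)")
    df["water_mm"] = pd.to_numeric(df["water_mm"])
    if (df["water_mm"] < 0).any():
        row = int((df["water_mm"] < 0).idxmax()) + offset
        raise ValueError(f"{path}, row {row}: negative water flux")
    for comp in df["compartment"].unique():
        dates = df.loc[df["compartment"] == comp, "date"].sort_values()
        gaps = dates.diff().dt.days.dropna()
        if (gaps > 1).any():
            warnings.warn(f"{path}: {comp} has {int((gaps > 1).sum())} gap(s) "
                          "in the daily record", stacklevel=2)
    return df[_WATER_COLUMNS]


def write_dataset(dataset: MonitoringDataset, outdir) -> dict[str, Path]:
    """Write a dataset to ``outdir``; ground truth goes to a sidecar file."""
    outdir = Path(outdir)
    chem = dataset.chemistry.copy()
    chem["period_start"] = pd.to_datetime(chem["period_start"]).dt.date
    chem["period_end"] = pd.to_datetime(chem["period_end"]).dt.date
    water = dataset.water.copy()
    water["date"] = pd.to_datetime(water["date"]).dt.date
    paths = {
        "chemistry": write_table(chem, outdir / "chemistry.csv", "chemistry"),
        "water": write_table(water, outdir / "water.csv", "water"),
    }
    if dataset.ground_truth is not None:
        paths["ground_truth"] = write_table(
            dataset.ground_truth, outdir / "ground_truth.csv", "ground_truth")
    return paths


def load_dataset(chemistry_path, water_path,
                 registry: SpeciesRegistry | None = None) -> MonitoringDataset:
    return MonitoringDataset(
        chemistry=read_chemistry_csv(chemistry_path, registry=registry),
        water=read_waterflux_csv(water_path),
        ground_truth=None,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one analysis run.

    Exactly one of (``scenario``) or (``chemistry_path`` and ``water_path``)
    must be set. Analysis constants default to the study-site values: an
    initial topsoil S stock of 2281.3 mmol m⁻² and stand demands of
    9.7 kg N and 0.9 kg S ha⁻¹ yr⁻¹.
    """

    scenario: ScenarioConfig | None = None
    chemistry_path: str | None = None
    water_path: str | None = None
    species_yaml: str | None = None
    initial_s_stock_mmol_m2: float = 2281.3
    n_demand_kg_ha_yr: float = 9.7
    s_demand_kg_ha_yr: float = 0.9
    s_uptake_mmol_ie_m2_yr: float = 0.0  # optional net tree uptake term
    degrees: Mapping[str, int] = field(default_factory=lambda: {
        "deposition": 4, "seepage": 5, "proton": 5, "delta_s": 3})
    threshold_rounding: str = "nearest10"
    fluctuation_percentile: float = 90.0
    outdir: str = "ionbudget_out"
    seed: int = 0

    def validate(self) -> None:
        has_paths = self.chemistry_path is not None or self.water_path is not None
        if self.scenario is not None and has_paths:
            raise ValueError("config must set either a scenario or data paths, not both")
        if self.scenario is None:
            if self.chemistry_path is None or self.water_path is None:
                raise ValueError("config needs a scenario block or both data paths")
            for p in (self.chemistry_path, self.water_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.initial_s_stock_mmol_m2 <= 0:
            raise ValueError("initial_s_stock_mmol_m2 must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        scenario = None
        if "scenario" in raw:
            block = dict(raw.pop("scenario") or {})
            use_default = block.pop("hoeglwald_like", True)
            trends_block = block.pop("trends", None)
            ph_block = block.pop("ph", None)
            if "dry_years" in block:
                block["dry_years"] = tuple(block["dry_years"])
            if trends_block is not None:
                block["trends"] = {
                    (comp, sp): TrendSpec(*spec)
                    for comp, species in trends_block.items()
                    for sp, spec in species.items()}
            if ph_block is not None:
                block["ph"] = {c: tuple(v) for c, v in ph_block.items()}
            scenario = (hoeglwald_like(**block) if use_default
                        else ScenarioConfig(**block))
        cfg = cls(scenario=scenario, **raw)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    summary: dict
    outputs: dict[str, Path]
    annual: pd.DataFrame
    proton: pd.DataFrame
    trajectory: budgets.StorageTrajectory


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage {name!r}: {exc}") from exc
            return False
    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all report files to ``config.outdir``.

    Stages: data (generate or load) → annual fluxes → proton budgets →
    sulfur trajectory → trends (delta-S window, deposition interpretability,
    proton-load/nitrate correlation) → summary JSON. A scenario-based run is
    fully reproducible from (config, seed).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = (SpeciesRegistry.from_yaml(config.species_yaml)
                if config.species_yaml else default_registry())
    logger.info("design flags: threshold_rounding=%s percentile=%s degrees=%s "
                "s_uptake=%s calendar-year aggregation",
                config.threshold_rounding, config.fluctuation_percentile,
                dict(config.degrees), config.s_uptake_mmol_ie_m2_yr)

    outputs: dict[str, Path] = {}
    with _stage("data"):
        if config.scenario is not None:
            scenario = replace(config.scenario, seed=config.seed)
            dataset = generate_scenario(scenario)
            outputs.update(write_dataset(dataset, outdir / "data"))
        else:
            dataset = load_dataset(config.chemistry_path, config.water_path,
                                   registry=registry)

    with _stage("fluxes"):
        annual = fluxes.annual_fluxes(dataset)
        outputs["annual_flux"] = write_table(annual, outdir / "annual_fluxes.csv",
                                             "annual_flux")

    with _stage("budgets"):
        proton = budgets.proton_budget_series(annual)
        outputs["proton_budget"] = write_table(
            proton, outdir / "proton_budget.csv", "proton_budget")
        deltas = budgets.s_balance_series(annual)
        trajectory = budgets.storage_trajectory(
            deltas, config.initial_s_stock_mmol_m2,
            uptake_mmol_ie_m2_yr=config.s_uptake_mmol_ie_m2_yr)
        outputs["s_trajectory"] = write_table(
            trajectory.table, outdir / "s_trajectory.csv", "s_trajectory")

    with _stage("trends"):
        years = deltas.index.to_numpy(dtype=float)
        fit_delta = trends.fit_polynomial(years, deltas.to_numpy(),
                                          config.degrees["delta_s"])
        threshold = trends.fluctuation_threshold(fit_delta, config.threshold_rounding)
        window = trends.detect_remobilization_window(fit_delta, threshold)

        trend_rows = [{
            "series": "delta_s", "degree": fit_delta.degree, "mae": fit_delta.mae,
            "threshold": threshold,
            "window_start": None if window is None else window.start_year,
            "window_end": None if window is None else window.end_year,
            "interpretable": None,
        }]
        interpretable_flags: dict[str, bool] = {}
        for comp in ("bulk", "throughfall"):
            for sp in ("SO4", "NH4", "NO3"):
                sel = annual[(annual["compartment"] == comp) & (annual["species"] == sp)]
                if sel.empty:
                    continue
                fit = trends.fit_polynomial(
                    sel["year"].to_numpy(dtype=float),
                    sel["flux_mmol_ie_m2"].to_numpy(),
                    config.degrees["deposition"])
                ok, _diag = trends.endpoint_change_interpretable(
                    fit, config.fluctuation_percentile)
                interpretable_flags[f"{comp}:{sp}"] = ok
                trend_rows.append({
                    "series": f"{comp}:{sp}", "degree": fit.degree, "mae": fit.mae,
                    "threshold": None, "window_start": None, "window_end": None,
                    "interpretable": ok,
                })
        outputs["trend_report"] = write_table(
            pd.DataFrame(trend_rows), outdir / "trend_report.csv", "trend_report")

        no3_out = annual[(annual["compartment"] == "seepage40")
                         & (annual["species"] == "NO3")].set_index("year")[
            "flux_mmol_ie_m2"]
        aligned = proton.set_index("year").join(no3_out.rename("no3"), how="inner")
        r2 = trends.correlation_r2(aligned["total_load"], aligned["no3"])

    with _stage("summary"):
        first5 = proton["buffered_percent"].iloc[:5].mean()
        last5 = proton["buffered_percent"].iloc[-5:].mean()
        summary = {
            "schema": "ionbudget-summary-1",
            "seed": config.seed,
            "years": [int(deltas.index.min()), int(deltas.index.max())],
            "initial_s_stock_mmol_m2": config.initial_s_stock_mmol_m2,
            "cumulative_s_change_mmol_m2": trajectory.cumulative_change_mmol_m2,
            "remaining_s_stock_mmol_m2": trajectory.remaining_stock_mmol_m2,
            "remaining_s_fraction_percent": trajectory.remaining_fraction_percent,
            "stock_exhausted": trajectory.stock_exhausted,
            "buffered_percent_first5_mean": float(first5),
            "buffered_percent_last5_mean": float(last5),
            "delta_s_mae_mmol_ie_m2": fit_delta.mae,
            "fluctuation_threshold_mmol_ie_m2": threshold,
            "remobilization_window": None if window is None else {
                "start_year": window.start_year, "end_year": window.end_year,
                "duration_years": window.duration},
            "r2_proton_load_vs_no3_seepage": r2,
            "interpretable_trends": interpretable_flags,
            "design_flags": {
                "year_basis": "calendar",
                "threshold_rounding": config.threshold_rounding,
                "fluctuation_percentile": config.fluctuation_percentile,
                "degrees": dict(config.degrees),
                "s_uptake_mmol_ie_m2_yr": config.s_uptake_mmol_ie_m2_yr,
            },
        }
        path = outdir / "summary.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs["summary"] = path

    return PipelineResult(summary=summary, outputs=outputs, annual=annual,
                          proton=proton, trajectory=trajectory)
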