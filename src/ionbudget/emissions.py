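"""Emission-inventory harmonization and molar S/N ratios.

National emission series come in kilotonnes of gas per year from several
sources and territories (pre-unification West/East German inventories,
historical reconstructions). For element bookkeeping everything is moved to
a molecule-molar basis (Gmol yr⁻¹; NOₓ expressed as NO₂ by convention),
historical series are anchored to the first inventory year, territories are
summed year-wise, and the emission S/N ratio is SO₂ / (NH₃ + NOₓ) on the
molar basis.
"""

from __future__ import annotations

import pandas as pd

from .species import SpeciesRegistry, default_registry

__all__ = [
    "mass_to_molar_emissions",
    "harmonize_historical",
    "combine_territories",
    "emission_sn_ratio",
]

_REQUIRED_GASES = ("SO2", "NH3", "NOx")


def mass_to_molar_emissions(
    amount_kt_per_yr: float,
    gas: str,
    registry: SpeciesRegistry | None = None,
) -> float:
    """Convert a gas emission from kt yr⁻¹ to Gmol yr⁻¹.

    kt × 10⁹ g ÷ (g mol⁻¹) ÷ 10⁹ mol Gmol⁻¹ = kt / molar mass; 64.07 kt of
    SO₂ is exactly 1 Gmol. NOₓ uses M(NO₂) = 46.006 unless the registry is
    overridden.
    """
    if amount_kt_per_yr < 0:
        raise ValueError("emission amount must be >= 0")
    registry = registry or default_registry()
    return amount_kt_per_yr / registry.gas_molar_mass(gas)


def harmonize_historical(
    historical: pd.Series,
    inventory: pd.Series,
    anchor_year: int,
) -> pd.Series:
    """Splice a historical series onto an inventory at ``anchor_year``.

    The historical series is scaled by ``inventory[anchor] /
    historical[anchor]`` so the two agree at the anchor; the output uses the
    scaled historical values before the anchor and the inventory from the
    anchor on. Idempotent on an already-anchored series.
    """
    for name, s in (("historical", historical), ("inventory", inventory)):
        if anchor_year not in s.index:
            raise ValueError(f"{name} series does not contain anchor year {anchor_year}")
    if historical.loc[anchor_year] == 0:
        raise ValueError("historical anchor value is zero; cannot scale")
    scale = inventory.loc[anchor_year] / historical.loc[anchor_year]
    pre = historical.loc[historical.index < anchor_year] * scale
    post = inventory.loc[inventory.index >= anchor_year]
    return pd.concat([pre, post]).sort_index()


def combine_territories(
    a: pd.Series,
    b: pd.Series,
    allow_partial: bool = False,
) -> pd.Series:
    """Year-wise sum of two territory series for the same gas.

    By default every year must be present in both series (a year covered by
    only one territory would silently understate the total);
    ``allow_partial=True`` restricts the output to the overlap instead.
    """
    overlap = a.index.intersection(b.index)
    if len(overlap) == 0:
        raise ValueError("territory series have disjoint year ranges")
    if not allow_partial:
        extra = a.index.symmetric_difference(b.index)
        if len(extra) > 0:
            raise ValueError(
                f"years {sorted(extra)} are covered by only one territory; "
                "pass allow_partial=True to sum over the overlap only")
    return (a.loc[overlap] + b.loc[overlap]).sort_index()


def emission_sn_ratio(series: pd.DataFrame) -> pd.Series:
    """Per-year molar S/N emission ratio: SO₂ ÷ (NH₃ + NOₓ), Gmol basis.

    ``series`` needs columns ``year, gas, amount_gmol`` with all three gases
    present for every reported year.
    """
    wide = series.pivot_table(index="year", columns="gas", values="amount_gmol",
                              aggfunc="sum")
    missing = [g for g in _REQUIRED_GASES if g not in wide.columns]
    if missing:
        raise ValueError(f"missing gases in emission series: {missing}")
    wide = wide.dropna(subset=list(_REQUIRED_GASES))
    n_total = wide["NH3"] + wide["NOx"]
    if (n_total <= 0).any():
        bad = wide.index[n_total <= 0].tolist()
        raise ValueError(f"zero total nitrogen emissions in years {bad}")
    ratio = wide["SO2"] / n_total
    ratio.name = "sn_ratio"
    return ratio
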