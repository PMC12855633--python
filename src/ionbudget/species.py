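"""Chemical species registry and charge-equivalent unit conversions.

Long-term deposition budgets compare very different quantities — kilograms of
element per hectare, millimoles of ions per square metre, gigamoles of gas —
and the only currency in which acid–base bookkeeping balances is charge.
This module defines the species registry (molar mass, signed ionic charge,
element stoichiometry) and every conversion between mass-based, molar and
charge-equivalent ("IE" = ion equivalents, i.e. moles of charge) quantities,
plus pH-to-proton fluxes and sulfur/nitrogen ratios.

Conventions
-----------
* ``mmol_IE`` is millimoles of charge: mmol of species × |ionic charge|.
* Fluxes are per m² (1 mm of water = 1 L m⁻²); stocks per m²; deposition
  rates per year.
* pH is converted assuming activity equals concentration — adequate for the
  dilute solutions of precipitation and soil water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

__all__ = [
    "IonSpecies",
    "SpeciesRegistry",
    "Unit",
    "Quantity",
    "UnitError",
    "default_registry",
    "mass_flux_to_equivalent_flux",
    "equivalent_flux_to_mass_flux",
    "molar_stock_to_mass_stock",
    "ph_to_proton_flux",
    "sn_ratio",
]


class UnitError(ValueError):
    """Raised for conversions between incompatible dimension classes."""


@dataclass(frozen=True)
class IonSpecies:
    """A chemical species as carried through all budgets.

    Parameters
    ----------
    name
        Registry key, e.g. ``"SO4"``.
    formula
        Human-readable formula with charge, e.g. ``"SO4-2"``.
    molar_mass
        g per mol of the *species* (96.06 for sulfate).
    charge
        Signed ionic charge (−2 for sulfate, +1 for ammonium).
    element
        The budget element the species carries (S, N, H, Ca, …).
    element_stoichiometry
        mol of element per mol of species (1 for SO₄²⁻ → S).
    """

    name: str
    formula: str
    molar_mass: float
    charge: int
    element: str
    element_stoichiometry: int = 1

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError(f"{self.name}: molar_mass must be > 0")
        if self.element_stoichiometry < 1 or int(self.element_stoichiometry) != self.element_stoichiometry:
            raise ValueError(f"{self.name}: element_stoichiometry must be an integer >= 1")

    @property
    def abs_charge(self) -> int:
        return abs(self.charge)

    def require_ionic(self) -> None:
        """Charge-equivalent conversions are undefined for neutral species."""
        if self.abs_charge < 1:
            raise UnitError(
                f"species {self.name!r} has zero charge; "
                "equivalent (mmol_IE) conversion is undefined"
            )


class SpeciesRegistry(Mapping[str, IonSpecies]):
    """Registry of ion species plus element and gas molar masses.

    The shipped default (``data/species.yaml``) covers the full analyte list
    of a forest monitoring programme: H⁺, NH₄⁺, NO₃⁻, SO₄²⁻, Cl⁻, Ca²⁺,
    Mg²⁺, K⁺, Na⁺, Al³⁺, Mn²⁺, Fe³⁺ (metals measured as elements, assumed
    fully ionic). Constants are overridable via a user YAML of the same
    schema.
    """

    def __init__(
        self,
        species: Iterable[IonSpecies],
        element_masses: Mapping[str, float],
        gas_molar_masses: Mapping[str, float] | None = None,
    ) -> None:
        self._species = {sp.name: sp for sp in species}
        self._element_masses = dict(element_masses)
        self._gas_molar_masses = dict(gas_molar_masses or {})

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, name: str) -> IonSpecies:
        try:
            return self._species[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}; known: {sorted(self._species)}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._species)

    def __len__(self) -> int:
        return len(self._species)

    # Lookups --------------------------------------------------------------
    def element_mass(self, element: str) -> float:
        try:
            return self._element_masses[element]
        except KeyError:
            raise KeyError(f"no molar mass registered for element {element!r}") from None

    def gas_molar_mass(self, gas: str) -> float:
        try:
            return self._gas_molar_masses[gas]
        except KeyError:
            raise KeyError(f"no molar mass registered for gas {gas!r}") from None

    def cations(self) -> list[IonSpecies]:
        return [sp for sp in self._species.values() if sp.charge > 0]

    def anions(self) -> list[IonSpecies]:
        return [sp for sp in self._species.values() if sp.charge < 0]

    @classmethod
    def from_yaml(cls, path) -> "SpeciesRegistry":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_dict(raw)

    @classmethod
    def _from_dict(cls, raw: Mapping) -> "SpeciesRegistry":
        species = [IonSpecies(**entry) for entry in raw["species"]]
        return cls(species, raw["elements"], raw.get("gases", {}))


def default_registry() -> SpeciesRegistry:
    """The registry shipped with the package (see ``data/species.yaml``)."""
    text = resources.files("ionbudget.data").joinpath("species.yaml").read_text(encoding="utf-8")
    return SpeciesRegistry._from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Quantity bookkeeping
# ---------------------------------------------------------------------------

class Unit(str, Enum):
    KG_PER_HA = "kg_per_ha"
    KG_PER_HA_PER_YR = "kg_per_ha_per_yr"
    MG_PER_M2 = "mg_per_m2"
    MMOL_PER_M2 = "mmol_per_m2"
    MMOL_IE_PER_M2 = "mmol_ie_per_m2"
    MMOL_IE_PER_M2_PER_YR = "mmol_ie_per_m2_per_yr"
    UMOL_IE_PER_L = "umol_ie_per_L"
    GMOL_PER_YR = "Gmol_per_yr"
    KT_PER_YR = "kt_per_yr"


# Dimension classes: conversions without a chemical/water/time argument are
# only defined inside one class.
_DIMENSION: dict[Unit, str] = {
    Unit.KG_PER_HA: "mass_stock",
    Unit.MG_PER_M2: "mass_stock",
    Unit.KG_PER_HA_PER_YR: "mass_rate",
    Unit.MMOL_PER_M2: "molar_stock",
    Unit.MMOL_IE_PER_M2: "equivalent_stock",
    Unit.MMOL_IE_PER_M2_PER_YR: "equivalent_rate",
    Unit.UMOL_IE_PER_L: "concentration",
    Unit.GMOL_PER_YR: "emission_molar_rate",
    Unit.KT_PER_YR: "emission_mass_rate",
}

# Scale factors to the first unit of each class.
_SCALE: dict[Unit, float] = {
    Unit.KG_PER_HA: 1.0,
    Unit.MG_PER_M2: 0.01,  # 1 mg m⁻² = 0.01 kg ha⁻¹
    Unit.KG_PER_HA_PER_YR: 1.0,
    Unit.MMOL_PER_M2: 1.0,
    Unit.MMOL_IE_PER_M2: 1.0,
    Unit.MMOL_IE_PER_M2_PER_YR: 1.0,
    Unit.UMOL_IE_PER_L: 1.0,
    Unit.GMOL_PER_YR: 1.0,
    Unit.KT_PER_YR: 1.0,
}


@dataclass(frozen=True)
class Quantity:
    """A number with a unit; guards against cross-dimension arithmetic."""

    value: float
    unit: Unit

    @property
    def dimension(self) -> str:
        return _DIMENSION[Unit(self.unit)]

    def to(self, unit: Unit | str) -> "Quantity":
        unit = Unit(unit)
        if _DIMENSION[unit] != self.dimension:
            raise UnitError(
                f"cannot convert {self.unit} ({self.dimension}) to {unit.value} "
                f"({_DIMENSION[unit]}) without a chemical/water-flux argument; "
                "use the explicit conversion functions"
            )
        return Quantity(self.value * _SCALE[Unit(self.unit)] / _SCALE[unit], unit)


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def mass_flux_to_equivalent_flux(
    mass_flux_kg_ha_yr: float,
    species: IonSpecies,
    registry: SpeciesRegistry | None = None,
    element_mass: float | None = None,
) -> float:
    """Convert an element mass flux (kg element ha⁻¹ yr⁻¹) to mmol_IE m⁻² yr⁻¹.

    1 kg ha⁻¹ = 100 mg m⁻²; mg of element → mmol of element (÷ element molar
    mass) → mmol of species (÷ stoichiometry) → mmol of charge (× |z|).

    Example: an annual stand nitrogen demand of 9.7 kg N ha⁻¹ yr⁻¹ expressed
    as ammonium equals 9.7 × 100 / 14.007 × 1 ≈ 69.3 mmol_IE m⁻² yr⁻¹.
    """
    if mass_flux_kg_ha_yr < 0:
        raise ValueError("mass flux must be >= 0")
    species.require_ionic()
    if element_mass is None:
        registry = registry or default_registry()
        element_mass = registry.element_mass(species.element)
    mmol_element = mass_flux_kg_ha_yr * 100.0 / element_mass
    return mmol_element / species.element_stoichiometry * species.abs_charge


def equivalent_flux_to_mass_flux(
    eq_flux_mmol_ie_m2_yr: float,
    species: IonSpecies,
    registry: SpeciesRegistry | None = None,
    element_mass: float | None = None,
) -> float:
    """Exact inverse of :func:`mass_flux_to_equivalent_flux` (kg element ha⁻¹ yr⁻¹)."""
    if eq_flux_mmol_ie_m2_yr < 0:
        raise ValueError("equivalent flux must be >= 0")
    species.require_ionic()
    if element_mass is None:
        registry = registry or default_registry()
        element_mass = registry.element_mass(species.element)
    mmol_element = eq_flux_mmol_ie_m2_yr / species.abs_charge * species.element_stoichiometry
    return mmol_element * element_mass / 100.0


def molar_stock_to_mass_stock(stock_mmol_m2: float, element_molar_mass: float) -> float:
    """Convert an element stock from mmol m⁻² to kg ha⁻¹.

    mmol m⁻² × (g mol⁻¹) = mg m⁻²; 1 mg m⁻² = 0.01 kg ha⁻¹. A topsoil sulfur
    reserve of 2281.3 mmol m⁻² is 731.5 kg ha⁻¹ (M(S) = 32.065).
    """
    if stock_mmol_m2 < 0:
        raise ValueError("stock must be >= 0")
    if element_molar_mass <= 0:
        raise ValueError("molar mass must be > 0")
    return stock_mmol_m2 * element_molar_mass * 0.01


def ph_to_proton_flux(ph: float, water_flux_l_m2: float) -> float:
    """Proton flux (mmol_IE m⁻²) from a pH and the period water flux (L m⁻²).

    10^(−pH) mol L⁻¹ × water × 10³; activity is equated with concentration
    (no ionic-strength correction — appropriate for dilute precipitation and
    soil water).
    """
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH out of range (0, 14): {ph}")
    if water_flux_l_m2 < 0:
        raise ValueError("water flux must be >= 0")
    if water_flux_l_m2 == 0:
        return 0.0
    return 10.0 ** (-ph) * water_flux_l_m2 * 1000.0


def sn_ratio(
    s_flux: float,
    n_fluxes: Sequence[float],
    basis: str = "equivalent",
    s_species: IonSpecies | None = None,
    n_species: Sequence[IonSpecies] | None = None,
) -> float:
    """Sulfur/nitrogen ratio of fluxes sharing one basis.

    On the ``"equivalent"`` basis the inputs are mmol_IE and the ratio is
    Σ S equivalents / Σ N equivalents. On the ``"molar"`` basis each flux is
    first converted to mmol of element (÷ |charge| × stoichiometry), which
    requires the species. For deposition data the printed throughfall ratios
    (≈0.8 in 1985 falling to ≈0.07) arise on the equivalent basis; emission
    inventories use the molecule-molar basis (see :mod:`ionbudget.emissions`).
    """
    if basis not in ("equivalent", "molar"):
        raise ValueError(f"unknown basis {basis!r}")
    if s_flux < 0 or any(f < 0 for f in n_fluxes):
        raise ValueError("fluxes must be >= 0")
    if basis == "molar":
        if s_species is None or n_species is None or len(n_species) != len(n_fluxes):
            raise ValueError("molar basis requires s_species and one n_species per flux")
        s_species.require_ionic()
        s_total = s_flux / s_species.abs_charge * s_species.element_stoichiometry
        n_total = 0.0
        for f, sp in zip(n_fluxes, n_species):
            sp.require_ionic()
            n_total += f / sp.abs_charge * sp.element_stoichiometry
    else:
        s_total = s_flux
        n_total = math.fsum(n_fluxes)
    if n_total <= 0:
        raise ValueError("total nitrogen flux must be > 0")
    return s_total / n_total
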