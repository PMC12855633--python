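# ionbudget

Element budgets for long-term forest monitoring records: annual ion fluxes
from sampling-period solution chemistry and daily water fluxes, dry-deposition
inference, a stoichiometric proton budget for nitrogen transformations,
cumulative topsoil sulfur storage with remobilization-window detection, and
emission-inventory S/N ratio tracking.

It is written for ecosystem biogeochemists and monitoring programmes (e.g.
ICP Forests Level II plots) who hold decades of biweekly bulk-precipitation,
throughfall and seepage chemistry and want the input–output bookkeeping done
consistently in one charge-equivalent currency.

## The accounting

All fluxes are carried in **mmol_IE m⁻²** (millimoles of ion equivalents =
millimoles of charge, mmol of species × |z|), the only unit in which acid–base
budgets balance. Core pieces:

* **Period flux** (per sampling period *p*): `F_p = c̄_p × Σ_d q_d × 10⁻³`,
  the mean concentration (µmol_IE L⁻¹) times the summed daily water flux
  (mm = L m⁻²). Annual fluxes are the sum of period fluxes assigned to the
  calendar year, split pro-rata by water at year boundaries.
* **Dry deposition** of canopy-inert ions (SO₄²⁻, largely NH₄⁺):
  throughfall − bulk precipitation flux.
* **Proton load from N transformations.** Counting protons per process
  (nitrification +2, NH₄⁺ uptake +1, NO₃⁻ uptake/denitrification −1,
  ammonification −1) and eliminating the unobservable rates through the N
  mass balances gives the closed form

  `H⁺(N) = (NH₄⁺_throughfall − NH₄⁺_seepage) + (NO₃⁻_seepage − NO₃⁻_throughfall)`

  The total proton load adds the direct H⁺ input with throughfall
  (10^(−pH) × water); the **buffered percentage** is
  `100 × (load − H⁺_seepage) / load`.
* **Sulfur storage.** `ΔS = SO₄²⁻_throughfall − SO₄²⁻_seepage` per year
  (mmol_IE m⁻²), accumulated on the element basis (÷2) against an initial
  topsoil stock (mmol S m⁻²). A low-order polynomial trend of ΔS defines a
  natural-fluctuation zone (±MAE, rounded to the nearest 10); the maximal
  contiguous run of years with fitted ΔS below the negative threshold is the
  **sulfur remobilization window**.

Because no such multi-decade record is publicly deposited, the package ships
a seeded synthetic generator that reproduces the *structure* of one (declining
SO₄²⁻/NH₄⁺ throughfall, roughly flat NO₃⁻, high inter-annual seepage
variability, drought years) together with its ground-truth annual fluxes, so
every stage is testable by parameter recovery.

## Worked example

```bash
ionbudget run --seed 1 --out out/
ionbudget report --summary out/summary.json
```

prints

```
years: 1985-2020
cumulative S change: -829.5 mmol m⁻²
remaining S stock:   1451.8 mmol m⁻² (63.6%)
buffered protons:    96.7% (first 5 yr) -> 94.3% (last 5 yr)
S remobilization:    1991-2020 (29 years)
R²(H⁺ load, NO₃⁻ seepage): 0.956
```

Reading this: over the simulated 36 years the topsoil lost 829.5 mmol S m⁻²
of its initial 2281.3 mmol m⁻² reserve (63.6% remains); the topsoil
neutralized 96.7% of the proton load early in the series but only 94.3% at
its end (slowly declining buffering capacity); the fitted ΔS trend stays below
the natural-fluctuation threshold from 1991 onward (ongoing sulfate
remobilization); and year-to-year variation of the proton load is dominated
by nitrate discharge (R² = 0.956), the signature of nitrification-driven
acidification.

Desk-scale conversions from the same API:

```python
>>> import ionbudget as ib
>>> r = ib.default_registry()
>>> ib.mass_flux_to_equivalent_flux(9.7, r["NH4"])   # kg N/ha/yr -> mmol_IE/m2/yr
69.25
>>> ib.mass_flux_to_equivalent_flux(0.9, r["SO4"])
5.61
>>> ib.molar_stock_to_mass_stock(2281.3, 32.065)     # mmol S/m2 -> kg/ha
731.5
```

The CLI verbs `generate`, `fluxes`, `budgets`, `trends`, `run` and `report`
are thin wrappers over the library; everything is equally usable from Python
(`ionbudget.run_pipeline`, `ionbudget.annual_fluxes`, …). Scenario and
analysis options live in a YAML config (see `PipelineConfig.from_yaml`).

## Layout

```
src/ionbudget/
  species.py    # registry, charge-equivalent conversions, pH, S/N ratios
  synthetic.py  # seeded scenario generator + emission-series builder
  fluxes.py     # period/annual fluxes, dry deposition, charge balance
  budgets.py    # proton budget, S storage trajectory, surplus, livestock units
  trends.py     # polynomial trends, thresholds, window detection, OLS
  emissions.py  # inventory harmonization, molar conversion, S/N ratios
  io.py         # CSV schemas, pipeline config, end-to-end pipeline
  cli.py        # command-line interface
docs/methods.md # model assumptions, parameter choices, limitations
```
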