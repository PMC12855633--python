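# Methods

This note documents the models, parameter choices and limitations of
`ionbudget`, in the order the pipeline runs.

## Unit system

The internal currency is the ion equivalent: 1 mmol_IE = 1 mmol of charge
(mmol of species × |z|). Concentrations are µmol_IE L⁻¹ (= µeq L⁻¹), fluxes
mmol_IE m⁻² (per year for rates), element stocks mmol m⁻², with 1 mm of
water = 1 L m⁻².

Molar masses (g mol⁻¹) in the shipped registry: S 32.06, N 14.007, and
standard values for H, Cl, Ca, Mg, K, Na, Al, Mn, Fe; gases SO₂ 64.07,
NH₃ 17.031, NOₓ as NO₂ 46.006. All are overridable through a YAML registry
file; conversions that depend on a molar-mass choice are honest to roughly
0.05% across common tabulations of atomic weights (e.g. M(S) 32.06 vs
32.065), which is far below the noise of any flux involved.

pH converts to proton concentration as 10^(−pH) with activity equated to
concentration. Precipitation and dilute soil solutions have ionic strengths
where the activity correction is at most a few percent — smaller than
sampling error — and no activity model is available for the records this
package targets.

S/N ratios support two bases. The *equivalent* basis divides summed S
equivalents by summed N equivalents and is the default for deposition data;
the *molar* basis first converts each flux to moles of element (÷|z| ×
stoichiometry, halving sulfate) and is the convention for emission
inventories, which are compared molecule-molar (Gmol). The two differ by a
factor ≈2 when sulfate dominates S; outputs always state their basis.

## Synthetic monitoring data

The generator emulates the structure of a 36-year intensive monitoring
record (default span 1985–2020, biweekly sampling, three compartments) with
known ground truth. Per year it:

1. draws annual precipitation (lognormal, mean 752 mm, cv 0.15 — matching a
   record spanning roughly 520–1050 mm), spreads it over gamma-distributed
   rain-day weights, and partitions it into compartments: throughfall =
   0.75 × bulk (canopy interception of a closed spruce stand), seepage =
   0.35 × bulk in normal years and 0.10 × bulk in drought years (default
   1997, 2003, 2018–2020);
2. interpolates each configured (compartment, species) annual-flux trend —
   linear or exponential-decay between its endpoint fluxes — and converts it
   to a base concentration using the realized annual water;
3. multiplies by two seeded lognormal noise factors with mean 1: one per
   sampling period (`concentration_cv`, default 0.25) and one per year
   scaled by compartment (0.2 × cv for bulk/throughfall, 0.8 × cv for
   seepage). Tying the annual factor to `concentration_cv` keeps the
   cv = 0 case exactly noise-free while giving seepage the much larger
   inter-annual variability that soil processes impose on real records;
4. assigns pH per period from a linear start→end trend per compartment
   (defaults: bulk 4.4→5.1, throughfall 4.6→5.6, seepage 4.45→4.6) plus
   Gaussian noise with sd = 0.4 × cv.

Drought years are applied afterwards by scaling daily seepage water only, so
every seepage ion flux of those years scales by exactly the multiplier
(0.10/0.35 ≈ 0.29 by default) — chemistry is untouched, as in a real dry
summer.

Default deposition trends (mmol_IE m⁻² yr⁻¹, start→end): throughfall SO₄
160→10 and NH₄ 150→70 (exponential), NO₃ 70→60; bulk SO₄ 60→10
(exponential), NH₄ 40→30, NO₃ 40→20. Seepage carries NO₃ 250→100, SO₄
150→70, NH₄ 8→3, Cl 120→40 and a cation load (Al 200→80, Ca 150→60, Mg
60→25, K 40→20) in which aluminium dominates with roughly 40–45% of the
cation equivalents.

What the generator does **not** emulate: non-monotone seepage trends (the
trend grammar is deliberately limited to linear/exponential endpoints, so
the mid-series sulfate-discharge hump of real records is absent); within-
year seasonality of concentrations; autocorrelated noise; mechanistic
hydrology (daily seepage is proportional to daily precipitation rather than
produced by a soil-water model); analytical method changes or detection
limits. Passing recovery tests therefore demonstrates that the *accounting*
is correct, not that the statistical machinery is robust to every pathology
of real data. The bulk/throughfall noise streams are uncorrelated by default
(bulk collectors typically stand on a separate open plot); a config switch
makes them share draws.

## Flux aggregation

Period flux = mean concentration × summed daily water × 10⁻³. Aggregation is
by calendar year (a hydrologic-year basis would only relabel the budgets);
periods spanning a year boundary are split pro-rata by the water falling in
each year, which preserves exact additivity. Missing concentrations are
filled by linear interpolation in time (period midpoints) within a
compartment/species, taking the nearest value beyond the endpoints; water is
never interpolated, because water carries the mass and a gap there cannot be
invented. Each annual value reports its water-weighted interpolated fraction
and is flagged low-confidence above 25%. A series that is missing entirely
is an error, as is a water day falling in a gap between periods.

H⁺ fluxes are derived per period from pH before aggregation, so proton
fluxes obey exactly the same period arithmetic as measured ions.

## Budgets

The nitrogen-transformation proton load uses the closed form
`(NH₄_in − NH₄_out) + (NO₃_out − NO₃_in)`; its equality with the rule-level
process accounting (2·nitrification + NH₄-uptake − NO₃-uptake −
ammonification) under the two N mass balances is an algebraic identity and
is verified exactly over 10⁴ random integer rate vectors in the tests.
Negative loads (net proton consumption) are reported, not clamped. The
buffered percentage is undefined (NaN) when the total load is ≤ 0.

The sulfur trajectory divides charge-equivalent deltas by 2 to the element
basis before accumulating against the initial stock (default
2281.3 mmol S m⁻², a measured humus + 0–40 cm reserve), and reports both
unit labels to keep the basis auditable. Net tree S uptake
(≈5.5 mmol_IE m⁻² yr⁻¹ for a mature spruce stand) and litterfall are
excluded by default — they roughly cancel over decades — but an uptake term
can be subtracted per year. The stock is never clamped; a trajectory that
crosses zero is flagged `stock_exhausted`.

Livestock units default to cattle 1.0 and pig 0.16 per head, the
coefficients that reproduce published district totals from head counts to
within one unit.

## Trend analysis

Polynomial trends are OLS fits on a centered, unit-scaled year axis
(`numpy.polynomial.Polynomial.fit`), making the fit invariant to year
translation. Default degrees follow what low-order visual trend fitting of
such series typically uses — 4 for deposition, 5 for seepage and proton
load, 3 for ΔS — all configurable.

The natural-fluctuation threshold is the fit's mean absolute residual
rounded to the nearest multiple of 10 with ties toward zero (MAE 52.8 → 50);
rounding mode "none" keeps the raw MAE. The remobilization window is the
maximal contiguous run of grid years with fitted ΔS below −threshold
(strictly); its edge years are refined by linear interpolation between the
neighbouring grid years and rounded to the nearest integer, since a smooth
trend crosses between sampling years.

"Inter-annual fluctuation" for the endpoint-interpretability test is
operationalized as the absolute year-to-year first differences of the
*observed* series (a residual-based alternative is available via
`method="residuals"`); the fitted endpoint change must reach the 90th
percentile (configurable) of those fluctuations to count as an
interpretable trend. Linear trends use `scipy.stats.linregress` with its
two-sided t-test on the slope, with no autocorrelation correction — the
diagnostic is deliberately the plain OLS one, and is labelled as such.

## Emissions

Inventory amounts convert kt → Gmol by dividing by the gas molar mass, with
NOₓ expressed as NO₂ (the standard inventory convention; overridable).
Historical reconstructions are spliced onto an inventory by scaling the
historical series to agree at the first inventory year; two territories are
combined by year-wise summation, and a year covered by only one territory is
an error unless the caller opts into overlap-only output — silent
understatement of a national total is the failure mode this guards against.
The emission S/N ratio is SO₂ / (NH₃ + NOₓ) on the Gmol basis.

## Pipeline, formats, reproducibility

CSV is the single interchange format (UTF-8, comma, "." decimal, ISO-8601
dates, concentrations in µeq L⁻¹); every written table carries a
schema-version comment line. Ground truth of synthetic datasets is written
to a sidecar file, never mixed into the data files. A pipeline run from a
scenario is fully reproducible from (config, seed): all randomness flows
from one `SeedSequence` spawned into named streams. The default pipeline and
test problem sizes (36-year span, biweekly periods, ~14 species-compartment
series) run in seconds; they are the sizes the method is designed for, and
larger spans scale linearly.

Plot output is not built in; all report tables are plain CSV/JSON and plot
readily with any tool.

## Known limitations

* The proton budget folds every unmeasured process (weathering, organic-acid
  exudation, redox of elements other than N, canopy exchange) into the
  input–output comparison; it is a topsoil balance, not a mechanistic model.
* Sulfur storage is inferred purely from the SO₄²⁻ input–output balance;
  sorption, precipitation and organic-S dynamics are not represented.
* Window detection reports a single maximal run; multi-episode
  remobilization would need the per-year fitted series, which is available
  in the trend report.
* The endpoint-interpretability verdict depends on the chosen polynomial
  degree at the series ends, where polynomial fits are least stable.
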