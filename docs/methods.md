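# Methods

## Conservative mixing and the Sources−Sinks term

The analysis assumes each fjord water mass (Surface Water SW, Intermediate
Water IW, and fjord Atlantic Water AWf) is formed solely by diluting shelf
Atlantic Water (AWs) with freshwater of salinity 0. Under that assumption
salinity is a conservative mixing tracer, and any tracer's concentration at
observed salinity S_obs should fall on the straight line between the
freshwater endmember (0, C₀) and the marine endmember (S_AW, C_AW):

    C_cons = C₀ + S_obs · (C_AW − C₀) / S_AW
    ΔC     = C_obs − C_cons

ΔC < 0 is a net biogeochemical sink (uptake), ΔC > 0 a net source. The key
assumptions, and when they fail:

- **Two endmembers only.** If a third water type (e.g. Arctic Water)
  contributes, the marine endmember is not valid. The approach is intended
  for systems where the shelf water mass demonstrably dominates.
- **Endmember stationarity.** The shelf pool is sampled at essentially the
  same time as the fjord; variability in AW on timescales shorter than the
  flushing time biases ΔC.
- **Gas exchange.** For DIC (a tracer containing a gas) air–sea CO₂ flux is
  an unquantified term folded into ΔC; summer surface waters undersaturated
  in CO₂ make the DIC sink estimate conservative.

Observed and endmember values are *pooled means*: per-station trapezoidal
depth-weighted means over the top 100 m, then an unweighted average across
stations. Station-first averaging was chosen because monitoring designs
pool named station sets with very different sampling densities; sample-level
pooling is available via `station_first=False`. Duplicate bottles at one
station/depth are averaged (and logged).

Pooled contrasts are screened with a two-tailed Welch t-test on raw bottle
concentrations (α = 0.05). Welch rather than the pooled-variance test
because water masses differ in both n and variance; the pooled test is
available by flag. No multiple-testing correction is applied by default —
each year × water-mass cell is reported with its own p — but a
Benjamini–Hochberg step could be layered on the returned p-values. Bottle
samples from different depths/places are not true replicates; the p-values
are a screen, not a formal inference.

## Endmembers

Freshwater salinity is fixed at 0 (glacier melt). Default freshwater
nutrient concentrations (µmol kg⁻¹): ammonium 1.44, nitrate+nitrite 2.00,
phosphate 0.064, silicic acid 9.77 — glacial-river means; all overridable.
The freshwater DIC endmember cannot be sampled directly, so it is estimated
per year as the Y-intercept of an OLS regression of DIC on salinity within
SW (all SW bottles of the year pooled across stations). Negative intercepts
are returned with a warning, not clamped: a clamp would silently bias ΔC.
Note a structural caveat: because SW itself carries the biogeochemical
signal, the regression intercept absorbs part of any uniform drawdown; the
regression route is therefore an endmember *estimate*, not ground truth,
and the synthetic closure tests use a configured freshwater DIC instead.

## Flushing time and NEM

With a steady-state single-box balance, exchange with the shelf at volume
flux Q through volume V (FT = V/Q) must offset the biogeochemical term, so

    rate = −ΔC / FT     (µmol kg⁻¹ d⁻¹, positive = net uptake = autotrophy)

is used as the NEM proxy. FT is a *parameter* here (default 13 d, the mean
of hydrodynamic-model estimates for Kongsfjorden); no circulation is
simulated. A Knudsen/LOICZ salt-balance alternative is provided:
Q_out = Q_fw·S_ocean/(S_ocean − S_fjord), FT = V/Q_out. The steady-state
assumption is reasonable when FT (days) is short against the seasonal
timescale of the tracer fields.

Depth integration uses rate·ρ·z·10⁻⁶ mol m⁻² d⁻¹ with z = 100 m and
ρ = 1000 kg m⁻³ by default. The nominal 1000 (treating µmol kg⁻¹ as
µmol L⁻¹) matches the convention behind the published gram-unit ranges;
using in-situ seawater density (~1027) raises the integrals by ~2.5% and is
available through the `density` parameter. Molar masses are per element:
N = 14.007, C = 12.011 g mol⁻¹. Areal upscaling multiplies g m⁻² d⁻¹ by the
fjord area (231.5 km² for Kongsfjorden inside the mouth transect).

Reported summary ranges use only the AWs-vs-IW and AWs-vs-SW contrasts
(AWf is the same water mass as AWs, merely diluted, and its contrast mixes
light limitation and remineralisation at depth); AWs-vs-AWf is computed but
excluded from NEM summaries. Rounding conventions for reported ranges:
rates to one decimal, integrated mol to two decimals, grams to one decimal,
tonnes to the nearest integer. The mean molar C:N uptake ratio is the
arithmetic mean of per-(year, contrast) ratios of matched DIC and
nitrate+nitrite rates with both rates positive; the exclusion list lets the
caller drop outlier years, and `cn_uptake_ratio` exposes the averaging
choices rather than hard-coding one (run over all matched published
contrasts with no exclusions it yields 7.2, close to Redfield 6.6).

## Water-mass classification

Rectangular T/S envelopes with explicit integer priorities; minima
inclusive, maxima exclusive; ambiguous points go to the highest-priority
envelope and unmatched points to a fallback label. The shipped defaults are
the Cottier et al. (2005) West Spitsbergen envelopes (AW: T ≥ 3, S ≥ 34.9;
TAW: 1 ≤ T < 3, S ≥ 34.7; IW: T ≥ 1, 34.0 ≤ S < 34.65; SW: T ≥ 1,
S < 34.0) and are deliberately config-editable placeholders — verify them
against the classification scheme of your own system. The depth window
defaults to 100 m with 50/150 m as sensitivity presets.

## Nitrogen budget

All fluxes are signed tonnes N d⁻¹, positive into the fjord water column.
Computed fluxes: atmospheric wet deposition (per ~weekly period,
mg N m⁻² = precipitation mm × concentration mg L⁻¹, daily-averaged over the
union of periods, upscaled to area), riverine input (runoff volume ×
concentration) and fjord–ocean exchange (volume transport × DIN).
Literature-derived constants (sediment denitrification, bird consumption,
plankton advection, …) enter as pass-through entries with provenance
strings. The internal balance sums everything except excluded categories
(default: ocean exchange, which is orders of magnitude larger and poorly
constrained in net terms). Particulate-aerosol and ammonium deposition are
supported but off by default (orders of magnitude below nitrate wet
deposition). Entries are tagged summer/annual; no seasonal interpolation is
attempted.

## Synthetic data generator

The generator emulates exactly the structure the analysis assumes, which is
what makes it a ground-truth oracle: salinity = f·S_AW with mixing fraction
f drawn per sample from a depth-layer range (fjord: SW 0–25 m with
f ∈ [0.92, 0.968], IW 25–55 m with f ∈ [0.973, 0.989], AW below; shelf: AW
throughout, f ∈ [0.998, 1]; ratios > 92% mirror the weak freshwater
dilution of the study system); conservative concentrations lie exactly on
the configured mixing line; a per-water-mass drawdown is subtracted from
fjord records only (the shelf is the reference); Gaussian noise is added
per tracer. Temperature carries no chemistry — it is placed at the intended
envelope's centroid ± jitter purely to drive classification, and the
generator fails fast if a layer's (T, S) placement would classify outside
its intended envelope. All randomness flows from one integer seed.

Defaults reflect the study conditions: 5 fjord and 3 shelf stations, 13/5
sampling depths, marine endmember S = 35.0 with nitrate 11 and DIC
2150 µmol kg⁻¹, freshwater nitrate 2.0 and DIC 900 µmol kg⁻¹, noise
σ = 0.3 µmol kg⁻¹ (nitrate) and 2 µmol kg⁻¹ (DIC) in the ready-made
scenario, whose imposed drawdowns (nitrate 2–5, DIC at 6.6× those) place
ΔC and the derived rates inside the published summer ranges.

What it deliberately does **not** emulate: real circulation or tides,
glacier-plume upwelling, seasonal irradiance cycles, three-endmember mixing,
vertical structure of drawdown within a water mass, or non-Gaussian
measurement error. Passing recovery tests therefore demonstrates the
*estimator chain* is correct under the model's own assumptions, not that
the assumptions hold in any particular fjord.

Budget series: weekly deposition periods with lognormal precipitation,
daily runoff zero November–April with a Gaussian July–August melt peak, and
near-constant volume transport. Truth fluxes are computed inside the
generator by direct summation, independent of the budget module's
constructors.

## Numerical and interface choices

- Missing measurements are absent map entries, never sentinels; statistics
  use present values only; absent table cells render as `-`.
- Unit conversion µM → µmol kg⁻¹ uses one configurable reference density
  (default 1000 kg m⁻³, valid range 990–1035), not per-sample density.
- `depth_weighted_mean` averages duplicate depths first, integrates by the
  trapezoidal rule from the shallowest sample to min(deepest, window), and
  returns the single value when only one depth is present.
- Degenerate inputs raise typed errors (equal endmember salinities, empty
  pools, < 3 regression points, zero salinity variance, s_fjord ≥ s_ocean);
  the CLI maps config errors to exit 2 and data errors to exit 3.
- Zero-variance equal-mean groups get p = 1 in the t-test screen.
- Output files start with a `# fjordnem v… config=<hash>` header; identical
  config + inputs + seed give byte-identical outputs.

## Problem sizes used in tests

Recovery tests run 200 generator replicates at 50 samples per water mass
with σ = 0.3 µmol kg⁻¹ (the monitoring noise scale), the regression check
100 fits of n = 200, and the t-test oracle 20 cases against a
100 000-permutation brute force — sizes chosen so the whole suite completes
in well under a minute while keeping Monte-Carlo error far below the
assertion tolerances.

## Known limitations

- FT enters as a single whole-fjord scalar; spatially resolved flushing
  (shorter near the mouth) is out of scope.
- The t-test screen treats bottles as replicates; they are not, strictly.
- DIC ΔC ignores air–sea CO₂ exchange (biases the sink estimate low in
  undersaturated summers).
- The nitrogen ledger is only as complete as its inputs: submarine
  groundwater, iceberg melt, fish/mammal fluxes and bird feces return are
  not represented.
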