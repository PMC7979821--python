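# Methods

`aquaflux` estimates CO₂ evasion from inland waters at national scale from
routine monitoring data: gauge water chemistry gives surface-water pCO₂,
hydraulics or wind give the gas transfer velocity, their product gives the
areal flux, and stratified surface-area bookkeeping integrates areal fluxes
to regional and national effluxes with Monte Carlo error propagation and a
terrestrial/aquatic carbon partition on top. This note records the models,
the defaults, and the choices made where the design was genuinely open.

## Carbonate speciation

Surface-water pCO₂ is derived from pH (NBS scale), total titration
alkalinity (µeq L⁻¹) and water temperature under the dilute freshwater
assumption: zero salinity, unit activity coefficients, titration alkalinity
read as carbonate alkalinity CA = [HCO₃⁻] + 2[CO₃²⁻] + [OH⁻] − [H⁺]. With
[H⁺] fixed by pH, bicarbonate follows algebraically, CO₂* = [HCO₃⁻][H⁺]/K1,
and pCO₂ = CO₂*/K_H.

Constants are the zero-salinity fits of Plummer & Busenberg (1982) for K1,
K2 and K_H and Millero (1995, S = 0) for K_w. At 25 °C these give pK1 = 6.352
and K_H = 0.0340 mol L⁻¹ atm⁻¹. The test suite cross-checks the whole
speciation against an independent route built from different published fits
(Harned & Davis 1943; Harned & Scholes 1941; Weiss 1974) and a DIC-based
formulation; agreement is within 5% over pH 6–9 and 5–30 °C. Station
pressure enters K_H through a Poynting factor and is derivable from gauge
elevation with the standard barometric formula; the correction is below 1%
even for high-plateau gauges, but keeps the interface explicit about
pressure.

Records whose alkalinity is inconsistent with their pH (non-positive solved
bicarbonate) are rejected with a logged reason rather than clamped. Sites
with fewer than 25 observations (configurable) are excluded from period
means, mirroring standard screening of yearbook records.

**Dilute-water calibration.** pCO₂ computed from pH/alkalinity is known to
be biased high in low-alkalinity, organic-rich waters. The published
correction this pipeline anticipates is not reproduced in open literature in
closed form, so the hook is pluggable: below 1000 µeq L⁻¹ a configurable
organic-alkalinity fraction `f_org` is subtracted and a pH offset `δpH`
applied; both default to zero (identity) and corrected samples carry a
provenance flag. A separate multiplicative bias divisor (default 1.09 where
enabled, off by default) is exposed for sensitivity analyses; the shipped
scenario arithmetic needs no bias correction.

## Gas transfer velocity

All parameterizations live in a YAML-round-trippable registry with citation
strings, so swapping a model is a configuration change.

* Streams, general (default, used for reported effluxes):
  k600 [m d⁻¹] = 2841.6·(V·S) + 2.02, with V flow velocity (m s⁻¹) and S
  channel slope. The intercept (8.42 cm h⁻¹) is the flat-water floor.
* Streams, energy dissipation (config alternative): two log-log regimes in
  eD = g·S·V, ln k600 = 0.35·ln eD + 3.10 below 0.02 m² s⁻³ and
  1.18·ln eD + 6.43 at or above it. The regimes are intentionally not
  continuous at the breakpoint; zero-slope reaches must be routed to the
  general model.
* Lakes and reservoirs: piecewise in wind at 10 m with a 3.7 m s⁻¹
  breakpoint — Cole & Caraco (1998) 2.07 + 0.215·U₁₀^1.7 below it,
  Crusius & Wanninkhof (2003, power form) 0.168 + 0.228·U₁₀^2.2 at or
  above. This pairing keeps a positive calm-water baseline and is
  non-decreasing across the breakpoint, which the linear high-wind
  alternative (4.33·U₁₀ − 13.3) is not.

Boundary values belong to the high regime in both piecewise models
(deterministic tie-break). Schmidt-number conversion uses the Wanninkhof
(2014) freshwater CO₂ polynomial (Sc(20 °C) = 600) with exponent −1/2 for
streams and wind-sheared surfaces and −2/3 for calm lentic surfaces.

## Areal flux and upscaling

F_CO2 = k·k_H·ΔpCO₂ in mmol m⁻² d⁻¹ (k in cm h⁻¹ × 0.24 → m d⁻¹; k_H·ΔpCO₂
in mmol m⁻³). Positive flux is evasion; the atmospheric reference defaults
to 340 µatm for the 1980s scenario and 400 µatm for the 2010s. Where direct
evasion measurements exist they take precedence over computed fluxes.

Strata are Strahler orders 1–8 for flowing waters (headwater = 1–2,
intermediate = 3–5, large = 6–8) and three size classes for standing waters
(<10 km² small, [10, 50] closed medium, >50 large). Each
(region, stratum, season) cell contributes F̄·SA·N·12/10¹⁵ Tg C, with SA the
stratum surface area (m²) and N the ice-free days of the season. Streams
carry seasonal areas (length × seasonal width); lakes and reservoirs carry a
single annual area paired with seasonal flux means. Missing strata inherit
the mean of adjacent orders within the region, else the regional seasonal
mean, and the fill is logged; unfillable gaps are an error, never a silent
zero.

Seasons default to dry = November–April (181 d) and wet = May–October
(184 d). Ice-free days are per-region configuration; the defaults keep the
full season in the subtropical south and reduce the dry season to 100 d in
NE China, 130 d in NW China, 165 d in Huang-Huai-Hai, and both seasons
(90/165 d) on the Tibetan Plateau. These counts are a design choice; the
scenario generator solves stratum fluxes *given* them, so the fixture totals
are insensitive to the exact values.

## Uncertainty

Monte Carlo (default 10,000 iterations, seeded, bit-reproducible; spawned
substreams per water type) perturbs stratum-mean fluxes and areas and
recomputes the stratified sums; the 5th/95th percentiles are the interval.
Independence structure: regions and water types independent; strata within
one region share a single standard-normal draw for their flux means (they
come from one regional site population); areas draw independent
zero-truncated normals. Flux draws are normal clipped at zero — for the
large relative errors of some regions the truncation shifts the Monte Carlo
mean upward by 1–2%, so reports use the deterministic stratified sum as the
central value and the Monte Carlo spread for the uncertainty. Independent
point estimates combine as value = Σ, sd = √Σsd², with a normal-theory
5th/95th interval.

## Carbon budget

Soil respiration is assumed to supply 90% of headwater-stream evasion and
20% of evasion from higher-order streams, lakes and reservoirs; the residual
(total − soil) is aquatic production not counted by biomass-based
terrestrial sink estimates, and its ratio to the sink bounds gives the
percent sink offset. The change between periods is decomposed as
ΔE = ΔF·S̄A + ΔSA·F̄ (mean-anchored two-factor split), which is exactly
additive — shares always sum to 100% with no interaction remainder; this is
one defensible convention among several, and is flagged as such. Report
rounding: one decimal for regional Tg values, integers for national totals
and percentages.

## Synthetic data

The generators define the study conditions; they are not free dials.

* `gen_scenario(period)` expands published national bookkeeping (seasonal
  stream areas, annual lake/reservoir areas, regional efflux totals with
  SDs, headwater efflux shares of 55%/61%) into full stratified fixtures.
  Areas split across regions by fixed shares (over half the lake area on
  the Tibetan Plateau) and across orders by a geometric profile with a
  ~35% headwater area share; per-order efflux shares follow a geometric
  profile whose ratio is solved so the headwater share matches the period;
  stratum fluxes are then back-solved exactly from the stratified sum with
  a wet/dry flux ratio of 1.35. Regional columns are rescaled by <0.2% so
  they sum to the published subtotals despite one-decimal print rounding.
  Aggregating a bundle therefore reproduces the period's regional and
  national totals by construction — that is the point: it makes the
  upscaling, Monte Carlo and budget stages testable end to end.
* `gen_gauges` draws per-site target fluxes from a per-order profile
  (linear 700 → 110 mmol m⁻² d⁻¹), hydraulics from a geometric V·S decline
  giving headwater k600 ≈ 43 cm h⁻¹, lognormal alkalinity (median
  1800 µeq L⁻¹), and a seasonal temperature sinusoid, then *back-solves* pH
  from (pCO₂, alkalinity, temperature) through the carbonate cubic via
  vectorized Newton iteration. Generated chemistry is thus exactly
  self-consistent: the forward pipeline recovers the target fluxes up to
  sampling noise, the induced national mean pCO₂ sits near 2.8 × 10³ µatm,
  and order means decline by ~95–105 mmol m⁻² d⁻¹ per order. These defaults
  were calibrated once against those population envelopes and then frozen.
* `gen_network` builds a Horton tree (number ratio 4, length ratio 1.85,
  width ratio 1.9) whose Strahler ordering provably matches the declared
  orders and whose headwater area share lands at ~35%.
* `gen_lentic` draws lognormal body areas spanning all three size classes,
  rescaled to the published national lake/reservoir areas per period (hence
  a 73% reservoir increase between periods), and a site pCO₂ lognormal
  whose median is placed so 21% of sites are undersaturated.

What the generators do **not** emulate: spatial autocorrelation, real
hydrograph timing, covariance between chemistry and hydraulics beyond the
order structure, measured-vs-computed flux mixtures, and any georeferencing.
Passing tests therefore demonstrate the estimator mechanics and the
published-arithmetic bookkeeping, not skill on real monitoring data.

## Numerical choices and limitations

* pH inversion: Newton on the cubic in [H⁺] from a bicarbonate-dominated
  start, 60 iterations, relative residual < 1e-8 enforced.
* Tie-breaks: regime boundaries high; medium size class closed [10, 50];
  Strahler junctions of ≥2 equal-order tributaries increment.
* Problem sizes: default synthetic gauge set is 372 sites × 30 observations
  across six regions and eight orders; scenario bundles have 168 flux cells.
  The full suite runs in a few seconds on one core.
* The published asymmetric national intervals (e.g. 91–200 Tg C yr⁻¹)
  arise from site-level resampling distributions that are not recoverable
  from printed summaries; the Monte Carlo here is validated by its
  contracts (degeneracy, linear error propagation, seeding) instead.
* Ionic-strength/activity corrections and non-carbonate alkalinity beyond
  the pluggable correction are out of scope, as are ebullition, CH₄/N₂O,
  chemical enhancement at high pH, and spatially explicit mapping.
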