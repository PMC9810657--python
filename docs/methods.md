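# Methods

This note documents the models, parameter choices and numerical
conventions behind `coastalghg`, and what the synthetic-data tests do
and do not demonstrate about real campaigns.

## Bulk flux formulation

The sea-air flux of CO₂ or CH₄ is computed as F = k·K₀·(pGas_sea −
pGas_air), with k the gas transfer velocity (m s⁻¹), K₀ the volumetric
solubility (mol m⁻³ atm⁻¹) and partial pressures in µatm. Positive
fluxes are effluxes to the atmosphere. Unit conversion to
mg m⁻² d⁻¹ uses molar masses of 44.01 (CO₂) and 16.04 (CH₄) g mol⁻¹.

**Wind.** Sensors on coastal masts sit below 10 m, so the measured wind
is scaled with the neutral logarithmic profile U₁₀ = U + (u*/κ)·ln(10/zu),
κ = 0.4, taking the natural logarithm (the profile is derived from
mixing-length theory, where the logarithm is natural). For sensors
above 10 m the shear term is negative and can drive the formula below
zero at very light winds; such values are clamped to 0 with a warning
because a negative speed is unphysical and k ∝ U₁₀² anyway vanishes.

**Solubility.** Both gases go through the same contract
{β, K₀ = β/(R·T_STD)} with R = 8.20573×10⁻⁵ m³ atm K⁻¹ mol⁻¹ and
T_STD = 273.15 K, but each coefficient set is used in its native fitted
form: the CH₄ set is a Bunsen-coefficient fit (Wiesenburg & Guinasso
1979), the CO₂ set a volumetric K₀ fit in mol L⁻¹ atm⁻¹ (Weiss 1974),
with β back-computed through the ideal-gas identity. This avoids
refitting either reference. Evaluation outside each fit's temperature
or salinity range raises rather than extrapolates. The test fixtures
for these fits are high-precision evaluations frozen at build time and
anchored against standard literature values (e.g. K₀(CO₂, 0 °C, S=0) =
0.0776 mol L⁻¹ atm⁻¹); they guard formula structure, coefficient entry
and unit handling.

**Schmidt number.** Pinned to the Wanninkhof (2014) fourth-order
polynomials in temperature (°C), valid −2…40 °C, with separate
fresh-water (S = 0) and sea-water (S = 35) fits. Brackish values use
standard linear interpolation Sc(S) = Sc_fw + (Sc_sw − Sc_fw)·S/35.
A product form of this interpolation sometimes seen in print is
dimensionally inconsistent; the linear form is what "interpolation
between the fresh- and sea-water fits" means and reproduces both
endpoints exactly. Salinities above 35 are refused (extrapolation).

**Transfer velocity.** k = 0.251·U₁₀²·(Sc/660)^−0.5. The 0.251
coefficient yields cm h⁻¹; the module converts explicitly
(÷3.6×10⁵) and returns both units to keep the flux equation's m s⁻¹
basis auditable. Wind-speed-only parameterizations are appropriate for
non-tidal sites without strong currents; alternative estuarine models
are out of scope.

## Equilibrator QC pipeline

The analyzer alternates 35 min of water-equilibrated headspace and
10 min of ambient air (45-min cycles); 1-Hz data are logged as 10-s
means. Choices that the instrument papers leave open:

- **Transition purge**: 300 s (configurable) after every phase switch
  or station move, covering several equilibrator/analyzer e-folding
  response times. Records flagged malfunction/low-flow are excluded
  outright. Increasing the purge can only flag more records
  (monotonicity is property-tested).
- **Atmospheric reference**: each cycle's purged air-window mean,
  applied to that cycle's water window (nearest in time); a truncated
  cycle inherits the nearest reference within the same habitat
  deployment.
- **Averaging**: fluxes are averaged to clock-aligned 15-min intervals
  (half-open [t, t+15)); diel composites use twelve 2-hour bins with
  bin 0 = [00:00, 02:00) local time. No daylight-saving shifts are
  assumed within a campaign.
- **Daily integration**: fluxes are already per-day quantities, so the
  daily net flux is the unweighted mean of the day's 15-min means; its
  SE is the SD of those means /√n. Using 15-min means rather than 10-s
  records avoids serial-correlation underestimation of the SE. Days
  with less than 50 % interval coverage are reported missing with a
  reason.
- Partial pressures come from dry mole fractions times total pressure;
  no water-vapor correction is applied because the analyzer measures a
  dried gas stream (a toggle exists but is deliberately unimplemented).

## Budgets and CO₂ equivalence

Annual fluxes are first-order estimates: Σ_seasons daily-mean ×
season-length, with quarter-year defaults (91.3125 d) and per-season
overrides. Seasonal campaigns are treated as independent, so the
propagated error is the root-sum-square of (SE × length). CH₄ is
converted to CO₂ equivalents with the sustained-flux GWP over a
100-year horizon (45, mass basis) — the appropriate metric for
ecosystems that exchange gas continuously rather than as a pulse; the
pulse GWP is intentionally not offered, and the SGWP value lives in
the constants file, not in code. Reported balances are rounded to
integer g CO₂-eq and integer percent; full precision is kept
internally. The offset percentage is 100·CO₂-eq(CH₄)/|F_CO₂|, labelled
an offset for a CO₂ sink and an augmentation for a source; it is
undefined (reported missing) when F_CO₂ = 0. This accounting describes
instantaneous radiative balance, not long-term carbon burial.

## Summary-statistics ANOVA / Tukey HSD

Group means, SDs and sizes are sufficient statistics for the one-way
ANOVA and the Tukey-Kramer intervals, so published comparisons can be
reproduced exactly from printed summaries. The studentized-range
quantile comes from `scipy.stats.studentized_range` (accurate well
beyond 10⁻⁴ in q); an independent cross-check against raw-data
`scipy.stats.tukey_hsd` on random fixtures is part of the test suite.
Pair sign follows the declared input order (published tables sometimes
mix sign conventions); with two groups the interval reduces to the
pooled-t interval (q = √2·t), which is also tested. Reproduction of
printed CIs is limited by the rounding of the published summaries:
endpoints match to the printed precision (±0.01), not necessarily in
the second decimal's rounding direction.

## Oxygen penetration depth

OPD is the shallowest depth at or below the sediment-water interface
where O₂ < 1 µM and stays below it for a persistence window of 3
consecutive 100-µm points (300 µm). The window is a robustness choice
against microsensor noise — the underlying rule states only the
threshold — and a single spurious dip therefore does not set the OPD.
Profiles that never durably cross the threshold return "not reached".

## Synthetic campaigns

The generator emulates the study conditions: 45-min water/air cycles,
10-s records, a diel pCO₂ cycle whose undersaturation minimum sits in
the 13:00–17:00 window, persistent CH₄ supersaturation at tens of
nmol L⁻¹, brackish salinity drawn once per campaign from 6.6–7.0 PSU,
Weibull wind (shape 2) with one-hour AR(1) persistence mapped through
the Weibull quantile function, a 1.5-m mast whose sensor wind is
derived from the true U₁₀ (so the pipeline's 10-m adjustment is
exactly invertible), first-order analyzer response (τ = 60 s) after
every phase switch, and additive Gaussian instrument noise (0.5 ppm
CO₂, 0.001 ppm CH₄ at 10 s). Wind and gas fields are independent by
default; their real cross-correlation is unknown. All draws flow from
a single seeded generator, so campaigns are byte-reproducible.

The 12 presets (3 habitats × 4 seasons) fix pCO₂ level/amplitude,
dissolved CH₄, temperature and wind scale so that default daily net
fluxes land inside the seasonal magnitudes observed for each habitat
type (CH₄ ~0.1–2.9 mg m⁻² d⁻¹ across habitats; CO₂ between strong
uptake and moderate release). They are calibration envelopes — chosen
once, not fitted distributions.

The truth ledger stores per-minute partial pressures, K₀, k and
instantaneous fluxes computed with the same bulk functions the
pipeline uses, daily trapezoidal flux averages, cycle boundaries and
the set of lag-contaminated records (within 2τ of a switch). Recovery
tests run 100 independently seeded one-day campaigns per preset
through the full pipeline and require ≥95 % of daily estimates within
2 ledger SEs of truth and a mean error inside a 99 % normal CI around
zero. Problem sizes (one day per replicate, 100 replicates, three
summer presets) keep the Monte-Carlo suite around a minute while
leaving the within-2-SE criterion far from its boundary.

**What passing does not show.** The generator contains no ecosystem
metabolism, tides, rain, wind-wave interaction, equilibrator fouling,
calibration drift, or correlated sensor error; recovery success
demonstrates that the pipeline's QC, referencing, averaging and unit
chain are unbiased and correctly propagated under the stated
observation model, not that real campaigns achieve this accuracy.

## Numerical conventions

- Half-open windows and intervals everywhere; timestamps are local
  clock time.
- Sample SDs use ddof = 1; single-record intervals report SD = NaN,
  single-interval days SE = 0.
- NaN inputs propagate as missing records through flux computation;
  they never raise.
- Recomputing a flux from its stored intermediates (k, K₀, Δp)
  reproduces the stored value bit-identically (tested).
- Range violations (solubility/Schmidt fits, salinity > 35) raise
  typed errors naming the gas and the fitted range.
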