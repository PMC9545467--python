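# Methods

## The detection model

`ventiscan` treats a ventilation episode (VE) as a *statistical* signature:
a multi-day period in which daytime CO₂ emission covaries with atmospheric
turbulence after the rank-linear influence of the ordinary meteorological
drivers has been removed. The underlying physical picture is that dry,
air-connected soil lets turbulence flush CO₂-rich vadose-zone air to the
atmosphere; turbulence (friction velocity u\*) is the trigger, low soil
water content the enabling condition, and the below-ground CO₂ store the
magnitude control. The algorithm does not model that physics — it screens
for periods where the ecophysiological interpretation of a positive flux is
implausible and the turbulence coupling is strong.

Three assumptions shape the screen: turbulence must be high enough to pump
air out of the soil (u\* > 0.2 m s⁻¹); no nocturnal ventilation is expected
(night-time stability and surface re-humidification close the soil-air
connection, hence the daytime-radiation filter); and air-temperature or
soil-moisture variability within the window must be too small to explain
the flux variation (the day-1 vs day-5 stability bounds of 3 °C and 1 %).
A 5-day window is the shortest span over which these conditions make the
attribution unambiguous, so the year is tiled into 73 consecutive 5-day
blocks anchored at 1 January; day 366 of a leap year falls into the
discarded remainder. Non-overlapping tiling keeps the "number of VE" per
year well defined; a `stride_days` option provides sliding windows for
sensitivity work.

## Partial Spearman correlation

The statistic is Spearman-based because the ventilation response to u\* is
expected to be monotone but not linear. All columns are midrank-transformed;
the ranks of F_c and u\* are residualised by OLS on an intercept plus the
covariate ranks (TA, VPD, TS, PA, SWC, SW_IN, PPFD_IN, the ones mapped at
the site); the coefficient is the Pearson correlation of the residuals.
Significance uses the standard partial-correlation test,
t = ρ√((n−2−k)/(1−ρ²)) on n−2−k degrees of freedom, two-sided — the
decision rule's separate ρ > 0.2 condition supplies the direction. The test
is an approximation for ranked data; the suite verifies empirically that
under the null (F_c independent of u\* given the covariates, N = 150) the
p-values are KS-uniform and the joint rule fires in well under 5 % of
windows.

Numerical choices: a covariate whose ranks add nothing to the design span
(constant columns, or exact rank duplicates such as a PPFD channel that is
a fixed multiple of SW_IN) is pruned deterministically in configured
covariate order, and the pruning is recorded per window. Residual sums of
squares below 10⁻¹⁰ of the centred rank variance mean the correlation is
*undefined* (e.g. F_c constant after filtering); the detector maps that to
"not VE, degenerate", never to a numeric ρ = 0. An independent
precision-matrix route (invert the Spearman correlation matrix of
[F_c, u\*, Z]; ρ_partial = −Ω₁₂/√(Ω₁₁Ω₂₂)) is implemented alongside and the
two routes are required to agree to 10⁻⁸ in the tests.

## Thresholds and their strictness

All record-level inequalities are strict, as their definitions read:
radiation > 50 (W m⁻² for SW_IN, µmol m⁻² s⁻¹ for the PPFD_IN fallback —
separate configurable thresholds because the units differ), F_c > 0,
u\* > 0.2 m s⁻¹, N > 40, ρ > 0.2, p < 0.05, and the precipitation cut
excludes records with P > 10⁻⁵ mm. The two stability bounds are inclusive
tolerances (|Δ| ≤ 3 °C, ≤ 1 %). Stability means use every non-missing
half-hour of the window's first and last calendar days, *before* record
filtering: the stability criteria describe the window's weather, not the
filtered subsample. Removed records are attributed to the first criterion
they fail, in the order night → non-positive flux → rain → low u\* → bad
qc → incomplete covariates, which makes the filter report additive and
order-independent. Missing precipitation drops the record when the site
maps a precipitation column (the value is unknown, not zero) and is treated
as zero only when no precipitation column exists at all; an unmapped qc
flag passes all records, since there is nothing to test.

Multi-year records: ≤ 4 years → analyse all; 5–6 → first four consecutive;
> 6 → years 1, 3, 5, 7 of the record ("first four non-consecutive"); the
reported year is the one with the most VE, earliest on ties. Both choices
where the policy was genuinely open (the alternating-year reading and the
tie-break) are explicit config parameters and recorded in `run.json`.

## The synthetic scenario

The generator emulates a winter-wet / summer-dry semiarid site at
half-hourly resolution: clear-sky radiation (seasonal amplitude × clipped
diurnal cosine, day length 8.8–15.2 h) with daily cloud attenuation; air
temperature as seasonal + diurnal harmonics plus a stationary AR(1) anomaly
(sd 1 °C); soil temperature as a 5-day running mean of TA; a wet-season
precipitation event process (DOY ≤ 120 and ≥ 300, 0.35 events day⁻¹, mean
8 mm); a soil bucket (capacity 30 %, residual 2 %) gaining 1.2 % per mm of
rain and losing water with a radiation-scaled e-folding of ~15 days, which
produces the characteristic 5-month drydown to ~2 % SWC; lognormal AR(1)
friction velocity with a daytime-enhanced mean (0.46 m s⁻¹ day, 0.12
night); VPD from saturation vapour pressure with relative humidity tied to
soil moisture; and a biosphere with a rectangular-hyperbola light response
down-regulated below 15 % SWC (GPP ≈ 0 below the 5 % wilting level) and
Q10 respiration with a dry-soil floor. Net flux is
F_c = −GPP + R_eco + VE + ε, ε ~ N(0, 0.7 µmol m⁻² s⁻¹); 1 % of values per
variable are deleted and 3 % of records get a non-zero qc flag. This makes
the dry season a weak daytime CO₂ source — exactly the regime in which
ventilation detection must not confuse respiration with venting.

The injected mechanism is the simplest form consistent with a monotone
flux–turbulence coupling: `ve_flux = gain · max(0, u\* − 0.15)` inside six
scheduled 5-day blocks (window indices 41–51, DOY 206–260, the driest
stretch of the drydown), during daytime and only while SWC < 8 %. All
random draws flow from one seeded generator in a fixed, schema-versioned
order, so a scenario + seed reproduces the CSV fixture byte for byte.

**Gain calibration.** The default gain (4.7 µmol m⁻² s⁻¹ per m s⁻¹) was set
by pilot runs over seeds 0–14 so that the *detected* within-block partial
coefficient averages ≈ 0.6 — the mid-range of coefficients the screen is
designed to flag — with ~80–120 surviving records per block. The weak level
used in the monotonicity checks is 1.5 (≈ 0.5 recall in the pilot). The
generator's defaults are fixed study conditions, not tuning knobs: tests
and the acceptance script consume them as-is.

**What the simulation does not contain**: real footprint variability,
energy-balance closure, multi-layer soil gas transport, instrument spikes
and long outage gaps, or advection. Passing the injection–recovery checks
therefore demonstrates the *algorithm's* correctness and calibration under
realistic statistical structure, not field performance at any particular
tower; on real archives, data gaps and unmapped ancillary variables will
lower window admission rates in ways Table-style availability indicators
(`data_availability`) are meant to expose.

## Problem sizes

The test suite and `scripts/acceptance.py` use 25–50 simulated site-years
per condition (a site-year is 17,520 half-hours; detection visits 73
windows), 2,000 null windows of N = 150 for calibration, and 100 seeded
instances (n = 240, k = 7) for the dual-route statistical checks — sizes at
which the stochastic acceptance quantities are stable to a few percent
while the whole battery completes in about a minute on one CPU.

## Known limitations

- The t-approximation for ranked partial correlation is slightly
  conservative at small N; with the N > 40 admission rule this is
  immaterial in practice.
- SWC percentile diagnostics use the midrank convention on the year's
  half-hourly distribution; sites that report SWC at a different depth than
  the ventilation-relevant horizon may shift these percentiles.
- The multi-year policy analyses at most four years; a site whose episodes
  only occur later in a long record will be reported as episode-free.
- Units are canonical by convention (no inference); the reader only guards
  against the common fractional-vs-percent SWC mistake.
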