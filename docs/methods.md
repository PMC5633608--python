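# Methods

## Model

Production per picophytoplankton group is carbon-based rather than
chlorophyll-based: standing stock is converted from cell counts to
carbon and multiplied by a temperature-derived growth rate, avoiding
the notoriously plastic Chl:C ratio. Depth-integrated production is

    PP_g = C_g · μ_g · Z_eu · h(I₀)        [mg C m⁻² d⁻¹]

and total picophytoplankton production is the sum over the three
groups. The volumetric form `PP_g = C_g · μ_g` (mg C m⁻³ d⁻¹) is used
wherever the reference measurement is a volumetric incubation.

Key structural assumptions:

- **Surface biomass drives the column.** C and μ are evaluated from
  surface values only; the vertical structure of carbon fixation is
  absorbed entirely into the scalar factors Z_eu and h(I₀). This
  matches the observation that picophytoplankton abundance shows no
  significant depth structure within shallow euphotic zones, but it is
  wrong where deep chlorophyll maxima dominate.
- **Growth depends on temperature only.** Light and nutrient limitation
  of μ are not modelled; this is the model's main acknowledged bias.
- **Fixed per-group CCFs.** Cellular carbon is assumed constant within
  a group; the sensitivity sweep (below) quantifies what that
  assumption costs.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| CCF direct (Pro/Syn/Euk avg) | 36 / 255 / 2590 | fg C cell⁻¹ | culture compilation; min–max 16–53 / 170–350 / 800–4400 |
| CCF in_situ (avg) | 60 / 154 / 1319 | fg C cell⁻¹ | cytometric cell size × carbon:volume; averages only, so the stored min = max = average |
| Pro eMIT9312 | −4.17 + 0.40 T − 0.0086 T² | d⁻¹, T °C | maximum ≈ 0.481 d⁻¹ at 23.26 °C |
| Pro eMED4 | −1.11 + 0.14 T − 0.0035 T² | d⁻¹, T °C | high-latitude ecotype |
| Syn Arrhenius | E = 0.73 eV, ln μ_c = 28.13 | — | fitted over 10–34 °C; outside → `out_of_range` flag |
| Euk Arrhenius | E = 0.86 eV, ln μ_c = 33.85 | — | field fit, valid at Chl ≥ 0.5 mg m⁻³ |
| Boltzmann k | 8.62 × 10⁻⁵ | eV K⁻¹ | |
| h(I₀) | 0.66125 · I₀/(I₀ + 4.1) | — | I₀ in mol photons m⁻² **per day** (the daily convention is the only one consistent with the 4.1 half-saturation and typical field values of 16–50) |
| Z_eu | −ln(0.01)/k490 | m | sign chosen so depth is positive; external (IOP) Z_eu wins when present |

Coefficients ship as YAML (`picopp/data/`); a user file with the same
layout overrides them, so no coefficient is hard-coded in logic.

### Design choices where the design was open

- **Prochlorococcus ecotype mixing.** No mixing rule between the two
  high-light ecotypes is established; the default is the arithmetic
  mean of the two curves (averaged before clamping), with either
  ecotype selectable. Both are warm-water ecotypes and neither
  dominates a priori at a random station.
- **Negative quadratic growth clamps to zero** (with a `clamped` flag)
  instead of raising: cold-season coastal stations would otherwise
  produce negative production, which is physically meaningless but not
  an input error.
- **Low-chlorophyll picoeukaryotes.** Below 0.5 mg Chl m⁻³ the
  temperature fit is not significant and overestimates μ by ~58% on
  average. No alternative model exists, so the curve is still applied,
  flagged `low_chl_warning`; an optional divisor of 1.58 is available
  (`correct_low_chl_bias`) and off by default.
- **Extrapolation is permitted but flagged**: winter shelf applications
  evaluate the *Synechococcus* curve at ~6 °C, below its 10–34 °C fit
  range, and this should be visible rather than fatal.
- **Missing group abundance contributes zero** and is flagged
  (`missing_abundance`): *Prochlorococcus* is genuinely absent from
  some temperate shelf seas, which is information, not an error.

## CCF sensitivity analysis

Each group's CCF is swept from its published minimum to maximum in 10%
increments of the span — 11 inclusive levels — and volumetric PP = C·μ
is recomputed per station; distributions over the record set are
summarised as median, mean and a 2.5–97.5% interval. Because PP is
exactly linear in the CCF, the max/min PP ratio per group equals the
pure CCF ratio (Euk 5.5, Pro 3.31, Syn 2.06) for any record set with
nonzero abundance, and the total-PP spread lies between those extremes
(typically ~3-fold for mixed communities). Two modes: `joint` moves all
three CCFs together (default); `per_group` varies one group with the
others held at their averages. The box-whisker statistics of any
particular published rendering are not reproduced — only the summary
statistics named above are claimed.

## Model-II validation

Estimated and measured production both carry error, so the
estimated-vs-measured comparison uses reduced major axis regression:
slope = sign(r)·s_y/s_x, intercept = ȳ − slope·x̄, with y = estimated
and x = measured, so slope − 1 reads directly as fractional model
overestimation. r² is the squared Pearson correlation *on the scale of
the fit* and is reported for raw and log₁₀-transformed data; under
log₁₀, pairs with a nonpositive member are dropped with a logged count.

Confidence intervals default to a seeded bias-corrected percentile
bootstrap over pair resamples (1999 resamples): production data are
heavy-tailed and the closed-form interval is optimistic there. The
analytic RMA interval (one-sample-t form, as in R's `lmodel2`) is
available via `ci_method="analytic"`. Bootstrap replicates with zero
resample variance are discarded from the percentile computation.

## Synthetic data

`generate_stations` emulates a basin-spanning compilation of paired
flow-cytometry / ¹⁴C records: SST uniform over 0–30 °C, PAR uniform
over 15–55 mol photons m⁻² d⁻¹, chlorophyll / k490 / abundances
log-normal (field abundances span orders of magnitude, so additive
Gaussian noise would be unfaithful), *Prochlorococcus* present with
probability 0.8. The latent abundances drive the model's latent
production `PP*`; the "measured" value is

    pp14c = PP* / bias · exp(ε),   ε ~ N(0, noise_sigma²)

while the *recorded* abundances carry an independent shared
counting/calibration factor `exp(δ)`, δ ~ N(0, abundance_noise_sigma²),
which propagates into the recomputed estimate. Splitting the error
across both axes this way is deliberate: RMA regression presumes error
in both variables, and with error on the measured side only the RMA
slope provably attenuates far below the injected bias (by ~40% at
realistic scatter) — a property of the estimator, not a bug. With
balanced errors the estimated:measured RMA slope recovers `bias`.

Defaults: `noise_sigma = 0.5` per side (natural-log scale), with
`abundance_noise_sigma = None` meaning "same as noise_sigma". This
calibration puts the raw-scale r² of estimated vs measured near 0.5,
the scatter typical of basin-scale production comparisons. A
200-replicate experiment at n = 171 stations per survey recovers an
injected 1.7× bias with median RMA slope within a few percent of 1.7
(the median, not the mean, because single-survey slopes are
heavy-tailed).

`bohai_fixture` draws temperate shelf stations per season around
published cruise means (Gaussian environment truncated positive;
abundances log-normal with moment-matched mean and sd; external Z_eu
always present; *Prochlorococcus* absent). At 50 stations, June totals
land at ~110–170 mg C m⁻² d⁻¹ — the right order, though not the exact
published seasonal means, which average per-station products that the
fixture only emulates distributionally.

What the generators do **not** emulate: spatial autocorrelation,
seasonal succession, satellite pixel geometry, depth structure, or any
real covariance between temperature and abundance. Passing tests on
synthetic data therefore demonstrate pipeline correctness and estimator
behaviour, not field skill; field skill requires real paired datasets.

## Numerical notes

- Temperature converts as T(K) = T(°C) + 273.15; temperatures at or
  below absolute zero, or non-finite, are rejected.
- Unit conversion in biomass is exact: cells mL⁻¹ × fg C cell⁻¹ × 10⁻⁶
  = mg C m⁻³ (1 m³ = 10⁶ mL, 1 fg = 10⁻¹² mg).
- The sensitivity grid endpoints are inclusive; level j uses
  CCF = min + j·(max − min)/10, j = 0..10.
- Degenerate RMA inputs (zero variance in either axis, n < 3,
  non-finite values) raise `ValueError` rather than returning NaNs.
- Station CSVs round-trip byte-identically (reads use round-trip float
  parsing); all CLI outputs carry a `.meta.json` sidecar with package
  version, config hash and seed, so runs are replayable from the
  sidecar alone.
- Problem sizes used by the shipped experiments (200 replicates × 171
  stations for bias recovery; 50-station seasonal fixtures) were chosen
  to make Monte-Carlo medians stable at interactive runtimes.

## Known limitations

- Growth ignores light and nutrients; the picoeukaryote curve is a
  community-level fit with large residual variance (r² ≈ 0.4 in the
  source data), so per-station μ_Euk is the least certain factor.
- Fixed CCFs introduce up to ~5-fold uncertainty for picoeukaryotes;
  variable (size-calibrated) CCFs would be the natural upgrade.
- The in_situ CCF set has no published spread, so sensitivity analysis
  over it is degenerate (flat).
- The Z_eu formula overestimates euphotic depth in turbid coastal
  water; supply an external Z_eu there (the default preference when
  both are present).
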