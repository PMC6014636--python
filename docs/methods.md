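# Methods

`antestia` models how temperature, acting through the full life cycle of
the coffee antestia bug (*Antestiopsis thunbergii*, a pentatomid pest of
Arabica coffee), shapes its infestation risk along an East-African
elevation transect, and how that risk shifts under a moderate-warming
scenario. This note documents the model, its numerical choices, and the
limits of what the synthetic test system can show.

## Stage-structured thermal model

The life cycle is an egg stage plus five nymphal instars followed by
adults. Each immature stage *i* carries two temperature responses:

* a **development rate** `r_i(T)` (day⁻¹), Brière-1 by default
  (`a·T·(T−T_min)·√(T_max−T)`), zero at or beyond the thermal limits
  `T_min = 14.6 °C` and `T_max = 32.9 °C`;
* a **cumulative stage mortality** `m_i(T) ∈ [0, 1]`, expressed through
  its hazard `q_i = −ln(1 − m_i)`.

Adults carry a lifetime **fecundity** `f(T)` (eggs · female⁻¹) and a
**senescence rate** (day⁻¹) whose reciprocal is the adult lifespan
`L(T)`. Response families are selected by name in a plain-text species
parameter file, so alternative curve shapes can be swapped in without
code changes.

At constant temperature the six life-table parameters follow in closed
form: development time `D = Σ 1/r_i`; immature survival
`s = Π(1 − m_i)`; gross reproductive rate `GRR = sex_ratio · f`;
net reproductive rate `R₀ = s · GRR`; generation time
`T_gen = D + L/2` (egg laying spread uniformly over adult life, so the
mean age of reproduction sits at mid-lifespan); intrinsic rate of
increase `r_m = ln R₀ / T_gen`; finite rate `λ = exp(r_m)`; doubling
time `Dt = ln 2 / r_m`. The closed form is verified in the test suite
against an independent day-stepping cohort simulation (relative
tolerance 1e−6). Whether a pre-oviposition delay belongs in `T_gen` is
an open biological question; the mid-lifespan convention is a
documented choice, not a claim about any particular laboratory study.

Fluctuating regimes use **rate summation**: every response is averaged
arithmetically over the temperature samples of the regime, except
mortality, which is averaged on the hazard scale (so one sample at a
fully lethal temperature extinguishes the stage — probabilities do not
average, hazards do).

## Risk indices

A year is 365 Julian days of (t_min, t_max); leap days are dropped on
ingest. The within-day cycle is a 24-point cosine between the extremes
(minimum at 02:00, maximum at 14:00, mean exactly the midpoint); the
original analysis environment does not publish its internal profile, so
this standard reconstruction is a documented alternative, not a claim
about that software.

* **ERI** (establishment risk): a day is *lethal* for stage *i* when its
  rate-summed daily survival `exp(−mean_h q_i)` falls to ≤ 0.005
  (configurable; exact zero is unreachable with smooth curves). ERI = 1
  − (days with at least one lethal stage)/365.
* **GI** (generations · year⁻¹): accumulated as `Σ_d 1/T_d` over the
  daily generation times. At constant temperature this equals `365/T`
  exactly; under fluctuation it is day-order invariant, which the
  alternative `365/mean(T_d)` is not.
* **AI** (activity): `Σ_d log₁₀ λ_d` with each day's contribution
  floored at `log₁₀ exp(rm_floor)`; fully lethal days contribute exactly
  the floor.

`rm_floor` defaults to −0.02 day⁻¹. The reasoning: a fully lethal day
kills the day's exposed immature cohort slice, not the standing
population — immatures develop over roughly a month, so one lethal day
removes on the order of a few percent of the population, i.e. a daily
log-decline of order 0.01–0.03. A large floor (say −0.5 day⁻¹, a 40 %
daily crash) would make the annual AI a near-duplicate of the lethal-day
count and erase the characteristic contrast in which establishment risk
*rises* with elevation while generation and activity indices *fall*.
The floor is exposed in the species file and the run configuration so AI
sensitivity to it can be reported. Flooring every day (not only flagged
ones) keeps the index continuous across the lethality threshold;
without it, days just below the threshold dominate the annual sum.

## Calibrated default species set

The published account of this system reports derived quantities, not
fitted curve coefficients, so the default parameter set is synthetic but
constrained: it is calibrated, once, to reproduce every printed
property of the bug's thermal biology —

1. development limits 14.6 / 32.9 °C;
2. positive intrinsic growth exactly on 19–25 °C (0.5 °C grid);
3. 2.6–4.4 potential generations · year⁻¹ across that window;
4. 89 % total immature mortality at 30 °C;
5. immature survival maximal at 22–24 °C —

plus the qualitative elevation contrast above. `thermal_constraint_report()`
re-runs all five checks. The shapes that satisfy these jointly: an
asymmetric quadratic hazard (chronic cold stress much stronger than
chronic warm stress, matching a tropical montane insect), a very steep
(power-60) acute heat-stress term anchored by the 89 %-at-30 °C
observation — which places total-mortality days at daily maxima of about
31 °C — and a warm-skewed fecundity curve (peak 24.4 °C) with a small
residual plateau (2.2 eggs) so that net reproduction falls just below
replacement, rather than collapsing, outside the growth window. Adult
lifespan is 110 days at 25 °C, declining gently with warmth; total
immature development is 30 days at 25 °C.

## Synthetic study system

The generators emulate the study transect with the statistical structure
the analysis assumes:

* **DEM**: ~11 × 2 km, cells 100 m (configurable), a monotone ramp from
  1000 to 1700 m asl with ±5 m smoothed roughness; area ≈ 22 km².
* **Loggers**: 9 stations from 15 % above the transect floor to its top
  (the field deployment started ~80 m above the floor), zig-zagging
  across the width. Daily midpoint = 28.9 °C − 5.73 °C/km × elevation +
  a 1.8 °C single-harmonic seasonal cycle coolest in mid-July; minima
  and maxima sit ±6 °C around it. The lapse rate is the regression slope
  through the five published logger rows; the intercept is set ~0.6 °C
  below the regression so annual means span ≈ 19–23 °C, consistent with
  the published range (the 1249 m row is an inversion outlier no linear
  model fits). Day-to-day anomalies are regional — shared by all
  loggers, as cloud cover is on a 22 km² transect — with SD 0.8 °C
  (minima) and 3.0 °C (maxima, matching the published SDs) plus a 0.2 °C
  per-logger component; anomalies are centred so configured annual means
  are exact.
* **Future scenario**: additive per-station (Δt_min, Δt_max) interpolated
  by elevation from the five published current-vs-2055 rows; deltas are
  applied exactly, day by day.
* **Survey**: 24 farms in groups of 4 near 1100–1600 m; farm totals over
  15 trees are gamma-Poisson (variance = 2 × mean) around
  `exp(−3.43 + 0.0038·elev + season)`, cool seasons +0.35 and the warm
  season −0.35 on the log scale (cool ≈ 2 × warm); per-tree counts are a
  multinomial split of the farm total.

What the synthetic system does **not** emulate: humidity and rainfall,
microclimate/shade heterogeneity between farms, natural enemies (egg
parasitoids), spatial autocorrelation of counts beyond the elevation
trend, multi-year weather, and any real GCM grid structure. Passing
tests therefore demonstrate that the pipeline recovers the structure it
assumes — not that the structure is a complete description of the field
system.

## Spatial interpolation

Station values spread over the DEM as
`value = a + b·elev + Σ w_j φ(‖x − x_j‖)` with the thin-plate kernel
`φ(r) = r² log r` on (lon, lat) and the usual orthogonality side
conditions; the augmented linear system is solved directly. Smoothing
defaults to 0 (pure interpolation; the stations are reproduced to
≤ 1e−6). Coordinates are WGS84 degrees; planar TPS on degrees is
accepted at the ~11 km scale of the transect. Rasters are north-up with
centre-registered cells; point sampling is nearest-cell. ERI maps are
clipped to [0, 1] after interpolation. Rasters write as Arc/Info ASCII
grids (6 significant digits, byte-stable round trip) and as GeoTIFF with
ModelPixelScale/ModelTiepoint tags.

Elevation-band sampling draws the same `n` cells per 100-m band
(centre ± 50 m, half-open above) from every raster, so current and
future values stay paired; selections are reproducible under a seed.

## Survey statistics

Farm counts are fitted with a log-link Poisson GLM (`count ~ elevation`
or `count ~ season`). Overdispersion is corrected iteratively: estimate
the dispersion φ from the Pearson statistic, downweight every
observation by 1/φ, refit, repeat until φ stabilises at 1 (tolerance
1e−8, cap 100 iterations; equidispersed data are a fixed point and the
reported dispersion never falls below 1). With scalar weights this
leaves the coefficients at their Poisson values and inflates standard
errors by √φ — the quasi-Poisson correction, arrived at through the
weighted-likelihood recursion. The goodness-of-fit χ² is the weighted
deviance.

Post-hoc season comparisons are single-step adjusted pairwise contrasts
on the linear predictor using the studentized range distribution — a
Tukey analogue for a GLM, and labelled as such since a literal Tukey
test is undefined here.

The current-vs-future comparison is a **paired** Wilcoxon signed-rank
test per elevation band and index (the same cells are sampled under both
climates; the saturated statistic `W = n(n+1)/2 = 210` at `n = 20` is
only reachable in the paired form). `W` is the rank sum of positive
`future − current` differences; zero differences are dropped and ties
take average ranks. For `n ≤ 25` the exact null distribution is built by
dynamic programming over sign assignments (on doubled ranks, so tied
half-integer ranks stay exact); beyond that, a normal approximation with
tie-corrected variance and continuity correction. Significance stars
follow the figure convention: * < 0.05, ** < 0.001, *** < 0.0001.

## Problem sizes and determinism

Default problem sizes are chosen so a full pipeline run completes in
seconds on one CPU: 100 m DEM cells (2 200 cells), 9 × 365-day stations,
160 band points, 24 × 4 survey records, 500-replicate parameter-recovery
simulations. Every stochastic step takes an explicit seed; identical
configuration and seed reproduce byte-identical CSVs and value-identical
rasters, and each CLI run writes a manifest with input hashes and seeds.

## Known limitations

* The lethality threshold (0.005 daily survival) and the within-day
  cosine are plausible conventions, not measurements; ERI levels (though
  not their elevation ordering) are sensitive to both.
* GI accumulated as `Σ 1/T_d` diverges from `365/mean(T_d)` under strong
  fluctuation; the accumulation form is used because it is day-order
  invariant and matches the printed definition at constant temperature.
* The TPS carries no uncertainty; interpolated maps inherit station
  noise without flagging it.
* Counts below ~1 per farm make the elevation GLM fragile in single
  seasons; the recovery guarantee (slope within 3 SE in ≥ 95 % of
  replicates) holds at the default effect size and sample layout.
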