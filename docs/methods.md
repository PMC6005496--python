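# Methods

This note documents the models, conventions and design choices behind
`efasdm`, in the order the pipeline runs them.

## Virtual landscape generator

The generator emulates the statistical structure of the inputs a
multi-scale SDM study needs, not any particular place.

**Terrain and climate.** Elevation is a smoothed Gaussian random field
scaled to 0–2500 m. Monthly mean temperature is a seasonal harmonic
(sea-level mean 15 °C, amplitude 8 °C, July peak) minus a lapse of
6.5 °C km⁻¹; monthly maxima/minima sit ± 5 °C around the mean, so the
ordering tmax ≥ tmean ≥ tmin holds by construction. Precipitation is a
winter-peaked harmonic around a sea-level annual total of 800 mm plus
50 mm per 100 m of elevation, clipped at zero. The resulting gradients —
annual means of roughly 5–15 °C and totals of roughly 600–3000 mm along
the relief — are typical of an Atlantic-Iberian mountain region, the kind
of setting where EFA-based SDMs are of practical interest.

**Land cover.** A smoothed random field, pulled upward by elevation so
bare soil concentrates on the tops, is quantile-thresholded into four
classes (`agric`, `forest`, `scrubs`, `bs`). It is generated on a grid
`landcover_subfactor` (default 4) times finer than the climate grid,
mirroring the usual situation of a ~100 m land-cover product under a
1 km analysis grid; the modal class per fine cell drives the satellite
harmonics. The smoothing length is the patchiness knob.

**Satellite series.** Each dimension is a per-cell seasonal harmonic plus
Gaussian observation noise, clipped to its physical range: EVI ∈ [−1, 1],
LST ∈ [−25, 45] °C, albedo ∈ [0, 1]. Baselines, amplitudes and peak days
are land-cover-specific (spring-peaking crops, summer-peaking damped
forest canopy, bright bare soil) and climate-coupled (wetter cells are
greener, warmer cells have stronger EVI seasonality). LST tracks monthly
air temperature interpolated to composite dates, with a class-dependent
seasonal amplitude (canopy damping ×0.7, bare-soil amplification ×1.35):
without that dependence the annual mean, maximum and minimum of LST would
be exactly collinear, which no real product exhibits. Composites follow a
fixed 16-day calendar starting on day 1 (23 per year). Because the
satellite dynamics are generated *from* the climate and land cover, EFAs
are genuine proxies of the traditional predictors — the condition under
which EFA-based and CLI+LC-based models should perform alike.

**Virtual species.** True suitability is
`logistic(β₀ + Σ βᵢ zᵢ)` over standardized driver predictors; if a target
prevalence is given the intercept is re-solved by bisection. Presences
are drawn without replacement with probability proportional to truth
(optionally × a bias layer; default unbiased), one jittered point record
per drawn cell so the same records can be re-binned at a coarser grain.
No true absences are ever emitted by the sampling path — the modelling
pipeline is strictly presence-only.

What the generator does **not** emulate: cloud gaps and QA masking,
spatially structured observer bias (the bias layer exists but defaults to
off), inter-annual climate anomalies (years differ only by noise), and
mixed pixels (one harmonic per cell). Passing tests therefore show the
pipeline recovers structure under clean, stationary conditions; they do
not certify performance on real archives.

## EFA metrics

Eight metrics per dimension and year: mean, max, min, standard deviation
(population form — the composites are the complete annual cycle), and the
sine and cosine of the days of maximum and minimum with
θ = 2π·doy/365 (leap days folded into day 365). This convention anchors
sin ≈ +1 to late March/April ("springiness") and cos ≈ +1 to late
December/January ("winterness"). Argmax/argmin ties break to the earliest
day, for determinism. Interannual averaging is done on each year's
sin/cos *components* (vector averaging), never on the dates: two years
peaking in spring and autumn average to ≈ 0 on both axes rather than to a
fictitious mid-summer date. Codes follow `{DIM}{suffix}` with suffixes
`av, mx, mn, sd, dmxs, dmxc, dmns, dmnc` — 24 rasters.

## Climate and land-cover predictors

Bioclim quarters are the 12 wrap-around windows of three consecutive
months (December–February allowed), ties broken to the earliest window.
TmWQ/TmDQ are the mean temperature of the wettest/driest quarter by
cumulative precipitation; PpWM/PpDM the wettest/driest monthly totals;
TAR the mean monthly range (mean over months of tmax − tmin); PS the
coefficient of variation of monthly precipitation in percent (population
sd over mean). Temperatures are plain °C throughout.

Landscape metrics are computed per analysis cell from the finer
land-cover raster: class fractions of all fine cells (nodata lowers the
sum below 1), Shannon diversity −Σ pᵢ ln pᵢ over the classes present, and
mean patch area of 8-connected patches clipped at the cell boundary.
Per-cell clipping (rather than landscape-wide patch delineation) keeps
the metric local and deterministic. Continuous rasters aggregate to
coarser grains by block means excluding nodata; categorical rasters
expand to per-class fraction rasters.

## Screening

Candidates are ranked by the cross-validated AUC of a single-predictor
logistic model on the cells the models will actually see (presences plus
the first pseudo-absence set). Selection is greedy by descending
priority, skipping candidates with Spearman |ρ| ≥ 0.8 against an
already-selected one; an iterative VIF filter (threshold 4) then removes
multicollinear survivors; the set is truncated at ⌊m/5⌋ predictors for m
presence records, and additionally at six predictors in the pipeline —
final model sets are conventionally held to six regardless of sample
size. Inside the selection the VIF filter is priority-aware: among
over-threshold columns the *lowest-priority* one is dropped first, so
that of a set of highly collinear predictors the most relevant survives
(the plain drop-largest variant is also provided as
`iterative_vif_filter`). This matters because near-exact linear
dependences — e.g. annual mean ≈ (max + min)/2 for any roughly harmonic
series — make the largest-VIF column an arbitrary member of a tied group.
An expert-override list can pin predictors past the correlation skip.

## Ensemble models

Pseudo-absences are random unoccupied valid cells, as many as presences,
with pairwise center distances of at least one grain (on a square grid
adjacent centers are exactly one grain apart, so the constraint reduces
to distinctness; it is checked explicitly and configurable upward).
Each member model is fitted on a stratified 80 % of records and scored on
the held-out 20 %: AUC by the tie-corrected rank (Mann–Whitney)
formulation; the binarisation threshold τ minimises
√((1−sens)² + (1−spec)²) over midpoints of consecutive unique scores
(ties toward the lower threshold); TSS = sensitivity + specificity − 1
at τ. The learner registry covers ten families — quadratic-term GLM,
ridge GLM, cubic-spline GAM, piecewise-linear adaptive splines, CART,
random forest, gradient boosting, a single-hidden-layer network,
discriminant analysis on a quadratic basis, and a from-scratch surface
range envelope scored as the fraction of predictors inside their
[2.5 %, 97.5 %] presence quantiles. The desk-scale default uses four
(glm, cart, rf, sre) with a 5 pseudo-absence sets × 5 runs design; the
full 30 × 30 × 10 matrix is a configuration away.

Members with AUC ≥ 0.7 form the ensemble; the continuous map is the
cellwise **median** of member probability maps (mean behind a flag), and
the ensemble's own τ comes from its scores on the pooled
presence/pseudo-absence records. Two AUC summaries are reported because
"ensemble AUC" is ambiguous: the median of member AUCs and the pooled
held-out AUC of the median map itself. Importance is permutation-based
(mean over permutations of 1 − |Pearson r| between reference and
shuffled-column predictions, in [0, 1]), normalised to contributions
summing to 1; only contributions > 0.1 are reported and given response
curves (focal predictor swept over its range, others at their medians).

## Map comparison

Fuzzy kappa builds, per map and category, a fuzzy membership raster as
the maximum of 2^(−d/halving) over same-category cells within the
neighbourhood radius (defaults: halving 2 cells, radius 4 — the usual
defaults of categorical map-comparison tools). A cell's similarity is the
minimum of the two one-way similarities (each map's crisp category read
off the other's fuzzy vector); κ = (P_obs − P_exp)/(1 − P_exp) with
P_exp the category-proportion product under random relocation. At radius
0 this is exactly Cohen's kappa. The autocorrelation-aware expectation of
the "improved" variant is not implemented; with the product-form
expectation our κ values are comparable across map pairs but not
numerically identical to that tool's output. Moran's I uses queen
contiguity with row-standardised weights over valid cells, computed on
the continuous suitability maps (binary behind a flag). Overlay
accounting splits the suitable union into A-only/B-only/overlaid areas
(km²) with percentages rounded half-even to two decimals; the partition
identity A-only + B-only + overlaid = union holds exactly by
construction.

## Experiment matrix and reproducibility

The orchestrator nests three square extents (defaults 60/40/20 cells a
side, echoing a sub-continental ⊃ regional ⊃ local design whose real
area ratios are far too extreme to reproduce literally) and two grains
(1 and 5 cells). The regional and local windows are placed where the
virtual species' truth is densest — as a protected area is placed around
a species stronghold — on a 5-cell lattice so 5 km alignment survives
nesting. The default virtual species is a cool-wet forest dweller
(TmWQ −2.0, forest +1.5, prevalence 0.15, 80 records), which yields
per-combination presence counts in the tens, the order of magnitude of
real rare-plant datasets. Every stage seeds its RNG with a CRC-32 hash of
the combination label mixed with the master seed (kept below 2³¹), so a
rerun of the same configuration is byte-identical, combination failures
are isolated, and inserting a combination does not reshuffle the others.

Validation harnesses: the **driver-recovery** experiment defines a
species from two strong EFA drivers (EVIdmxs +4, LSTmn −4 — a spring
phenology axis and a thermal axis, both from the canonical final
predictor set) among the 24 candidates, with 150 records on a 40 × 40
landscape, and asks whether screening keeps both, whether they take the
top-2 importance contributions, and how the ensemble scores on a fresh
validation sample. Fresh validation uses presences drawn ∝ truth *and
true absences drawn ∝ (1 − truth)* — available only because the species
is virtual; random background cells include genuinely suitable habitat
and would cap the attainable AUC well below 1 regardless of model
quality. Fitting never sees these labels. The **parity** harness fits
EFA-based and CLI+LC-based ensembles on the same climate-driven
landscapes and compares their member-AUC medians over replicates; the
margin of 0.05 AUC is the working definition of "performs as well as".

## Numerical conventions and limitations

Tie-breaks are always toward the earliest index (quarter windows,
argmax/argmin days, threshold candidates) for determinism. Nodata is NaN
everywhere and excluded from means, screening and scoring. Degenerate
inputs raise informative errors rather than returning silent defaults:
constant columns in Spearman/VIF, single-class splits after bounded
retries, all-equal scores at thresholding, constant maps in Moran's I.
Problem sizes in the test-suite harnesses (20–60-cell landscapes, 2–5
pseudo-absence sets, 2–4 learners) were chosen once as the smallest
configurations at which the experiments are stable; all thresholds come
from the modelling protocol, not from the suite. The package handles a
single planar CRS only — no reprojection, no geographic coordinates —
and the generator's clean-world assumptions mean results on real data
will be noisier than the synthetic benchmarks suggest.
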