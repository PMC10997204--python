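# Methods

This note documents the models, estimators, parameter defaults and
numerical choices behind `pfaa_ssa`, and what the synthetic fixtures do
and do not establish about real data.

## Enrichment-factor estimation

**Model.** For each PFAA homolog and aerosol size fraction, the
sodium-normalised SSA concentration is proportional to the
sodium-normalised seawater concentration; the proportionality constant
is the enrichment factor (EF). Sodium cancels the sampled air volume,
so EFs are dimensionless and typically 10³–10⁶.

**Censoring.** Seawater values below MDL_water are substituted by
MDL_water (a conservative upper bound that biases EFs low, if
anything); SSA values below MDL_SSA are excluded from regressions and
per-experiment EFs rather than substituted, because a substituted
numerator would manufacture spurious EFs. A censored entry without an
MDL is an error, not a silent drop. EFs are only estimated for
homologs detected in strictly more than 30 % of the water samples
(detection counted over all triplicate cartridges).

**Estimator selection.** Per homolog × fraction, the mean EF is the
slope of the through-origin total least squares (TLS) regression of the
SSA ratio on the water ratio across experiments when Pearson's
correlation is significant (two-sided p < 0.05, t-test with n − 2 df on
the raw paired values; a log-scale option exists), and otherwise the
geometric mean of per-experiment EFs. The TLS slope has the closed
form minimising Σ(yᵢ − s·xᵢ)²/(1 + s²); there is no intercept because
the model line passes through the origin. Regression requires ≥ 3
points with non-degenerate x.

**Uncertainty.** The slope CI is a nonparametric percentile bootstrap
over experiments (2000 resamples, seeded; degenerate resamples are
dropped). The geometric-mean CI is a Student-t interval for the mean
log EF, back-transformed. Both are 95 % by default (α = 0.05).

**Aggregation choices.** The experiment's water concentration is the
mean of the triplicate cartridges after substitution. The
representative diameter d_p of a pooled fraction is the geometric mean
of its bounding stage cutoffs. Linear and branched PFOS are carried as
separate homologs through estimation and pooled (relabelled into one
homolog, so their points enter one regression collectively) for the
flux estimates.

**Known estimator limitation.** With slopes far above 1 — EFs of
10³–10⁶ mean the fitted line is almost vertical in raw units — the
orthogonal-distance objective asymptotically reduces to the inverse
regression Σy²/Σxy. Under multiplicative log-normal scatter with
geometric standard deviation g, that functional carries a geometric
bias of about e^{1.5·ln²g} (≈ 1.28 for g = 1.5) and the percentile
bootstrap centres its interval on the biased estimate. The geometric
mean estimator is unbiased on the log scale under the same noise. The
acceptance script reports the measured recovery and coverage rates for
the selected estimator, and the unit suite verifies the geometric-mean
path's recovery. Users fitting data with very large slopes and
multiplicative scatter should prefer EF_Gmean or fit in log space.

## Impactor scheme

The 14-stage cascade-impactor cutoffs (d50) default to the instrument's
nominal cutpoints spanning 0.015–9.91 μm, with an inlet cut of 15 μm
for the top stage. Stages 1–6 are pooled into fraction 1 and stages
7–8 into fraction 2, giving eight fractions. For source-function
integration the outermost fractions extend to 0 and ∞ so the fractions
tile the diameter axis. Aerodynamic diameters are treated as dry
diameters (the sampling line dries the aerosol below 40 % RH); no
shape-factor conversion is applied.

## Source function

Three log-normal mass modes with median dry diameters 0.095, 0.6 and
1.5 μm. The published chamber-derived source function gives geometric
standard deviations 2.10, 1.72 and 1.60, used as defaults.
Mode mass weights are not fixed by the median diameters; the defaults
(0.01, 0.10, 0.89) put the bulk of salt mass in the coarse mode, as a
number-to-mass conversion of chamber size distributions implies. With
these defaults about 27 % of toy-world salt mass sits below 1 μm —
higher than global-model estimates (~2.5 %), because a single fixed
mass-weight triple cannot reproduce a global model's spatially varying
size distribution. All mode parameters are plain configuration.

A mode's EF is the mass-weighted mean of the per-fraction EFs, weights
being the mode's log-normal mass between the fraction bounds. Weights
are renormalised over fractions that have an EF; a missing fraction
carrying more than 1 % of the mode's mass is an error. Scenario values
take the per-fraction mean EF (mean), CI-low (low) or CI-high (high) —
the scenario is built from per-fraction CI bounds, not from a CI of the
aggregated mode EF, so the low/high mode EFs bracket the mean by
construction.

## Gridded world

The grid is global regular latitude × longitude (default 1.9° × 2.5°
for real model output; the toy world uses 24 × 36). Cell areas follow
A = R²·Δλ·(sin φ_top − sin φ_bot), summing exactly to the sphere.

Concentration assignment rules, in order: grid-cell median of located
measurements (values below a study's detection limit are expected
pre-substituted with that study's MDL); provinces with fewer than three
occupied cells are merged into the adjacent province with the most
occupied cells (adjacency = shared cell edge, longitude wrapping at the
dateline), iterating to a fixed point; provinces with ≥ 3 occupied
cells get median/Q1/Q3 scenario triples (linear-interpolation, type-7
quartiles); data-free provinces copy an adjacent noncoastal province
with data (earlier-resolved provinces may serve as sources in later
passes), else the Atlantic province with maximal latitude-band overlap.
All ties (equal overlap, equal counts, equidistant sources) break to
the smaller province id for determinism. An isolated sparse province
with no data-bearing neighbour is kept as-is with a warning rather than
silently dropped.

Cells intersecting land polygons are land cells; cells intersecting
coastline geometry are coast cells; land minus coast is inland. For
deposition concentrations, land cells within two queen-neighbour
dilation steps of a coastal-province cell take that province's
concentrations (nearest source wins, BFS metric); remaining land cells
take the closest noncoastal province by the same metric. Ocean cells
always use their own province.

## Flux estimation

PFAA flux = EF × (0.307 × salt flux) × C / 10.8, per mode, summed over
modes. Constants: Na⁺ is 30.7 % of dry sea-salt mass; mean surface
seawater Na⁺ is 10.8 g/L; the model year is 365 × 86 400 s (no-leap
calendar, configurable); ng → t is 10⁻¹⁵. With salt in kg m⁻² yr⁻¹ and
concentrations in pg/L the PFAA flux is in ng m⁻² yr⁻¹ by unit algebra
alone. Monthly mean fields are annualised with day-count weights and
averaged across years. If only a total salt field is available it is
split across modes by the mass weights.

Deposition uses the same relation with wet/dry salt deposition fields
and the extended concentration raster. Because the concentration is
applied at the deposition location, the origin of deposited salt is
untracked; global deposition can therefore slightly exceed emission,
which is a property of the method, not a numerical defect.

Breakdowns: coastal share integrates emission over cells of coastal
provinces; the submicron share weights each mode's emission total by
that mode's mass below 1 μm; inland/coastline shares integrate total
deposition over the respective masks; the dry share is dry/(wet + dry).
Scenarios pair jointly — low EFs with Q1 concentrations, high with Q3 —
with no cross-combinations, so scenario totals are ordered.

## Synthetic data

The chamber generator draws per-experiment seawater concentrations
log-uniformly over 25–250 pg/L (about the decade spanned by reported
open-ocean transect measurements), produces SSA concentrations from
known true EFs with multiplicative log-normal noise (default GSD 1.5),
small triplicate scatter (GSD 1.05), and censors at configurable MDLs;
19 experiments by default. True EFs are drawn log-uniformly over
10³–10⁶ per homolog × fraction (an optional diameter power law is
available). Truth records accompany every fixture.

The toy world has one rectangular continent, two coastal provinces
ringing it, and open provinces tiled by basin × latitude band; salt
emission follows a smooth mid-latitude-peaking profile scaled to
3.0 × 10¹² kg/yr, and deposition is a neighbour-smoothed copy of
emission rescaled so the world is closed (global deposition = emission
exactly), split 60/40 wet/dry. The default measurement layout plants
rich, sparse and data-free provinces so the merge and fallback rules
all execute.

What the fixtures do not emulate: real bathymetry or province
geometry, spatial covariance of concentrations beyond the province
structure, seasonality, size-dependent atmospheric residence times, or
surf-zone spray production. Passing tests demonstrate the estimators
and bookkeeping are correct under the assumed statistical structure,
not that the toy magnitudes transfer to the real ocean.

## Problem sizes and runtime

Defaults are sized so the full test suite runs in a few minutes on one
core: 24 × 36 toy grids, 19-experiment campaigns, 2000 bootstrap
resamples (vectorised closed-form TLS), 200-replicate recovery studies.
All randomness flows from explicit seeds through
`numpy.random.default_rng`; reruns with the same configuration are
bit-identical.

## Known limitations

* The TLS slope bias under multiplicative noise at large slopes
  (discussed above) is inherited from the estimator definition.
* Province concentrations are piecewise constant; real gradients within
  provinces (especially coastal) are not represented, and coastal
  concentrations taken from open-ocean fallbacks understate coastal
  emission.
* Deposition totals are not mass-consistent with emission by
  construction (untracked origin), so emission–deposition differences
  should be read as spatial patterns, not budgets.
* No Monte-Carlo uncertainty propagation: the three discrete scenarios
  are the only uncertainty treatment.
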