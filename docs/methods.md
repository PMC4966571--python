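# Methods

`smallarea` implements the statistical pipeline of an ecological trend
study of socioeconomic inequalities in all-cause mortality across the
census tracts of many cities, compared between two multi-year periods.
This note documents the models, the synthetic study design, the sampler,
and the numerical and design choices, in enough detail to audit or extend
any of them.

## Study structure and notation

Units are census tracts *i* = 1..n_j nested in cities *j* = 1..J, observed
in two periods *t* ∈ {1, 2}.  For each (tract, sex, 5-year age group,
period) we observe death counts and populations (person-years).  Tract
contiguity within each city is an undirected graph.  Deprivation is a
scalar tract covariate X_ij shared by both periods.  All models, rates and
tables treat the sexes as entirely separate analyses.

## Deprivation index

Five census indicators (% unemployment, % manual workers, % temporary
workers, % low education among adults, % low education among the young)
are standardized to mean 0, SD 1 (population denominator) over the tracts
of **all cities pooled** — pooling is what makes index values comparable
across cities — and projected on the unit-norm first eigenvector of their
correlation matrix.  The sign is fixed so the index correlates positively
with unemployment (higher = more deprived).  We report the first-axis
loadings, the fraction of variance explained and the Pearson correlations
of the index with each raw indicator.  Tertiles (and, for maps, septiles)
are unweighted tract quantiles of the pooled index.

Choices made where the design was open:

* PCA is on the correlation structure (indicators pre-standardized); no
  tract population weighting.
* Quantile cut points use linear ("type 7") interpolation; intervals are
  left-closed, so a value tied with a cut point falls in the **lower**
  group.  This makes group assignment deterministic and independent of
  input order.
* A single index serves both periods (area deprivation changes slowly
  relative to the decade covered).
* The raw index has SD √λ₁ (λ₁ the first eigenvalue), not 1.  The
  regression drivers rescale it to unit SD so relative risks read "per SD
  of deprivation"; the index builder itself returns the raw projection.

## Age standardization

* **Direct** (for comparison tables): ASMR = Σ_a w_a r_a × 10⁵, with w_a
  normalized reference-population age weights and r_a local age-specific
  rates.  Age groups with zero local population contribute zero and are
  logged.
* **Indirect** (for model offsets): E = Σ_a rate_ref(a) × pop(a), in two
  modes.  `city_period1` derives reference rates from the city's own
  period-1 aggregate, which conserves the city's period-1 totals exactly
  (observed = expected, the smoothed-SMR convention); `national` uses a
  supplied schedule, making risks comparable across cities and periods
  (the regression convention).

Rounding for printed tables (rates/differences to integers, ratios to two
decimals, percentages to integers, ties half-up/away-from-zero) is applied
only when writing display tables; all internal arithmetic is full
precision.

## The three hierarchical models

All share the Poisson likelihood O ~ Poisson(E·θ) and the BYM latent
structure: an intrinsic-CAR (ICAR) spatial field S per city-period with
conditional scale σ_S, and iid Normal heterogeneity H with scale σ_H.

1. **Disease mapping** — log θ_ijt = b_1jt + S_ijt + H_ijt, fitted
   independently per (city, period) with a flat prior on the intercept.
   The smoothed SMR is E[exp(b_1jt + S_ijt + H_ijt)]·100.
2. **Ecological regression** — log θ_ijt = b_1j + b_2j·X_ij + b_3j·T_2t +
   b_4j·X_ij·T_2t + S_ijt + H_ijt with flat priors on the four per-city
   coefficients (T_2t is 0/1 for period 1/2).  exp(b_2j) is the
   first-period RR per unit deprivation; exp(b_2j + b_4j) the
   second-period RR; Pr(b_4j > 0) the probability the association grew,
   categorized into the bins [0, .025), [.025, .05), [.05, .95),
   [.95, .975), [.975, 1] (first/fifth bin = significant decrease /
   increase).
3. **Random coefficients** — as 2 but b_kj ~ Normal(β_k, σ_bk²) with flat
   priors on β_k, yielding global RRs exp(β₂) and exp(β₂ + β₄) and the
   global trend probability Pr(β₄ > 0).  It needs ≥ 3 cities; below that
   the between-city variances are unidentifiable.

Every SD (σ_S, σ_H, σ_bk) carries a Uniform(0, 10) prior, interpreted on
the **conditional** (pairwise-difference) ICAR scale — the convention of
the classic disease-mapping software this model family comes from.  Flat
priors are implemented as genuinely improper flats; the posteriors are
proper through the likelihood.  Point estimates are posterior means;
intervals are equal-tailed 2.5/97.5 posterior percentiles.

### Identifiability conventions

Only S + H (plus intercept) is likelihood-identified.  S is constrained to
sum to zero per connected component of the city graph; isolated tracts get
S = 0 with a warning (H absorbs their variability); the free intercept
fixes the level.  Smoothed SMRs always use the full sum, never S or H
alone.

### Sampler

No external MCMC backend is used; the sampler is a Metropolis-within-Gibbs
scheme written for exactly this model family (see `smallarea.mcmc`):

* the log-risk surface u = log θ updates by vectorised elementwise
  random-walk Metropolis (its full conditional factorises across strata);
* coefficients b, the spatial field S (a constrained Gaussian Markov
  random field with precision L/σ_S² + I/σ_H²), the hyper-means β and all
  SDs are exact conjugate Gibbs draws (truncated-Gamma precisions under
  the uniform-SD priors);
* three families of joint "interweaving" moves — translating (b_k, u)
  along a design column, and rescaling (S, σ_S) or (H, σ_H) or the
  coefficient deviations (b_k − β_k, σ_bk) jointly — remove the slow
  funnel-shaped coupling between fields and their scales that plain
  one-at-a-time updates suffer from when a variance is near zero.

Proposal scales adapt toward standard acceptance targets (0.44 scalar,
0.30 for scale moves) during burn-in only, so retained draws come from a
fixed Markov kernel.  Defaults: 3 chains, 5 000 burn-in + 5 000 retained
draws per chain, thinning 1; one master seed spawns independent chain
seeds.  Convergence is gated on split R-hat < 1.1 and effective sample
size > 100 (via ArviZ) for every monitored coefficient, hyperparameter and
SD; a failing fit is returned with `converged=False` and the offending
parameters listed, never silently accepted.

### Numerical details

* SD draws are floored at 10⁻³ (far below any scale of scientific
  interest here) to keep precision matrices well-conditioned.
* Truncated-Gamma precisions are drawn by rejection with an inverse-CDF
  fallback.
* The latent surface is initialised at log((O + ½)/E) plus jitter; chains
  start from over-dispersed points.
* Per-iteration dense Cholesky factorizations of the n×n spatial
  precision are exact (no sparse approximation); cities of a few hundred
  tracts are well within this budget.

## Synthetic studies

The generator emulates the data structure the models assume, with known
ground truth:

* geometry: each city is a rook-contiguity rectangular lattice (the most
  nearly square factorization of the requested tract count) — real tract
  polygons carry no information the models use beyond contiguity;
* deprivation: a latent standard-normal score x per tract; the five
  indicators are x plus independent N(0, 0.3²) noise, mapped to
  percentage scales and clipped to [0, 100] — equal population loadings,
  so the PCA stage should recover near-equal weights and a dominant first
  axis;
* coefficients: b_kj ~ Normal(β_k, σ_bk²) per city; fields: exact ICAR
  draws (eigenbasis of the graph Laplacian, covariance σ² L⁺, exactly
  zero-sum) and iid Normal heterogeneity, per city-period;
* populations: person-years per (tract, age) = base_population × a
  geometric age profile (ratio 0.93 per 5-year group, mean 1) × a
  log-normal tract-size multiplier (SD 0.2), rounded to integers;
* rates: Gompertz-like reference schedules rising 1.5× per age group,
  calibrated to crude rates around 1 100 (men) / 650 (women) per 100 000
  person-years — the range of adult urban all-cause mortality; deaths are
  Poisson with mean pop × ref_rate × θ, both sexes sharing one risk
  surface θ.

Default study conditions (chosen once as the package's standard
validation scenario): 8 cities × 100 tracts, β = (0, 0.12, −0.15, −0.02)
— a first-period RR of exp(0.12) ≈ 1.13 per SD of deprivation weakening
by exp(−0.02), with declining overall mortality — σ_b = (0.05, 0.03,
0.03, 0.01), σ_S = 0.2, σ_H = 0.05, base_population = 250 person-years
per tract-age stratum (≈ a 1 500-person tract over a 3-year period).
These magnitudes match the between-city spread and sSMR ranges typical of
published multi-city urban analyses while keeping an 8-city recovery
study informative.

What the generator does **not** emulate: real Spanish demography or city
footprints, migration, geocoding failures, spatially *clustered*
deprivation (x is iid across tracts, so deprivation–spatial-field
confounding is milder than in real cities), or population change between
periods.  Passing recovery tests therefore validate the estimators under
the models' own assumptions — they do not certify behaviour under model
misspecification.

## Validation surfaces

* Printed-table arithmetic is checked against published city rows whose
  derived cells are arithmetically self-consistent at the stated rounding
  (some published cells are off by one because they were computed from
  unrounded rates; those cells are excluded rather than reverse-engineered).
* Disease-mapping calibration: on a null study (θ ≡ 1, one 100-tract
  city) ≥ 90 % of tract sSMR 95 % intervals must cover 100.
* Recovery: on the default 8-city study the hierarchical model must
  recover exp(β₂) within ±0.03 and report Pr(β₄ > 0) < 0.5, with the
  convergence gate satisfied on all hyperparameters.  Recovery fits use
  the generator's unit-variance ground-truth deprivation score as the
  covariate so the coefficient scale matches the generating scale; the
  PCA index is validated separately (loading recovery, dominant first
  axis).

A repeated-replication coverage experiment (e.g. 20 independent studies)
would strengthen the recovery evidence but is outside the default test
budget; single-study recovery at full scale is the tested surface.

## Known limitations

* The ICAR scale interpretation (conditional vs marginal) is a
  convention; results are comparable only under the same convention.
* Fits require strictly positive expected counts per tract-period; merge
  or drop zero-population tracts upstream.
* The sampler is exact but not gradient-based; for very large cities
  (thousands of tracts) per-iteration Cholesky costs grow as n³ and a
  sparse solver would be the next step.
* Septile maps are emitted as tables only; joining to real geometries is
  left to the caller.
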