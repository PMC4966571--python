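# smallarea

Bayesian analysis of socioeconomic inequalities in all-cause mortality
across the census tracts of many cities, compared between two periods.
Built for epidemiologists and public-health analysts who work with
small-area mortality registries: it takes stratified death counts and
populations, tract contiguity, and five census deprivation indicators,
and produces the full analytical surface of a multi-city inequality
trend study.

## What it computes

* **Deprivation index** — the five indicators (% unemployment, % manual
  workers, % temporary workers, % low education, % low education among
  the young) are standardized over all cities' tracts pooled and combined
  with the first principal component's loadings; tertiles/septiles of the
  index stratify every later step.
* **Age-standardized rates** — direct ASMRs per (city, sex, period) for
  the extreme deprivation tertiles, with T3/T1 ratios, differences and
  cross-period percentage reductions; indirect standardization produces
  the expected counts E used as model offsets.
* **Three hierarchical spatial models**, sharing the BYM (Besag–York–
  Mollié) latent structure S + H (intrinsic-CAR spatial field, sum-to-zero
  per city-period, plus iid heterogeneity) over a Poisson likelihood
  O ~ Poisson(E·θ):

  1. *Disease mapping*: log θ = b₁ + S + H per (city, period); smoothed
     SMR = E[exp(b₁+S+H)]·100, mapped as septiles.
  2. *Ecological regression*: log θ = b₁ⱼ + b₂ⱼX + b₃ⱼT₂ + b₄ⱼX·T₂ + S + H
     per city; RR per unit deprivation is exp(b₂ⱼ) in period 1 and
     exp(b₂ⱼ+b₄ⱼ) in period 2; Pr(b₄ⱼ>0) classifies the trend into five
     probability bins.
  3. *Random coefficients*: b_kj ~ Normal(β_k, σ²_bk) pools the cities
     and yields global RRs exp(β₂), exp(β₂+β₄) and Pr(β₄>0) — a one-step
     meta-analysis of the city associations.

Models are fitted by a purpose-built Metropolis-within-Gibbs sampler
(conjugate Gibbs for fields, coefficients and variances; vectorised
Metropolis for the log-risk surface; interweaving scale moves against the
variance funnel), with convergence gated on split R-hat < 1.1 and
effective sample size > 100 for every monitored parameter.  A synthetic
multi-city generator with known ground truth (lattice cities, one-factor
indicators, exact ICAR fields, Poisson deaths) backs all validation.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the
default synthetic study (8 cities × 100 tracts, both sexes, deprivation
RR exp(0.12) ≈ 1.13 weakening to exp(0.10) ≈ 1.11):

```bash
python analysis/01_simulate.py
python analysis/02_deprivation_index.py
python analysis/03_tertile_tables.py
python analysis/04_smooth_ssmr.py
python analysis/05_city_regressions.py
python analysis/06_pooled_trend.py
```

`02` prints the index diagnostics — near-equal loadings, as built into
the generator:

```
first-axis loadings: [0.447, 0.448, 0.447, 0.448, 0.446]
variance explained: 92.7%
```

`03` prints the tertile comparison (men, rates per 100 000; excerpt):

```
  city  asmr_t1_p1  asmr_t3_p1  ratio_p1  asmr_t1_p2  asmr_t3_p2  ratio_p2
city01        1108        1318      1.19        1020        1133      1.11
city02         989        1356      1.37         884        1118      1.26
```

— most-deprived tracts die faster in every city, and the gap narrows in
period 2.  `06` prints the pooled trend:

```
global RR period 1: 1.100 (95% CI 1.063-1.140); generating value 1.127
global RR period 2: 1.081 (95% CI 1.040-1.125); generating value 1.105
Pr(global RR increased): 0.078 -> [0.050, 0.950)
```

— the multilevel model recovers both generating global RRs inside their
credible intervals and correctly reports a probable (but at this scale
not significant) decline in inequality.

Per-city tables, septile map tables and forest-plot data land under
`results/`.  A `smallarea` CLI (`simulate` / `index` / `standardize` /
`fit` / `report`) exposes the same steps for file-based workflows.

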