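# Methods

## Scope and structure

The package estimates the economic burden attributable to childhood
violence in three strands: (i) nonfatal attributable DALYs via
population attributable fractions, (ii) fatal DALYs via homicide counts
and a standard life table, and (iii) productivity losses via
selection-corrected wage effects. A synthetic cohort generator with
fully known parameters backs the statistical estimators, so each stage
is testable by parameter recovery rather than against unavailable
survey microdata.

## Attributable fractions

Levin's formula PAF = p(RR−1)/(1+p(RR−1)) is used for a binary
exposure; it equals the counterfactual incidence contrast
(I − I₀)/I for any baseline risk, which the tests verify directly.
Sex-stratified cells use sex-specific prevalence; "total" cells use
total prevalence. A relative risk below 1 produces a negative
(protective) fraction and a logged warning rather than an error.
Cells with no pooled RR are absent from the output, never zero-filled,
so downstream totals only reflect evidence that exists.

Odds ratios are brought to the RR scale with the Zhang–Yu conversion
RR = OR/((1−P₀)+P₀·OR). P₀ (unexposed outcome risk) must be supplied
per study; a rare-outcome mode (P₀ = 0, RR ≡ OR) exists and is flagged
in the output. Externally derived adjusted/unadjusted OR ratios can be
applied multiplicatively before conversion; no default ratios are
bundled. Pooling uses sample-size weights on the log-RR scale —
the weighted geometric mean — chosen so reciprocal effects pool
symmetrically; a linear-scale mode is available and every pooled row
records which scale produced it.

## Baseline DALYs and double counting

Baseline DALY totals per outcome (age-15+, GBD-2015-style categories)
are a user-supplied table. The bundled
`baseline_dalys_synthetic.csv` is a **validation fixture**: each value
is a published burden cell divided by the corresponding full-precision
PAF, so that the multiplication and aggregation paths reproduce the
published table end-to-end. Where a cell had only sex-specific
relative risks and no total, the fixture splits the cell equally
between the sex strata (the true split is unknowable from the published
material; the fixture validates arithmetic, not epidemiology). Strata
that the published table folds into a "total" PAF carry a zero
baseline so the attribution contract — every PAF cell must find a
baseline — still holds. A handful of fixture values sit a fraction of
a DALY below the printed integers; these offsets are forced by the
published economic values and exposure totals, whose rounding implies
the unrounded cells were just under the printed figures.

Two double-counting mechanisms are implemented. First, an explicit
cause-exclusion map subtracts named cause-category contributions from a
risk factor's baseline before multiplication (the standard example:
self-harm and HIV/AIDS removed from the drug-use envelope when
attributed separately); negative post-exclusion baselines clip to zero
with a warning, and the map is validated acyclic. Second, at
aggregation an *envelope rule* drops sub-category cells from an
exposure's total when the enclosing envelope outcome is also attributed
for that exposure — by default anxiety and depression under serious
mental illness (the mental-disorders envelope). This rule is what the
published exposure totals follow: where a serious-mental-illness cell
exists, the anxiety cell is printed but not summed. Both mechanisms
are configuration, not hard-coded behaviour.

## Fatal burden

Fatal DALYs are Σ deaths × YLL(a) over age bands, with the
representative age a = floor((low+high)/2) — matching the published
ages 2, 7, 12, 16 for bands 0–4, 5–9, 10–14, 15–17 — and YLL read from
bundled life-table anchors (90.01, 85.02, 80.03, 76.04 years) by
piecewise-linear interpolation, exact at anchors and erroring outside
the table range. Full precision is kept until reporting.

## Monetisation and the earnings chain

One DALY is valued at per-capita GDP. The bundled value,
ZAR 73,061.20, is implied by the published burden table (total value ÷
total DALYs); the fatal-burden section implies a slightly different
value (≈ 73,557), recorded in the fixture comments — the table-implied
value is the default because it underlies 27 of the 28 published
monetary figures. `gdp_total` (ZAR 4.0 × 10¹²) is back-computed from
the published earnings-loss share (25.2 bn = 0.63% of GDP) and only
feeds share-of-GDP reporting. The CPI ratio is likewise the implied
3262/3120. The ZAR/USD rate in the fixture is indicative only.

The productivity-loss chain multiplies labour force × prevalence ×
CPI-adjusted median earnings × proportional reduction × 12 with **no
intermediate rounding**: rounding the victim count and per-victim loss
first misses the published monthly total by about ZAR 1.9 million, and
a regression test pins the unrounded behaviour. Victim counts are
displayed with half-up rounding (the convention the published figures
follow for ×.5 counts).

## Cohort estimators

Relative risks for binary outcomes come from a log-link binomial GLM,
whose exposure coefficient is a log-RR directly. Log-binomial
likelihoods are notoriously fragile near the risk boundary; on
non-convergence the estimator refits a log-link Poisson model with HC1
robust variance (the modified-Poisson workaround) and records the
method used. A stratum with zero events raises an instructive error
rather than silently producing an infinite estimate.

Wage effects use the two-stage (not full-information ML) Heckman
correction: probit participation by maximum likelihood, then OLS of
log wage on exposure, confounders and the inverse Mills ratio
φ(z)/Φ(z) evaluated at the probit linear predictor, over participants.
The Mills ratio is computed on the log scale so it is stable deep in
the left tail. The reported effect is 1 − e^β (log-wage is the
standard earnings-equation convention; the source material reports only
percentage reductions). Standard errors come from a seeded
nonparametric bootstrap over individuals (default 200 replicates);
ρ̂ is recovered from the Mills coefficient via the usual variance
decomposition and clipped to [−1, 1]. The caller designates the
exclusion restriction; if every selection covariate also enters the
wage equation a warning notes that identification rests on the Mills
nonlinearity alone. Survey-design variance (clustering,
stratification) is out of scope; estimates are i.i.d.-bootstrap based.

## The synthetic cohort

The generator emulates a single cross-section of a youth panel:
independent Bernoulli exposures at stated prevalences; bernoulli,
categorical or standard-normal confounders; binary outcomes under a
log-risk model (so generating coefficients are log-RRs, the scale the
PAF machinery consumes — a logistic model would not recover them);
log-normal wages with multiplicative per-exposure reductions; and a
probit participation equation whose latent error is bivariate-normal
with the wage error at correlation ρ. Latent draws can be returned for
tests that instrument the selection structure directly.

Validation rejects any specification whose implied risk can exceed 1 —
a priori for bounded covariates, and on the realised draws for normal
covariates — naming the offending outcome, rather than silently
truncating (truncation would bias recovery tests). The bundled default
specification uses n = 50,000, prevalences 0.261/0.126 for
physical/emotional violence, outcome RRs of 1.55/1.35 (alcohol abuse)
and 1.57/1.86 (anxiety), wage reductions 0.117/0.092, ρ = 0.5, a
baseline outcome risk of 8–10%, and an employment rate near 57% — the
magnitudes of the published effect landscape. n = 50,000 keeps the
3-SE recovery bands a few percent wide while the whole suite runs in
well under a minute.

What the generator does **not** emulate: poly-victimisation
(exposures are independent across types), panel attrition and wave
structure, cluster/stratum survey design, and measurement error in
self-reports. Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to those features
of real survey data.

## Numerical and reporting conventions

All arithmetic is double precision with rounding only at report time:
DALYs to integers, burden values in millions of Rand, earnings in Rand
and billions (the published mixed convention). The pipeline run is
deterministic given configuration and seed. Witnessing-family-violence
rows ship in the effects table (their PAFs are computable) but the
default inclusion list excludes them from burden totals, as too few
consequence studies support them; exploitation is absent entirely. The
report prints the exact fatal+nonfatal sum (ZAR 172.6 bn); headline
summaries elsewhere round this to ZAR 173 bn.

## Known limitations

- PAFs assume the pooled RRs are causal and transportable to the
  national population; confounding in the underlying studies
  propagates directly.
- The additive exposure-specific totals ignore overlap between
  violence types (poly-victimisation), likely overstating the sum.
- Baseline DALY inputs are static totals; no age- or time-resolved
  attribution, no discounting or age-weighting, and no uncertainty
  intervals (the published figures carry none).
- The earnings loss is a single-year snapshot, not a discounted
  lifetime projection.
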