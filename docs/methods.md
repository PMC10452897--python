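# Methods

## Scoring model

The polygenic risk score of sample *j* is the linear allele count
`PRS_j = Σ_i a_ij β_i` over a weight set's variants, where `a_ij ∈
{0,1,2}` counts the effect allele and `β_i` is the published per-allele
log-odds effect. No clumping, pruning or p-value thresholding is
applied: published breast-cancer weight sets (at the 77–3820 SNP
scales) are already curated, and the score is meant to reproduce them
as specified. Scores are standardized by subtracting the cohort mean
and dividing by the cohort standard deviation, cases and controls
pooled; "standardized" is read as plain z-scoring, not a rank-based
inverse-normal transform. The SD uses the population (divide-by-N)
convention, pinned by tests. Missing dosages are imputed with the
variant's cohort-mean dosage before summation, which leaves the cohort
mean score equal to the observed-dosage score and adds no variance of
its own.

Harmonization matches variants by identifier (rsID), not by
chromosome:position — published weight sets distribute rsIDs, and
positional matching would additionally require build reconciliation,
which is out of scope. Orientation is resolved from the genotype file's
declared allele pair: identical pair → match, swapped pair → dosage
`2−a` (counted as a flip), any other pair → drop. Palindromic (A/T,
C/G) variants are dropped unconditionally rather than rescued by
frequency comparison; that is deterministic and conservative, and the
harmonization report makes the loss visible. QC runs in a fixed order —
variant missingness, then minor allele frequency, then sample
missingness, 2% thresholds each by default — so each filter sees the
survivors of the previous one.

## Discrimination

AUC is computed in its Mann–Whitney form, P(z_case > z_control) + ½
P(tie); tie handling is half-credit, made explicit because whole-unit
dosage sums can produce tied scores on small weight sets. The odds
ratio per SD comes from a logistic regression of status on the
standardized score alone (no covariates), fitted by Newton/IRLS with
convergence at |Δβ| < 1e−8 within 100 iterations; the SE is from the
observed information, and complete separation is detected and raised
rather than returning a diverged coefficient. Confidence intervals are
Wald on the log scale.

## Left-truncated Cox model

The time scale is age: a subject enters the risk set at enrolment age
and leaves at diagnosis (cases) or last follow-up (controls). The risk
set at event age *t* is `{i : entry_i < t ≤ exit_i}`, and the log
partial likelihood is maximized by a scalar Newton iteration
(convergence |Δ log L| < 1e−9), with Efron's correction for tied event
ages — ages recorded in whole years make ties common — and Breslow
available behind a flag. The score is centered internally for numerical
stability, which leaves the estimate unchanged. The SE is the inverse
square root of the observed information. Only the single PRS covariate
is supported; that is the model under study, and it keeps the Newton
step exact. The implementation is checked against lifelines to 1e−6 in
both the coefficient and its SE, with and without truncation and under
heavy ties.

Harrell's C counts a pair (i, j) as comparable when i has an event at
t_i and j is at risk then (entry_j < t_i ≤ exit_j), concordant when the
event carries the higher score, with half-credit for score ties. Its SE
is a Noether-type linearization treating each event's comparable-pair
set as one cluster of the underlying U-statistic.

## Absolute risk

The absolute risk of onset in (a, a+τ], in the presence of competing
mortality m(t), is

    R(a, a+τ) = ∫_a^{a+τ} λ₀(t) e^{bz} exp(−∫_a^t (λ₀(u) e^{bz} + m(u)) du) dt.

All rates are piecewise constant on a 1-year grid (registry tables are
step functions), and the integral is evaluated exactly within each
year: the year at age t contributes `S · [λ/(λ+m)] · (1 − e^{−(λ+m)})`
with `λ = λ₀(t) e^{bz}`, where S is the accumulated all-cause survival
factor. This makes results grid-exact rather than quadrature
approximations; an implementation using a different internal grid could
differ in the third decimal.

**Baseline calibration.** λ₀(t) is chosen so that the model's
population-average incidence reproduces the registry's marginal rate
λm(t). The referent score distribution (standard normal, since the
cohort score is z-standardized) is represented by 1001 equally weighted
quantile points z_k; each carries a disease-free survival weight w_k
that starts at 1 and is depleted by that year's disease hazard
λ₀(t)e^{bz_k}. All-cause mortality multiplies every w_k equally and
cancels in the ratio, so it is omitted. Ages are processed forward
once, setting λ₀(t) = λm(t)·Σw_k / Σw_k e^{bz_k}; no outer iteration is
needed because each year's depletion only uses already-calibrated
earlier years. This susceptible-depletion scheme (rather than the naive
constant λ₀ = λm/E[e^{bZ}] = λm e^{−b²/2}, kept behind a flag for
sensitivity checks) matters at later ages, where the disease-free
population's score distribution has drifted down and the naive version
under-corrects. At b = 0 the calibration is the identity by
construction, and a simulation test confirms that drawing a large
population from the calibrated model recovers λm in every decade.

Percentile risk curves evaluate R at z = Φ⁻¹(p) for nominal percentiles
p — the referent is the standard normal the scores were standardized to
— rather than at empirical cohort quantiles; lifetime curves run from
age 20 (incidence below the mid-20s is negligible) to 80, both
configurable. The per-SD log hazard ratio b is taken from the Cox fit.

## Synthetic data

The generators emulate a genotyped female case/control cohort with
follow-up:

* **Genotypes.** Per-variant MAF ~ Uniform(0.01, 0.49); dosages are two
  independent allele draws (Hardy–Weinberg), with optional planted
  missingness, rare variants and high-missingness samples for QC tests.
  No linkage disequilibrium, population stratification or genotyping
  error is modelled — passing tests therefore say nothing about
  LD-induced score miscalibration in real data.
* **Weights.** Betas ~ N(0, 0.1), non-palindromic allele pairs by
  default; the raw score variance then follows the Hardy–Weinberg
  algebra Σ 2p(1−p)β².
* **Rates.** Incidence is zero before 25 and rises along a smooth
  logistic toward a plateau of 3.3×10⁻³ per person-year (midpoint 50,
  scale 8) — the shape of Nordic female breast-cancer registry curves,
  yielding a cumulative hazard of ≈0.097 over ages 20–80; mortality is
  Gompertz, m(t) = 2×10⁻⁵·e^{0.095t}. Published on 5-year bins to
  mimic registry format. The stand-in plateau runs somewhat below the
  real Norwegian registry peak, so absolute risk *levels* computed from
  it land slightly under values derived from the real tables, while
  risk *ratios* between percentiles are insensitive to the level.
* **Cohorts.** Onset ages are drawn by inverse-CDF sampling from the
  piecewise-constant hazard λ₀(t)e^{bz} (default b = ln 1.494); death
  from m(t); enrolment age ~ N(40, 10) truncated at 20 and
  administrative censoring ~ N(78, 8), capped at age 90. Subjects whose
  outcome precedes enrolment are discarded — left truncation realized
  by rejection, the way a prevalent cohort arises; a
  condition-on-survival sampler is deliberately not provided. Defaults
  give roughly 7% cases in the retained cohort. A `case_control_target`
  option subsamples to a fixed case:control split (e.g. the 1:7
  imbalance of a case-enriched study), but it is off by default:
  subsampling controls selects on the outcome and visibly attenuates
  the hazard ratio, so parameter-recovery checks run on the unenriched
  cohort. The cohort PRS can come either from simulated
  genotypes × weights or directly as N(0,1) draws; both paths are
  tested.

## Problem sizes and numerical choices

Parameter-recovery checks use 100 cohorts of 8000 subjects (~550 events
each), chosen to give the 95% CI coverage test adequate resolution;
calibration-in-the-small and decile-stratification checks use 60–80
thousand simulated subjects, at which binomial noise per decile is a
few percent. Closed-form oracles (binormal AUC Φ(Δμ/√2), logistic slope
= mean shift under equal-variance Gaussians, constant-hazard risk
[λ/(λ+m)](1−e^{−(λ+m)τ})) are asserted at Monte-Carlo or exact
tolerance; brute-force oracles (all-pairs AUC, O(n²) concordance
enumeration, grid-search Cox on a three-subject toy) are asserted to
1e−5 or better. Degenerate inputs raise rather than return: single-class
AUC, complete logistic separation, constant scores, fewer than two
events, empty post-QC matrices, risks requested outside the calibrated
age span.

## Known limitations

Matching by rsID cannot rescue variants published under positional
ids; fractional imputation dosages are not supported (hard calls only);
the Cox model is univariable by design, with no clinical covariates or
time-varying effects; competing mortality enters only the absolute-risk
stage, not the Cox fit; and the synthetic incidence curve is a shape
stand-in, not a transcription of registry tables, so absolute risk
levels derived from it should not be quoted as population estimates.
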