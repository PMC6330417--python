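# Methods

## Model

Disability (a binary indicator; in the survey context the GALI item,
"limited" or "severely limited") is modelled with a binomial additive
hazard: Y_i ~ Bernoulli(pi_i), pi_i = 1 − exp(−eta_i), with linear
predictor

    eta_i = alpha_{a,e} + sum_d gamma_{c} * delta_{d,e} * X_{d,i}.

* `alpha_{a,e}` ≥ 0 — background cumulative disability rate, one per
  background age band a (25–39, 40–49, 50–59, 60–69, 70–79, 80+) and
  education level e (low / middle / high, ISCED 0–1 / 2–4 / 5–8). It
  captures disability occurring without any of the listed diseases
  (unreported or unlisted conditions, ageing, other causes).
* `gamma_c` ≥ 0 — one age pattern shared by all diseases, on coarser
  rank bands (25–39, 40–54, 55–69, 70+), with gamma = 1 in the
  youngest band. This is the rank-one reduction of the full
  age × disease × education interaction: beta_{c,d,e} = gamma_c *
  delta_{d,e}. Without the gamma_1 = 1 normalization (gamma, delta)
  would only be identified up to a common scale.
* `delta_{d,e}` ≥ 0 — disabling impact of disease d in education group
  e at the reference (youngest) rank band, on the cumulative-rate
  scale. The "disabling impact" reported in output tables is the
  age-standardized mean of beta over the standard population's age
  structure, i.e. (Σ_c w_c gamma_c) · delta_{d,e}; with a flat age
  pattern it equals delta itself.

Age bands are half-open integer-age intervals: "25–39" is [25, 40).
The model is fitted separately for men and women.

Assumptions: diseases and background act as independent additive
competing causes; reported (current) diseases explain the distribution
of disability; cause-specific cumulative rates are proportional over
the pre-survey period; a common start of time at risk. Under these,
pi decomposes exactly as pi · (term / eta) over the hazard terms, which
is the attribution rule used throughout (all shares zero when eta = 0).

## Estimation

Weighted maximum likelihood under box constraints at zero. Survey
weights enter as frequency-style multipliers (pseudo-likelihood),
normalized to mean one within the fitted subset; `use_weights=False`
gives the unweighted fit. log(1 − pi) = −eta is used exactly; pi is
floored at 1e−12 so a disabled respondent with eta = 0 yields a finite
(heavily penalized) likelihood rather than −inf.

The optimizer alternates two box-constrained L-BFGS-B blocks with
analytic gradients — (alpha, delta) given gamma, then gamma given
(alpha, delta) — and finishes with one joint L-BFGS-B polish over all
parameters, which removes the slow zigzag the bilinear gamma·delta
coupling causes near the optimum. Monotone ascent is asserted after
every block and the polish. Convergence: relative log-likelihood
change below `tol` (default 1e−9). Multi-start (default 2) jitters the
deterministic initialization (alpha from disability rates among the
disease-free per cell; delta from crude marginal attributable rates;
gamma flat) and keeps the best likelihood; starts are reproducible from
`seed`. When `init_params` is supplied (e.g. warm-starting bootstrap
replicate fits at the original-data optimum) the joint polish runs
directly. Diseases absent from an education stratum have delta pinned
at zero and are boundary-flagged; non-convergence is flagged on the
result, never raised.

## Attribution and standardization

Population contributions are survey-weighted means of individual
shares; the quantity partitioned is the weighted mean of the
*model-predicted* pi, which makes additivity (background + Σ
contributions = prevalence) exact by construction. The weighted mean of
observed Y is reported alongside as a fit diagnostic; contributions are
not rescaled to it.

Direct age standardization averages band-specific values with
standard-population weights (normalized per sex). Being linear, it
preserves additivity exactly. Gamma lives on rank bands while standard
populations are tabulated on background bands; band mass is spread
uniformly over ages within a band (open-ended bands get a nominal
20-year width) when re-aggregating onto rank bands. With the default
groupings only the 50–59 band straddles a rank boundary (split 50/50).

Proportion CIs use a normal approximation with the Kish effective
sample size (Σw)²/Σw²; odds ratios are crude (unadjusted) weighted
ratios with Woolf-type log-scale CIs on Kish-scaled cells, and a zero
cell is an error (no continuity correction).

## Counterfactual scenarios

Both scenarios transfer a property of the donor education group (high)
to the recipient (low); background alpha is never swapped, though the
background *contribution* changes through the proportional-share rule.

* `swap_impact`: the recipient's observed records are re-attributed
  with the donor's delta column (alpha, gamma unchanged), then
  age-standardized. A donor identical to the recipient reproduces the
  baseline exactly.
* `swap_prevalence`: the donor's *age-specific* weighted disease
  prevalences (not a single standardized figure, which can mask
  opposite age-specific differences) feed an exact expectation under
  independence: per background band, all 2^m disease-state vectors are
  enumerated (8192 for m = 13), each with probability Π p^x (1−p)^(1−x),
  attribution computed per state and averaged, then standardized. For
  m > 15 a seeded Monte-Carlo fallback is used and flagged in the
  result. Independence matches the generator and the model's
  competing-causes assumption; in real data with residual multimorbidity
  correlation the identity-swap check holds only approximately.

The gap decomposition reports baseline gap (low − high standardized
prevalence) and the gap remaining under each scenario; the two
remaining gaps need not sum to the baseline gap.

## Bootstrap

Records are resampled iid with replacement, weights carried; the full
fit + attribution statistic is recomputed per replicate (warm-started
at the original optimum). Default 1000 replicates; the default interval
is normal-type (point ± 1.96 bootstrap SD), which — unlike percentile
intervals — can extend below zero for boundary-constrained parameters,
a realistic feature for small impacts. Replicates whose statistic
raises are dropped and counted; results with >10% failures are flagged.

## Synthetic cohorts

The generator emulates a national cross-sectional disability survey:
six age bands from 25 with a realistic age mix, three education strata
(30/45/25), sex-specific, education-graded disease prevalence tables,
gamma-distributed sampling weights with mean 1 and coefficient of
variation 0.5, and disability drawn from the additive hazard model at
known parameters. Diseases are independent given age × sex × education
by default; `disease_correlation` adds a shared Gaussian latent factor
to probe multimorbidity clustering. The `default_truth()` fixture uses
realistic magnitudes (musculoskeletal conditions common, more prevalent
and more disabling among the low-educated; dementia and sensory
impairment rare; background rising with age, falling with education;
mild reverse gradients for cancer and accidents in line with survey
patterns) — they are fixture choices for testing, not estimates from
any survey. What the generator does *not* emulate: multi-stage survey
design, household clustering, non-response, reporting bias, or
education-dependent diagnosis; passing tests therefore validate the
estimation and decomposition machinery, not robustness to those
real-data features.

## Numerical choices and test scales

* pi floor 1e−12; boundary flags below 1e−6; additivity asserted to
  1e−10 on computed results (a loose tolerance is available when
  assembling results from externally rounded figures).
* Block sweeps stop at relative change 1e−6 before the joint polish at
  `tol`; monotonicity violations raise rather than pass silently.
* Test problem sizes are chosen per purpose: parameter-recovery runs
  use cohorts of 100k–200k; counterfactual-validity checks 100k with a
  1.5-percentage-point tolerance covering sampling plus estimation
  noise; bootstrap calibration uses 200 cohorts × 200 replicates of
  n = 5000 on a two-disease, single-education design so the refits stay
  cheap, with coverage judged against a 90–99% band.

## Known limitations

* Sampling-noise floor: for diseases with ~1% prevalence, delta is
  estimable only to ±0.04–0.05 (1 SE) even at n = 200,000; constrained
  non-negativity then piles replicate estimates at zero and biases the
  old-age background rates slightly downward in null data.
* Pseudo-likelihood weighting ignores the survey design beyond the
  weights themselves; variances come from the bootstrap, not
  design-based estimators.
* The counterfactual expectation assumes independent diseases given the
  stratum; no Shapley-type or mediation-formal decomposition is
  offered.
* No analytic standard errors and no reduced-rank variants beyond
  rank one.
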