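# Methods

This note documents the models, the synthetic-cohort generator and its
calibration, the numerical choices, and what the tests do and do not
establish about real data.

## Scoring

The weight of advice s = (E2 − E1)/(X − E1) is computed as an exact
rational (`fractions.Fraction`) over integer estimates, so s = 0, s = 1
and the interval bounds are decided without floating-point ties and the
reconstruction identity E2 = (1 − s)E1 + sX holds exactly.  Labels:
stay (s = 0), copy (s = 1), compromise (0 < s < 1), invalid_negative
(s < 0), invalid_overshoot (s > 1), undefined_zero_distance (X = E1; the
calibrated task never produces it, but arbitrary input data can).
Undefined rounds count toward the exclusion tally exactly like the two
invalid categories: a participant with three or more such rounds (out of
five) is excluded and logged.  Mean s and P(s < 0.5) summarize only valid
rounds (invalid rounds are dropped, not imputed); the first-estimate
accuracy ratio E1/true uses all five rounds, since validity is a property
of E2 only.

## Task engine

True counts are fixed at (43, 58, 34, 44, 39).  The peer estimate is
X = round(E1·(1 + δ)) with |δ| ~ U(0.15, 0.25) and the sign taken from a
balanced per-round schedule (+,−,+,−,+ by default).  A multiplicative
band keeps the *relative* scope for adjustment constant across E1
magnitudes, which is what neutralizes distance-weighting (discounting of
advice far from one's own estimate).  The exact calibration used in the
original task software is not published; the symmetric ±[15%, 25%] band
is this package's design choice implementing the stated intent.  A
minimum gap |X − E1| ≥ 2 guarantees an integer strictly between E1 and X
exists, so a compromise is always representable; δ is resampled (up to
100 times) when integer rounding collapses the gap, then the offset is
forced to exactly the minimum distance, flipping to the positive side if
X would fall below 1.  Whether the original sign schedule was fixed or
randomized per participant is not stated; it is exposed in `TaskConfig`.

## Generative model of a participant

For participant i in group g, on every round:

1. **First estimate.**  E1 = max(1, round(true·R)), R lognormal with
   median `accuracy_median` and log-scale sd `accuracy_cv` (default 0.20,
   a typical coefficient of variation for brief numerosity estimation).
   People underestimate large numerosities roughly multiplicatively, so
   the error is multiplicative and right-skewed.  Because the published
   accuracy figures are *means* of E1/true (69% TD, 68% CP/LCU, 74%
   CP/HCU), defaults set the median to mean·exp(−cv²/2) so the realized
   mean hits the target; the per-round draws are independent (no stable
   participant-level estimation skill — see Limitations).
2. **Strategy.**  With probability logistic(c_g + u_i) the round is
   all-or-nothing, else compromise; u_i ~ N(0, τ00) with τ00 = 3.96.
   The conditional intercept c_g is obtained by *inverting the
   logistic-normal integral* so that the population-average
   all-or-nothing share equals the target marginal — at τ00 ≈ 4 the
   naive logit of the marginal would be badly wrong (conditional and
   marginal odds differ by roughly a factor of two here).  The integral
   uses 40-node Gauss–Hermite quadrature; the inversion is a Brent
   root-find to |Δ| < 1e−10.
3. **Response.**  All-or-nothing rounds split stay:copy with fixed odds
   p_stay:p_copy.  Compromise rounds draw w ~ Beta(a, b) and set
   E2 = round(E1 + w·(X − E1)), clamped to the open integer interval
   between E1 and X so integer rounding can never relabel a drawn
   compromise as stay or copy.
4. Optionally (off by default) a round is replaced by an out-of-range
   response at rate `invalid_round_rate`, purely to exercise the
   exclusion filter; no behavioural mechanism is claimed.

Heterogeneity enters only the all-or-nothing propensity — one random
intercept, mirroring the single random factor of the fitted strategy
model; the stay/copy split and the Beta weights are homogeneous within
group.  Age and IQ are group-shifted normals (means/sds from the
published sample table), used only to exercise covariate re-runs.

## Calibration by moment matching

Round-level targets per group are {compromise share p_comp, mean s,
P(s < 0.5)}.  With m the Beta mean and F the below-half mass of the
compromise weight, the moment system is

    p_copy + p_comp·m = mean_s
    p_stay + p_comp·F = P(s < 0.5)
    p_stay + p_copy + p_comp = 1.

Three equations cannot pin down four unknowns (p_stay, p_copy, a, b), so
the Beta mean is fixed — default 0.35 — and the concentration κ = a + b
is solved by root-finding so F matches.  The marginal shares are
invariant to the heterogeneity because u_i only reallocates
all-or-nothing propensity across participants, not its population
average.

**Integer discretization.**  Because E2 is an integer, a realized
compromise weight lives on the grid k/d with d = |X − E1| (typically
4–10).  When d is even, all w within 1/(2d) of 1/2 round to exactly
s = 1/2, which removes roughly ten percentage points from P(s < 0.5)
relative to the continuous Beta CDF when the weights are concentrated
just below one half.  The packaged default profiles therefore calibrate F
against the *realized* below-half probability, averaged over the task's
empirical gap distribution (computed once, deterministically, from the
accuracy model and task config): F_d = G(1/2) for odd d and
G(1/2 − 1/(2d)) for even d, with G the Beta CDF.  This is also why the
default Beta mean is 0.35: at 0.40 the TD target P(s < 0.5) = 0.80 is
unattainable on the grid (the attainable maximum is ≈ 0.83 continuous-
equivalent).  `calibrate_profile` retains the continuous contract when no
gap distribution is supplied.

Default targets: TD 64.11% compromise, mean s 0.36, P(s < 0.5) 80.00%;
CP/LCU 35.86%, 0.32, 74.19%; CP/HCU — whose compromise share was reported
only graphically — uses 0.50, midway between the other groups (consistent
with it differing significantly from neither), with its published mean s
0.36 and P(s < 0.5) 68.75%.  The CP/HCU share is flagged as a
non-published value in the packaged config.

## Inference

* **Adjustment model.**  Fit to *round-level* s (not participant means):
  with a subject random intercept this is the only reading consistent
  with an observation count equal to the number of valid rounds.  REML
  via `statsmodels.MixedLM`; a τ00 estimate at the boundary (~0) is
  reported with a singular-fit warning, not an error.
* **Strategy GLMM.**  In-house ML fitter with *adaptive* Gauss–Hermite
  quadrature (21 nodes; per-cluster mode by damped Newton, grid centred
  and scaled at the mode, log-sum-exp accumulation).  With τ00 ≈ 4 and
  five observations per cluster, prior-scaled (non-adaptive) grids
  misplace the mass and bias τ00.  The fitter reproduces
  `lme4::glmer(nAGQ = 25)` to ~1e−3 in coefficients and log-likelihood
  on a 108-participant dataset (tested).  Wald CIs are computed on the
  link scale from a finite-difference Hessian and exponentiated for odds
  ratios.  The group factor is tested by a likelihood-ratio χ² against
  the model without group terms (the statistic is invariant to the
  reference level).  Degenerate outcomes and separation fall back to a
  mild ridge penalty (0.1) on the fixed effects, flagged in the result.
* **Tukey contrasts.**  All pairwise group differences of the fixed
  effects; the single-step adjusted p for contrast k is
  1 − P(max_j |Z_j| ≤ |z_k|) under the joint normal of the contrast
  statistics (scipy multivariate-normal CDF), which is monotone in |z|,
  never below the unadjusted p, and reduces to the plain Wald test with
  two groups.
* **Variance explained.**  ICC = τ00/(τ00 + σ²) with σ² = π²/3 on the
  logit scale; Nakagawa marginal R² = Vf/(Vf + τ00 + σ²) and conditional
  R² = (Vf + τ00)/(·), with Vf the variance of the fixed-effect linear
  predictor over the estimation sample (the model's own design matrix,
  not population weights).
* **Covariates.**  Age and IQ are mean-centered before entry so the
  intercept keeps its TD-reference interpretation.
* **Accuracy ANOVA.**  One-way ANOVA on participant mean E1/true with
  η² = SS_between/SS_total.

## Problem sizes and reproducibility

Seeds are mandatory everywhere (no wall-clock defaults); the pipeline is
byte-deterministic given (config, seed).  The packaged analyses use: one
108-participant cohort for the worked example; 100 replicates at the
study's group sizes for recovery experiments; 20,000 participants
(100,000 rounds) per group for calibration checks.  These sizes put
Monte-Carlo error well inside the tolerances being checked while keeping
any single script in the tens of seconds on one CPU.

## Limitations

* The generator has no stable participant-level estimation skill: the
  accuracy draws are independent across rounds, so between-participant
  accuracy variance is much smaller than in real data and a group
  difference in mean accuracy reaches significance far more easily than
  it would empirically.  The accuracy ANOVA is exercised, not
  benchmarked.
* Because heterogeneity enters only the strategy choice — and the TD
  copy-share among all-or-nothing responses happens to sit near the
  Beta mean — participant mean-s varies little between participants and
  the adjustment model's ICC on synthetic cohorts is near zero, unlike
  in real data where compromise weights themselves are participant-
  stable.  Passing tests therefore validate the estimators, not the
  realism of the between-participant structure of s.
* No learning or order effects across rounds (the task design gives no
  feedback), no response-time model, no distance weighting (the
  calibration removes it by construction).
* Invalid responses (s < 0, s > 1) have no behavioural model; the
  injection switch exists only to test the exclusion machinery.
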