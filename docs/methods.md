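# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and what the validation studies do and do not establish.

## Time and age conventions

Time is discretized to calendar months (`month = year*12 + m`); ages are
month differences. Months are the finest grain any estimator here needs:
the direct life table works on child-months, and indirect methods work on
whole years. A child dying in the interview month counts as an observed
death (the tie between death and censoring is broken toward the death,
and the death month contributes a full month of exposure). Women are
interviewed mid-year of the survey year at ages uniform on 15–49.

## Synthetic birth histories

The generator emulates the structure of restricted survey/census
microdata so every stage is testable end to end.

* **Latent surface.** `logit Q_kt = α + S_kt`, with S a zero-mean
  Gaussian field with separable covariance Σ_space ⊗ Σ_time — the
  inverses of a proper-CAR precision (D − ρₛW) and a stationary AR(1)
  precision — rescaled so the average marginal variance equals σ²_S.
  Sampling uses the matrix-normal factorisation S = A Z Bᵀ.
* **Fertility.** Age-specific annual birth probabilities per 5-year
  group, applied monthly (rate/12). The default schedule
  (0.10, 0.25, 0.24, 0.20, 0.14, 0.06, 0.02 births/woman/year for ages
  15–19 … 45–49) is a high-fertility East-African-style pattern chosen to
  give realistic parity distributions; any schedule can be supplied.
  Fertility is independent of mortality (no replacement effects) and
  women do not migrate — stated simplifications.
* **Child survival.** A piecewise-constant monthly hazard over the six
  under-five age segments. `hazard_split` fixes the share of all
  under-five deaths falling in each segment (default 0.35, 0.30, 0.15,
  0.10, 0.06, 0.04 — a declining pattern loosely mimicking model life
  tables; the true within-five age pattern behind published indirect
  coefficients is not known, so this is a documented stand-in). Segment
  monthly hazards are solved so the cumulative death probability equals
  the surface value q5 for the child's county and birth year exactly.
* **Censuses** are represented as surveys with `collects_sbh` only and
  large n.

What passing tests on these data do **not** show: robustness to date
heaping and displacement, survey weights and cluster designs, HIV-related
under-reporting in summary histories, or migration — none of which the
generator produces.

## Direct estimator

Deaths and exposure are tabulated by age segment and period (default 24
months, anchored at the interview month and counted backwards, the DHS
convention). Monthly risk per cell is m = D/E, survival P = 1 − m, and
q5 = 1 − Π Pₛ^(width_s). The phrase "ratio of deaths to months lived
raised to a power" is read as P = 1 − D/E raised to the segment width,
which is the only reading consistent with the product formula. Periods
with any zero-exposure segment yield an explicitly undefined estimate
(NaN + flag), never a silent zero. The period's time label is the
calendar year of its central month.

## Indirect estimators

Group rules: maternal age groups 15–19 … 45–49; time-since-first-birth
groups 0–4 … 20–24 (childless women and first births beyond 24 years are
excluded with a log entry). Groups with CD = 0 or CD = CEB are skipped —
the logit is undefined there — rather than imputed. The CEB regressor is
mean parity (CEB per woman), the standard Brass usage.

**Calibration.** Published coefficient tables derive from external pooled
multi-country fits that are not reproducible here, so the package fits
its own by OLS on a synthetic corpus (≥ 20 surveys, varied true
mortality): the response is logit of the *direct* estimate on the same
simulated population at the group's reference time; regressors follow the
cohort/period linear predictors. The country offset U is identically 0 —
a single synthetic region absorbs it into the intercept. Reference
offsets r_i are the exposure-weighted mean years-before-interview of each
group's under-five child-months (pooled over the corpus, capped at the
18-year cohort horizon and forced non-decreasing in group order); this is
a regression-based stand-in for classical Brass time-location, which the
source material does not specify. Groups with fewer than six usable
corpus points fall back to the identity conversion with a warning.
Degenerate designs (a constant regressor) raise a calibration error
naming the regressor.

The held-out validation uses 5,000-women surveys so that the direct
"truth" itself is estimated with small error; at much smaller samples the
apparent relative error is dominated by noise in the truth, not by the
conversion.

## Spatio-temporal smoother

Model: `logit(Q_ijkt) = α + S_kt + Z_ijkt` with
`Q_S = (1/σ²_S)(D − ρₛW) ⊗ Q_AR1(φₜ)` and
`Var(Z_ijkt) = τ²ⱼ / log n`. Taken literally, "noise variance is the
product of the log sample size and a method factor" would give *larger*
surveys *more* noise; since the stated intent is weights ∝ log n, the
default divides. The literal product is available via
`variance_mode="multiply"`. Census sample size is the number of women.
Natural log; n ≥ 3 enforced at load (so log n > 1), smaller records
rejected with a log entry.

The proper CAR (ρ < 1) is used rather than the intrinsic CAR so the joint
prior is proper and the dense Kronecker oracle used in tests is
well-defined. Note the two parameterisations: the *generator* rescales
the separable covariance to a target marginal variance; the *smoother*
uses the raw precision (1/σ²)Qₛ⊗Qₜ, where σ² is a scale parameter, not
the marginal variance. Both are stated where they appear.

**Priors** (unstated in the source; weakly informative, overridable):
α ~ N(0, 10²); σ_S and τⱼ half-normal(0, 5) on the SD scale;
ρₛ ~ U(0, 1); φₜ ~ U(−1, 1).

**MCMC.** Gibbs for the field (its full conditional is Gaussian with
precision Q_S + diag(Σ 1/v); sampled via dense Cholesky — problem sizes
here are a few hundred cells, where dense factorisation is faster than
sparse machinery) and for α; adaptive random-walk Metropolis on
transformed scales (log σ², logit ρ, atanh φ, log τ²) with scale
adaptation every 100 iterations during burn-in targeting ~30% acceptance,
frozen afterwards so the post-burn-in chain preserves detailed balance.
The reference schedule is 110,000 iterations, 10,000 burn-in, thin 10
(10,000 retained draws); validation studies use a reduced
11,000/1,000/10 schedule, which the oracle and coverage checks show is
adequate at the study sizes used (9–12 counties, 20–25 years). County-
years with no data are predicted automatically from the joint field draw
— process prior conditioned on neighbours, no noise term. Stored
probability draws are clamped away from exact 0/1 (float saturation of
the inverse logit under near-flat priors). A disconnected graph triggers
a warning and independent per-component fits.

**Cross-validation** holds out 10% of observations within every
(survey, method) stratum with at least 10 records, refits, and scores
held-out predictions on the probability scale (RMSE, bias).

## Targets and inequality

ARR uses discrete compounding, 1 − (end/start)^(1/Δt): with the published
2000 and 2013 national means it reproduces the printed 4.5%/year, whereas
the continuous log form gives 4.6% (available behind `continuous=True`).
The 2015 value is projected from the 2000–2013 ARR. World Summit
"and/or" is implemented as OR. Margin classes are computed per target —
within 20% relative of the binding criterion is a near miss —
and `margin_class` reports the MDG 4 (most recent) class. SDG 3.2 is
evaluated only when a 2030 value is supplied; long-range projection to
2030 is deliberately not performed. Palma-style group sizes round to the
nearest integer (47 counties → 19 high, 5 low); at least 10 counties are
required.

## Validation studies (what the numbers mean)

* **Recovery/coverage** (3×3 lattice, 20 years, 5 methods, 2 surveys,
  11,000/1,000/10, 20 replicates): posterior-mean RMSE vs truth must beat
  the raw per-observation RMSE, and pooled 95% CI coverage must lie in
  [90%, 99%]. Sizes chosen to make the experiment a routine run on one
  core.
* **Cross-validation bias** on the same design: pooled held-out bias
  within 2 Monte-Carlo SEs of 0 under a well-specified model.
* **Calibration hold-out**: 30 training + 8 test surveys of 5,000 women;
  median absolute relative error for central cohorts (20–34) and period
  years 0–15 at or under 10%.

## Known limitations

No survey weights, date-quality corrections, or HIV bias adjustment; no
covariates in the smoother (intercept + field only, by design); no
non-separable space-time kernels; fertility–mortality independence in the
generator; the calibrated coefficients are valid for data generated under
this generator's assumptions and are not substitutes for published
coefficient tables when analysing real data (drop those in via CSV).
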