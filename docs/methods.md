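# Methods

This note documents the statistical models behind `metabosurv`, the
assumptions of the synthetic-cohort generator, the numerical choices, and
what the test suite does and does not demonstrate.

## The survival model

All time-to-event inference is built on the Cox proportional-hazards model
with the **Breslow** tie approximation of the partial likelihood

  ℓ(β) = Σ_{event times t} [ Σ_{i∈D_t} x_i'β − d_t · log Σ_{j∈R_t} exp(x_j'β) ],

where D_t are the deaths at t, d_t = |D_t|, and R_t = {j : time_j ≥ t} is
the risk set. Breslow was chosen over Efron because (a) the simulated event
times are continuous, so ties have probability zero, and (b) it is the
default of the major commercial packages used in the clinical literature,
keeping coefficients comparable. Fitting is Newton–Raphson from β = 0 with
step halving; convergence when max|score| < 1e−8 or the log-likelihood
improves by < 1e−10, capped at 50 iterations. Step halving guarantees the
iterates are monotonically non-decreasing in ℓ. Standard errors come from
the inverse observed information; inference is Wald (z tests and
exp(β ± 1.96·se) 95% intervals), matching how clinical tables report HR /
CI / P. Likelihood-ratio intervals are not provided.

Degenerate designs are rejected up front (constant covariate, rank-deficient
matrix). Monotone likelihoods (perfect separation) are *flagged*, not
raised: a fit whose linear predictor moves more than 50 log-hazard units per
covariate standard deviation is returned with `converged=False` and a
diagnostic, so screening loops can record the failure and continue. The
baseline hazard is never estimated — no quantity in scope needs it.

Kaplan–Meier uses the product-limit estimator with the censored-after-event
convention at ties. The K-sample log-rank test accumulates the
hypergeometric mean and covariance of the per-group death counts at each
distinct event time; risk sets of size 1 contribute zero variance.

## The GIM polynomial search

GIM (generalized iterative modelling) searches for the polynomial
combination of covariates that maximizes the Cox partial likelihood. The
implementation is a penalized greedy forward(-backward) selection over
candidate monomials:

* Candidates are powers 1…max_degree (default 2) of each candidate variable.
* At every step each unused monomial is tried by **jointly refitting all
  coefficients** with a full Cox fit, and the model is scored by an
  information criterion; the best improving monomial is added, then single
  drops that improve the criterion are applied. The default criterion is BIC
  with the **number of events** as the effective sample size — the standard
  choice for partial-likelihood model selection, where censored rows carry
  little information. AIC is available.
* Ties within `tie_tolerance` (1e−10) break deterministically by
  (variable, power) lexicographic order, so the search is reproducible
  across platforms.

Two representation choices matter:

* **Centered monomial basis.** Candidate monomials are powers of the
  *centered* variable, standardized to unit variance. Raw powers of a
  positive covariate are nearly collinear over a physiological range
  (corr(x, x²) > 0.99 for plasma concentrations around 65 or 550 μM), which
  makes raw-basis selection arbitrarily flip between algebraically
  equivalent term sets; centered powers are close to orthogonal, so each
  degree's independent signal is visible to the criterion.
* **Exact raw-scale expansion.** The selected centered polynomial is
  expanded by the binomial theorem back to raw `coefficient · variable^power`
  terms (plus an intercept, which is irrelevant to hazards but keeps raw and
  internal evaluations identical). Coefficients are reported un-rescaled:
  the score is *not* a unit-variance linear predictor, mirroring how such
  published scores are stated in original units (years, μM).

The search strategy itself (greedy + information criterion) is one
reasonable reading of "iterative modelling to maximize the likelihood";
global or genetic search and cross-validated penalties are out of scope.
Interaction terms are excluded by default (the published score has none).

A caveat on recovered coefficients: on raw scale the linear and quadratic
coefficients of one variable are strongly anti-correlated estimates, so at
~160 events their individual sampling error is large (relative sd ≈ 0.2 for
the Phe linear term, ≈ 0.4 for Gln) even though the term *set*, the signs,
and the fitted risk surface are stable. Tests therefore assert term-set
recovery and unbiasedness of the coefficients, not tight per-replicate
coefficient error.

## Horizon classification under censoring

"Case by year t" is defined only for patients observed long enough: event
with time ≤ t → case (boundary inclusive); event-free follow-up through t
(time ≥ t, including events after t) → control; censored event-free before
t → excluded from that horizon. This reproduces the exclusion convention of
cross-sectional evaluations of prognostic markers; inverse-probability
time-dependent ROC estimators are deliberately out of scope.

ROC curves sweep the unique observed scores with the rule
score ≥ threshold → predicted case. The trapezoidal AUC is asserted at run
time against the tie-corrected rank statistic U/(n₁n₀) — an internal
identity, not a test-only check. AUC significance uses the Hanley–McNeil
normal approximation against 0.5, the same asymptotic family as the
clinical software the convention comes from; DeLong is not implemented. The
Youden-optimal cutoff maximizes J = Se + Sp − 1 with ties resolved to the
lowest qualifying cutoff, so a fixed score distribution yields one reusable
threshold across horizons. Zero-denominator predictive values are reported
as absent, never as 0/0. Mann–Whitney U uses exact null enumeration when
n₁·n₂ ≤ 400 and the pooled sample is tie-free, and the tie-corrected normal
approximation otherwise.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes — it
is a study-conditions definition, not a fitting target:

* **Covariates.** Age, AST, ALT, platelets, Phe, Gln are truncated-at-zero
  normals (published cohort summaries give only mean ± sd: age 59.50 ± 11.04
  y, AST 44.50 ± 38.57, ALT 39.19 ± 43.27 U/L, platelets 130.87 ± 57.54
  ×10⁹/L); sex/HBV/HCV are Bernoulli (0.63 / 0.57 / 0.31). AST/ALT and FIB-4
  (= age·AST / (platelets·√ALT)) are computed from the sampled values so the
  table is internally consistent.
* **Metabolite marginals.** No concentration distributions are published for
  the cohort; Phe ~ N(65, 15²) μM and Gln ~ N(550, 120²) μM truncated at
  zero are physiological plasma ranges consistent with the score's quadratic
  vertices (≈90 μM for Phe, ≈296 μM for Gln). Note the published year-wise
  Gln cutoffs (~39–42) are far below plasma-physiological μM and are
  probably on an instrument scale; the generator stays in μM and makes no
  attempt to reconcile the units. A consequence worth knowing: over the
  simulated Gln range the published quadratic is *increasing*, so in the
  synthetic world higher Gln predicts higher risk even though the screen's
  linear association in the source setting was negative.
* **Outcome.** Event time T is exponential with rate
  λ_i = r·exp(hr_per_unit · (R_i − mean R)), R the generating polynomial
  score (default: the packaged published score). The exponential baseline is
  the simplest choice with closed-form expectations, and Cox inference is
  invariant to it. Censoring C is uniform on (0.1, 4.1] years — the
  enrolment-to-database-lock window of the emulated study design;
  time = min(T, C), event = [T ≤ C].
* **Calibration.** When a target event fraction is set (default
  39/475 ≈ 0.082), the baseline rate r is found by monotone bisection on the
  closed-form expectation
  P(T ≤ C) = 1 − (e^{−0.1λ} − e^{−4.1λ})/(4λ), averaged over the realized
  relative hazards. No Monte Carlo is involved; monotonicity in r is
  asserted during the bisection.
* **hr_per_unit.** Default 0.862, so the fitted hazard ratio per score unit
  is exp(0.862) ≈ 2.37 — an emulation of the magnitude reported for such
  scores, not a reproduction claim. Setting hr_per_unit = 1 gives the pure
  H(t|R) = H₀(t)·e^R form; both conventions are exposed because published
  formulations are ambiguous between them.
* **Spectra.** Spectra are born binned on the 0.505–9.495 ppm axis
  (900 × 0.01 ppm bins): bins inside a metabolite's annotation interval
  carry gain·concentration, all others a flat baseline (10), plus iid
  Gaussian noise (sd 7, giving a bin-to-concentration correlation ≈ 0.9).
  No free-induction decay, phasing, baseline-correction or peak-shape
  physics is emulated, and the annotation intervals (e.g. Phe 7.30–7.45 ppm)
  are toy placeholders, not curated chemical shifts. The water region
  [4.50, 5.00) ppm is present in raw spectra and dropped by the screen; the
  interval was fixed so the α-glucose reference doublet at 5.23 ppm stays on
  axis.
* **Secondary quantification.** The chromatographic re-measurement is
  conc·(1 + N(0, σ_rel)) with a small positive floor. σ_rel = 0.246 was
  fixed by grid-search simulation so that r(true, re-measured) for Phe at
  n = 475 is ≈ 0.676, the cross-platform agreement the analysis design
  presumes.

Because covariates are independent (apart from derived ratios), real-world
correlations — age with platelets, etiology with transaminases — are absent.
Passing tests therefore demonstrate correctness of the *methods* under the
assumed proportional-hazards structure, not performance claims about any
real cohort; headline cohort numbers (HRs, AUCs, cutoffs) from the emulated
study are cohort-specific and are never used as expected values.

## Pipeline conventions

* Screen: total-area normalization by default (reference-bin division is
  available; with a reference bin the screen reports that bin as untestable
  rather than erroring). Pareto scaling precedes the Welch screen for parity
  with multivariate metabolomics practice; the per-bin Welch t is invariant
  to per-column affine maps, so this does not change which bins are flagged.
  Raw P ≤ 0.01 flags with **no multiplicity correction** by default, as in
  exploratory untargeted screens; Benjamini–Hochberg is available behind a
  flag.
* Per-patient metabolite proxies are the mean (optionally max) normalized
  intensity over a metabolite's annotated significant bins, standardized to
  z-scores so hazard ratios read "per sd of normalized intensity".
* Univariate Cox screening carries variables with p < 0.05 into the
  multivariate fit and (continuous ones) into the GIM search.
* Determinism: every stochastic step is seeded; artifacts are written with
  repr round-trip floats and read back with correctly rounded parsers, and
  intensity matrices are kept C-contiguous, so re-running a stage from its
  persisted inputs reproduces byte-identical CSVs and a pipeline re-run
  reproduces identical manifest checksums.

## Problem sizes used by the test and acceptance suites

Monte-Carlo checks use: null screen calibration — 50 replicates × 850
screened bins at n = 200; Cox type-I error — 50 replicate cohorts (n = 500,
~45% events under a null hazard) × 8 independent null covariates; Cox
coefficient recovery — 3 replicates at n = 5,000 (uncensored); score
hazard-scale recovery — 5 replicates at n = 5,000 under the e^R form; GIM
term-set recovery — 20 replicates at n = 2,000 with the default 8.2% event
fraction. These sizes give estimator standard errors comfortably inside the
asserted tolerances while keeping the default suite under a minute of
Monte-Carlo work.

## Known limitations

* No time-varying covariates, stratified Cox, frailty, or Efron/exact ties.
* No time-dependent (IPCW / incident-dynamic) ROC; the exclusion rule above
  is the implemented convention.
* The annotation library is a lookup toy; real chemical-shift matching,
  peak deconvolution and spectral databases are out of scope.
* The generator's independence assumptions understate real covariate
  correlation; power estimates transfer to real cohorts only qualitatively.
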