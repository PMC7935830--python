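# Methods

## The population model

Darunavir disposition is described by a one-compartment model with
first-order absorption and first-order elimination, evaluated at steady
state on the apparent (oral, dose/F) scale.  The within-interval profile is
the standard periodic superposition closed form; `t` is always time after
the most recent dose (TAD, decimal hours) and times beyond one interval are
reduced modulo τ, so a sample drawn 19 h after the morning dose of a q12h
regimen is evaluated 7 h into the steady-state interval.  A pre-dose sample
(C₀, t = 0) equals the trough at the end of the interval by periodicity.
The removable singularity at kₐ = kₑ is evaluated with its analytic limit
whenever |kₐ − kₑ| < 10⁻⁸ h⁻¹; continuity across the switch is tested.

Inter-individual variability is log-normal and independent across CL/F,
V/F and kₐ (no correlation terms are estimated in the source model).
Covariate effects are coded proportionally, `TV·(1 + θ·indicator)`; the
magnitudes (−0.198 for female sex and −0.192 for CYP3A5 non-expressers on
CL/F, +0.991 for SLCO3A1 T-carriers on V/F) read naturally as percent
shifts under this form.  The genotype reference groups — CYP3A5 flag = 1
for \*3/\*3 homozygotes, SLCO3A1 flag = 1 for GT/TT — are assumptions of
this package (the source publication does not restate the original coding)
and both the coding and the parameter values are switchable through the
frequency-table and YAML config layers.

Residual error combines an exponential and an additive component:
`y = f·exp(ε₁) + ε₂`.  Simulation uses this form exactly; estimation uses
the variance-linearised Gaussian approximation `g = f²σ_exp² + σ_add²`
(the usual NONMEM convention — the exact log-normal + normal convolution
has no closed form).  The mismatch is deliberate and mirrors practice.

## Synthetic populations

No clinical data ship with the package; all analyses run on virtual
populations.  Subjects are drawn by independent categorical sampling from
the published learning-set frequencies (female 33.1%; CYP3A5 \*1/\*1 /
\*1/\*3 / \*3/\*3 / missing = 26.0/26.0/45.7/2.4%; SLCO3A1 GG/GT/TT/missing
= 82.7/14.2/0/3.1%; regimens 600 mg q12h / 800 mg q24h / 1200 mg q24h =
7.9/91.3/0.8%).  Printed columns can sum to slightly more than 100%
(one-decimal rounding); distributions within 0.5% of unity are
renormalised.  Missing genotypes are imputed with the most frequent
genotype for the subject's race; because only marginal genotype frequencies
are published, the overall modal genotype stands in for every race.

Resampling frequencies rather than reusing the original 127 covariate
vectors (which are not deposited) is the main approximation of the whole
artifact: strategy-evaluation metrics inherit the Monte-Carlo variability
of the covariate mix, which dominates the tolerance budget of the
acceptance checks.

Validation-style datasets place one sample per subject at a random
post-intake delay drawn from a truncated log-normal, parameterised from the
published summaries: μ = ln(median) and σ solved so that the 97.5th
percentile of the untruncated law equals the range maximum (q24h: median
14.8 h on [2, 31.5]; q12h: 13.7 h on [2, 25.8]).  Observed concentrations
below 0.001 mg/L are floored there — a value far below any plausible assay
LLOQ, chosen only to forbid nonphysical negatives; whether the original
simulations floored or redrew negatives is unstated.

Every generator is a pure function of its inputs and a seed.  Random
streams are keyed per (master seed, subject, replicate), and the parameter
draw precedes the observation noise within each stream, so two sampling
strategies evaluated under the same master seed see identical true
parameters — a paired-comparison variance reduction that can be disabled
(`independent_seeds=True`).

## MAP estimation

Individual random effects are the posterior mode of

    Σ_obs [(y − f(t;η))²/g(t;η) + ln g(t;η)] + Σ_k η_k²/ω_k²,

found by BFGS from the prior mode η = 0 (gradient tolerance 10⁻⁶) with a
5-point prior-sampled multistart fallback when the Hessian at the solution
is not positive definite.  All three η's are estimated jointly even though
only CL feeds the AUC — V and kₐ shape the prediction at early times.  With
ω_k = 0 the corresponding η_k is fixed at zero.  For Monte-Carlo studies a
vectorised damped-Newton solver fits tens of thousands of profiles at once
on the identical objective; any problem missing the gradient tolerance is
re-fit with the scalar path and flagged.  Batch and scalar paths are tested
for objective agreement to 10⁻⁶, and both against a dense grid scan.

Two properties of this estimator deserve emphasis because they defeat naive
expectations.  First, shrinkage: with sparse data the mode sits between the
prior and the likelihood, so even *noise-free* observations do not return
the data-generating η exactly (the ln g term alone displaces the mode);
exact recovery emerges only in the σ → 0 likelihood limit, which is what
the tests assert.  Second, IWRES computed against MAP individual
predictions have spread below 1 (≈0.9 on rich 8-point profiles, ≈0.76 on
single samples) because the fit absorbs part of the residual noise into η̂.

## Strategy evaluation

For each sampling strategy (1–4 distinct times in [0, 24) h): simulate 250
replicate profiles per subject, observe at the strategy's times,
MAP-estimate, derive AUC_OSS = daily dose / CL̂, and pool all
subject × replicate evaluations against AUC_ref = daily dose / CL_true:

    PE = (AUC_ref − AUC_OSS)/AUC_ref,  MPE = 100%·mean(PE),
    RMSPE = 100%·√mean(PE²),

plus Spearman ρ (average ranks on ties) and the fraction of |PE| ≤ 0.15
(inclusive), also restricted to the clinically meaningful exposure window
AUC_ref ∈ [50, 130] mg·h/L.  Pooling (rather than per-subject averaging)
is used throughout.

**Residual error in the evaluated observations.**  By default the MAP fits
consume the *noise-free* individual profiles, while the likelihood keeps
the full combined-error variance.  This choice reproduces the published
strategy comparison across all eight strategies and all four metrics
within Monte-Carlo noise — including the signs of the biases — whereas
fitting noisy observations degrades every strategy far beyond the reported
precision (e.g. RMSPE 17.5% instead of ≈12% for the three-point optimum).
The reference Monte-Carlo evidently evaluated noise-free simulated
profiles; `residual_error=True` exposes the harder assay-realistic variant.

## D-optimal design

The design stage linearises the mixed-effects model in η around 0 (FO):
marginal mean f(t; θ, 0) and covariance V = AΩAᵀ + diag(g), A = ∂f/∂η|₀.
The per-subject Fisher information matrix is assembled block-wise with the
normal-theory formulas; the group FIM is the subject FIM times the group
size, and the D-criterion is ln det.  Derivatives use central finite
differences (relative step 10⁻⁴).  Defaults, all switchable:

- *reduced* FIM (mean-derivative block without ∂V/∂θ terms), the default
  of the reference optimal-design software; a *full* variant is available;
- fixed effects CL, V, kₐ only — the design group is a homogeneous
  reference-covariate population (12 subjects, 800 mg q24h, the rich-PK
  substudy), in which the covariate θ's carry no information and would
  make the FIM singular;
- IIV variances ω² included; residual variances σ² treated as **fixed**.
  Under this convention one- and two-point designs have singular FIMs (the
  published analysis likewise could not compute the criterion for them),
  and the log-det gap between the {1,4,19} and {0,1,4} designs is small
  (0.11) and favours {1,4,19}, matching the published "comparable
  (delta = 0.081)".  With σ² estimated, the gap reverses sign and triples —
  inconsistent with the published optimizer outcome;
- the prior distribution used in the original estimation is *not* added to
  the FIM: the criterion measures design information only;
- numerically rank-deficient FIMs (smallest eigenvalue ≤ 10⁻¹² of the
  largest) report a non-computable criterion rather than a meaningless
  tiny determinant; optimised times keep a 0.1 h minimum spacing.

The time search runs adaptive random search (3000 draws, shrinking
perturbation around the incumbent, interleaved uniform restarts), then
cyclic per-coordinate line search on a 0.05 h grid, then a simplex polish;
the result is reported exactly and rounded to integer hours.  Against
exhaustive enumeration of all integer-hour triples the search always
attains the enumeration maximum.

**Known limitation.**  Under every defensible FIM convention and every
published parameter column, the global three-point optimum for this model
is {≈1, ≈7, ≈22} h, not the published {1,4,19} (which is not even a local
optimum of the criterion surface here).  The published design most likely
derives from the original full-model parameter vector (including the AAG
covariate), which is not printed in the source and cannot be
reconstructed.  The package reports its true optimum rather than the
published times; the design-comparison and sensitivity conclusions are
insensitive to this.  Sensitivity analysis (±30% on each of CL, V, kₐ,
one at a time) re-optimises and reports the last sampling time of the
hour-rounded design, counting a pre-dose sample as the end-of-interval
trough; across all six perturbations it stays within 16–24 h.

## Diagnostics

NPDE: per subject, K (default 1000) replicate observation vectors are
simulated under the full model; observed and simulated vectors are
decorrelated by the inverse Cholesky factor of the empirical simulation
covariance (identity for single observations); the prediction discrepancy
is the half-rank of the decorrelated observation among its simulations,
clamped to [1/2K, 1 − 1/2K], and npde = Φ⁻¹(pde).  The battery tests mean 0
(Wilcoxon signed-rank), variance 1 (χ² on the sample variance) and
normality (Shapiro–Wilk; on a seeded 5000-subsample when n exceeds the
implementation's reliable range).  The global adjusted p multiplies the
smallest component p by 3 (Bonferroni) by default; a ×4 variant mirrors
the correction magnitude of the reference R implementation, whose global
test adjusts over four components — with component p-values
(0.1, 0.39, 0.01) the two conventions give 0.03 and 0.04 respectively.
Under the true model the global test's type-I error is calibrated (≈5%
over 200 self-simulated datasets of 500 subjects).

pcVPC: observations are binned by TAD quantiles (default 8 bins; bins with
fewer than 3 observations merge into a neighbour), each observation and
simulation is multiplied by (bin-median population prediction / its own
population prediction), and the 5th/50th/95th observed percentiles are
compared with the 2.5–97.5% envelope of the same percentiles across the K
simulated replicates.  Finding a good binning for heterogeneous sparse
designs is intrinsically hard; the bin count is a parameter.  On
self-simulated data ≈90% of prediction-corrected observations fall inside
the simulated 5–95% band.

GOF tables provide PRED (η = 0), IPRED (η = η̂ from all of the subject's
observations) and IWRES = (DV − IPRED)/√g(IPRED).  FOCE-linearised
residuals (CWRES) are out of scope.

## Problem sizes and reproducibility

The headline strategy evaluation uses 127 subjects × 250 replicates
(31,750 MAP fits per strategy), the design stage a 12-subject group, the
diagnostics calibration 200 repetitions × 500 subjects, and the dense-grid
MAP oracle a 0.01-step scan of the ±4ω box — sizes chosen to match the
source analysis where stated and to keep the full test suite in the
minutes range.  Every stochastic quantity is a deterministic function of
an integer seed.  What passing tests show is fidelity of the machinery and
reproducibility of the published Monte-Carlo under frequency-matched
covariates; they cannot show how the model performs on real patients —
the synthetic population has independent covariates (no sex–genotype or
race–genotype dependence), no adherence irregularities, no
between-occasion variability and no assay censoring.
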