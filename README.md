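# drvoss

Population-pharmacokinetic simulation and optimal-sampling analysis for
darunavir, an HIV-1 protease inhibitor boosted with ritonavir or
cobicistat.

Darunavir exposure varies widely between patients, and a single trough
concentration is often a poor summary of it.  `drvoss` implements, as a
reusable and fully tested Python library, the machinery needed to design
and evaluate *limited sampling strategies* — small sets of post-dose
sampling times from which an individual's daily exposure (AUC₂₄) can be
estimated reliably:

- a fixed-parameter **one-compartment population model** with first-order
  absorption and elimination at steady state, log-normal inter-individual
  variability on CL/F, V/F and kₐ, combined exponential + additive residual
  error, and proportional covariate effects (sex and *CYP3A5\*3* on CL/F,
  *SLCO3A1* rs8027174 on V/F);
- a **synthetic-population generator** that resamples the published
  covariate/regimen frequencies (127-subject learning cohort; 800 mg q24h
  and 600 mg q12h regimens) and emulates sparse validation-style sampling;
- **MAP (empirical-Bayes) estimation** of individual random effects from
  sparse concentrations, with a vectorised batch solver for Monte-Carlo
  studies;
- **Monte-Carlo evaluation of sampling strategies** (Spearman ρ, MPE,
  RMSPE, fraction of AUCs within ±15%);
- **D-optimal design**: FO-linearised Fisher information matrix,
  log-determinant criterion, search over sampling times, and ±30%
  sensitivity analysis;
- **simulation-based diagnostics**: NPDE with the Wilcoxon / variance /
  Shapiro–Wilk battery and a prediction-corrected VPC.

## Model

Steady-state concentration after oral dosing (dose *D* every *τ* h):

```
C(t) = D·ka / (V·(ka − ke)) · [ e^(−ke·t′)/(1 − e^(−ke·τ)) − e^(−ka·t′)/(1 − e^(−ka·τ)) ]
```

with `ke = CL/V`, `t′ = t mod τ`, and the analytic limit at `ka = ke`.
Individual parameters are `CL = CL_pop·(1 + θ_sex·SEX)·(1 + θ_CYP·CYP)·exp(η₁)`
(and analogously for V and kₐ); `AUC₂₄ = daily dose / CL`.  MAP estimation
minimises

```
Σ_obs [ (y − f)²/g + ln g ] + Σ_k η_k²/ω_k²,   g = f²σ_exp² + σ_add²
```

The shipped default parameter set is the learning-set column of the source
model (CL/F 12.6 L/h, V/F 137 L, kₐ 0.545 h⁻¹, ω 0.238/0.353/0.575,
θ −0.198/−0.192/+0.991, σ 0.306/0.611); custom sets load from YAML/JSON.

## Worked example

Estimate a patient's clearance and exposure from three sparse samples
(`examples/fit_sparse_profile.py`):

```python
import drvoss as d

pop = d.LEARNING_SET
patient = d.CovariateProfile(female=1, cyp3a5_flag=1, slco3a1_flag=0)
regimen = d.Regimen(dose=800, tau=24)
obs = d.ObservationSet(times=(1.0, 4.0, 19.0), conc=(2.1, 3.4, 0.9),
                       regimen=regimen, covariates=patient)
fit = d.map_estimate(obs, pop)
print(fit.cl_hat, d.auc_from_map(fit, regimen))
```

```
typical CL for these covariates: 8.17 L/h
MAP individual CL:              11.85 L/h  (eta_CL = +0.372)
estimated AUC24:                67.5 mg*h/L
clinically expected exposure window: 50-130 mg*h/L -> inside
```

The three concentrations pull the clearance estimate 37% above the
covariate-typical value; the implied exposure still falls inside the
50–130 mg·h/L window that covers 95% of the learning population.

Comparing sampling strategies on a small virtual population
(`examples/evaluate_sampling_strategies.py`, 50 subjects × 50 replicates):

```
 strategy   rho    MPE  RMSPE  pct_within15  pct_within15_clinical    n
C1-C4-C19 0.939  1.772 11.889         82.24                 88.318 2500
 C0-C1-C4 0.928  0.910 12.676         80.88                 86.561 2500
    C0-C4 0.910  0.641 13.733         76.32                 82.740 2500
       C0 0.818 -1.736 17.423         64.76                 70.400 2500
       C1 0.702 -1.843 21.101         56.52                 61.880 2500
```

Three well-placed samples (1, 4, 19 h — or the logistically easier 0, 1,
4 h) estimate AUC₂₄ with ~12% RMS error and put ~4 in 5 predictions within
±15% of the truth; a pre-dose sample alone is the best single-sample
choice but leaves a third of predictions outside that band.

Other examples: `simulate_dataset.py` (population simulation + NONMEM-style
CSV), `optimal_design.py` (D-optimal times, design comparison, sensitivity),
`validate_with_npde_vpc.py` (NPDE battery and pcVPC on a sparse dataset).

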