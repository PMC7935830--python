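"""Simulate a virtual darunavir population and persist it as NONMEM-style CSV.

Draws subjects from the learning-set covariate/regimen frequencies, simulates
steady-state concentration profiles with log-normal inter-individual
variability and combined exponential+additive residual error, and writes the
dataset to disk.
"""

import drvoss as d

pop = d.LEARNING_SET
subjects = d.sample_covariates(n=20, rng_seed=42)
dataset = d.simulate_profiles(pop, subjects, n_rep=3, times=[0, 1, 4, 19], rng_seed=42)
d.write_dataset(dataset, "simulated_darunavir.csv")

print(dataset.head(8).round(3).to_string(index=False))
print(f"\n{dataset.ID.nunique()} subjects x {dataset.REP.nunique()} replicates, "
      f"{len(dataset)} observation rows written to simulated_darunavir.csv")
print("DV is the observed concentration (mg/L), CPRED the noise-free individual "
      "prediction, AUC24 the true steady-state exposure (mg*h/L).")
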