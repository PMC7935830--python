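"""Simulation-based model diagnostics on a sparse validation-style dataset.

Builds a synthetic external-validation dataset (one random post-intake
sample per subject), then runs normalized prediction distribution errors
(NPDE) with the three-test battery and a prediction-corrected visual
predictive check (pcVPC).
"""

import drvoss as d

pop = d.LEARNING_SET
dataset = d.sample_validation_like(pop, n_subjects=164, rng_seed=11)

npde = d.compute_npde(dataset, pop, K=1000, rng_seed=11)
print(f"npde mean {npde.table.npde.mean():+.3f}, variance {npde.table.npde.var(ddof=1):.3f}")
print(f"Wilcoxon (mean=0)      p = {npde.p_wilcoxon:.3f}")
print(f"variance test (var=1)  p = {npde.p_fisher_var:.3f}")
print(f"Shapiro-Wilk normality p = {npde.p_shapiro:.3f}")
print(f"global adjusted        p = {npde.p_global:.3f}  ({npde.adjustment})")
print("Under a correct model the npde are ~N(0,1); a small global p flags "
      "model misspecification.")

vpc = d.pc_vpc(dataset, pop, K=1000, n_bins=6, rng_seed=11)
cols = ["tad_mid", "n_obs", "obs_p50", "sim_p50_lo", "sim_p50_hi"]
print("\npcVPC (observed medians vs 95% CI of the simulated median, by TAD bin):")
print(vpc.table[cols].round(2).to_string(index=False))
inside = (
    (vpc.table.obs_p50 >= vpc.table.sim_p50_lo) & (vpc.table.obs_p50 <= vpc.table.sim_p50_hi)
).mean()
print(f"fraction of bins with the observed median inside the band: {inside:.2f}")
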