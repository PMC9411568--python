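"""Simulate a seeded synthetic biobank cohort.

Builds methylation betas (cell-type mixtures plus sparse causal effects),
genotype dosages in Hardy-Weinberg proportions, baseline covariates, and one
continuous lab plus one binary diagnosis outcome, then prints what the
generator planted so downstream examples can try to recover it.
"""

import numpy as np

from methrisk import SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_samples=300, n_cpgs=500, n_variants=300, seed=7,
                       panel_spec=[("renal_panel", ["lab_1"])])
cohort = simulate_cohort(cfg)

print(f"methylation: {cohort.methylation.shape[0]} samples x "
      f"{cohort.methylation.shape[1]} CpGs, betas in "
      f"[{cohort.methylation.to_numpy().min():.3f}, "
      f"{cohort.methylation.to_numpy().max():.3f}]")
print(f"genotypes:   {cohort.genotypes.shape[1]} variants, "
      f"mean MAF {np.minimum(cohort.genotypes.mean() / 2, 1 - cohort.genotypes.mean() / 2).mean():.3f}")
print(f"binary outcome prevalence: {cohort.outcomes['phecode_1'].mean():.3f} "
      f"(target {cfg.binary_prevalence})")
t = cohort.truth["lab_1"]
print(f"lab_1 signal: {len(t.causal_cpgs)} causal CpGs, "
      f"{len(t.causal_variants)} causal variants, oracle R^2 = {t.oracle_r2:.3f}")
# oracle R^2 is the ceiling any predictor can reach on this outcome:
# var(linear predictor) / (var(linear predictor) + noise variance)
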