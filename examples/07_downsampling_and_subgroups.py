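"""Learning curves and subgroup transfer of a risk score.

Re-runs the double cross-validation on subsamples of increasing size to show
how accuracy grows with cohort size, then evaluates a whole-cohort model
within each self-reported group and re-trains inside groups with the
p < 0.01 replication rule.
"""

from methrisk import SimulationConfig, simulate_cohort
from methrisk.experiments import (
    downsample_experiment, retrain_within_group, subgroup_evaluate,
)
from methrisk.models import double_cv, prepare_covariates

cohort = simulate_cohort(SimulationConfig(n_samples=400, n_cpgs=300,
                                          causal_cpgs_per_outcome=10, seed=21))
C = prepare_covariates(cohort.covariates)
y = cohort.outcomes["lab_1"].to_numpy()

res = downsample_experiment(y, cohort.methylation, C, sizes=[100, 200, 400],
                            reps=5, seed=21, families=("lasso",),
                            outcome="lab_1")
print("learning curve (mean CV R^2 with 95% CI):")
for _, row in res.summary().iterrows():
    print(f"  n={int(row['size']):>4}: {row['mean']:.3f} "
          f"[{row['ci_lo']:.3f}, {row['ci_hi']:.3f}]")
# accuracy should rise with n: the score is information-limited, not
# model-limited, at these cohort sizes

cv = double_cv(y, cohort.methylation, C, families=("lasso",), seed=21,
               outcome="lab_1")["lasso"]
groups = cohort.covariates["group"]
rep = subgroup_evaluate(cv, y, groups, B=300, seed=21)
print("\nwhole-cohort model evaluated within each group:")
print(rep.table.round(3).to_string(index=False))

retrained = retrain_within_group(y, cohort.methylation, C, groups, seed=21,
                                 min_group_n=50, outer_k=5, inner_k=5)
print("\nre-trained within groups (replication = association p < 0.01):")
print(retrained.table[["group", "n", "metric", "p", "replicated"]]
      .round(4).to_string(index=False))
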