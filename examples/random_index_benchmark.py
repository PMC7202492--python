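"""Benchmark randomly assembled indices by deficit count.

Randomly composed indices provide the reference distribution an optimized
index must beat: here we sweep sizes 25-108 and summarize the ten-stratum
mean AUC per size bin.
"""

from frailty_ga import CohortSpec, generate_cohort, random_fi_study

cohort = generate_cohort(CohortSpec(n_individuals=1500, n_causal=10,
                                    causal_effect_scale=2.0, seed=9))
study = random_fi_study(cohort, n_fixed=100, fixed_k=40, n_sweep=400,
                        k_range=(25, 108), seed=10)

fixed = study.records[study.records["study"] == "fixed"]
print(f"100 random 40-deficit indices: mean AUC median "
      f"{fixed['mean_auc'].median():.3f}, max {fixed['mean_auc'].max():.3f}")
print()
print("sweep of 400 random indices, sizes 25-108, binned by deficit count:")
print(study.summary.to_string(index=False,
                              float_format=lambda x: f"{x:.3f}"))
print()
print("The median rises then plateaus with size: once enough informative")
print("deficits are aboard, adding more mostly dilutes the index.  A zero")
print("bin at the smallest sizes means those indices were excluded by the")
print("missing-data rules (with few deficits included, a single missing")
print("cell already voids a person's FI) and received sentinel fitness 0.")
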