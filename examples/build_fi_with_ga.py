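"""Evolve a frailty index with the genetic algorithm and score the result.

Runs a reduced-scale configuration (population 200 instead of 1100) on a
synthetic training sample, then checks how many truly causal deficits the
optimized index recovered.
"""

import numpy as np
from scipy.stats import hypergeom

from frailty_ga import (CohortSpec, GAConfig, evaluate_fitness,
                        generate_cohort, run_ga, split_train_test)

cohort = generate_cohort(CohortSpec(n_individuals=3363, n_causal=10,
                                    causal_effect_scale=2.0, seed=1))
split = split_train_test(cohort, 0.70, seed=2)

config = GAConfig(population_size=200, max_iterations=60, patience=7, seed=3)
result = run_ga(split.train, config)
best = result.final_best

print(f"converged after {result.iterations_run} iterations ({result.converged_by})")
print(f"training mean AUC (10 strata): {result.final_best_fitness:.4f}")
print(f"deficits included:             {best.n_included} of {cohort.n_deficits}")

test_report = evaluate_fitness(best, split.test)
print(f"test mean AUC:                 {test_report.mean_auc:.4f}")

overlap = np.intersect1d(best.included_indices, cohort.causal_set).size
null = hypergeom.ppf(0.975, cohort.n_deficits, cohort.causal_set.size,
                     best.n_included)
print(f"causal deficits recovered:     {overlap} of {cohort.causal_set.size} "
      f"(chance 97.5th percentile: {null:.0f})")

# The fitness is the mean of ten AUCs (whole sample + sex and age subgroups,
# each at 3y and 6y); an overlap above the hypergeometric null shows the GA
# found signal, not a lucky subset.
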