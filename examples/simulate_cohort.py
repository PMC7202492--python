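"""Generate a synthetic aging cohort and inspect its structure.

The generator emulates a population-based study of adults aged 60+:
age-graded deficit prevalences, deficit-driven mortality at two horizons,
and sporadic missingness.
"""

import numpy as np

from frailty_ga import CohortSpec, generate_cohort

spec = CohortSpec(n_individuals=3363, seed=1)
cohort = generate_cohort(spec)

old = cohort.age > 78
D = cohort.deficits
frac_increasing = np.mean([np.nanmean(D[old, j]) > np.nanmean(D[~old, j])
                           for j in range(cohort.n_deficits)])

print(f"individuals:            {cohort.n}")
print(f"median age:             {np.median(cohort.age):.1f} years")
print(f"proportion female:      {np.mean(cohort.sex == 'female'):.3f}")
print(f"3-year mortality:       {cohort.death_3y.mean():.3f}  (target 0.142)")
print(f"6-year mortality:       {cohort.death_6y.mean():.3f}  (target 0.276)")
print(f"missing cells:          {np.isnan(D).mean():.3f}")
print(f"deficits more prevalent in the old: {frac_increasing:.2f}  (target 0.80)")

# Mortality intercepts are calibrated by bisection, so the realized rates sit
# within sampling noise of the targets; ~80% of deficits rise with age by
# construction, mirroring the deficit-accumulation literature.
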