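# Methods

## The frailty index and its missing-data rules

For a chromosome including *k* deficits, an individual's FI is the number
of included deficits present divided by the number of included deficits
observed.  Two rules guard against missingness distorting the ratio:

* **Person rule.** If the individual's missing included deficits *strictly
  exceed* 10% of *k*, the FI is set to missing.  "Exceed" is read
  literally: 5 missing out of 40 (> 4.0) triggers the rule, 4 does not.
* **Cohort rule.** If the number of missing FIs strictly exceeds
  ceil(0.075 · n) individuals, the index is flagged *excluded*.  The
  ceiling reproduces the canonical threshold of 177 for a 2354-person
  training sample (0.075 · 2354 = 176.55).

Individuals with a missing FI are dropped from all AUC computations —
standard ROC practice; the alternative (imputation) is out of scope.  An
excluded index receives sentinel fitness 0, which lets proportionate
selection purge it without disturbing population size; the other option,
resampling a replacement chromosome, would complicate reproducibility for
no clear gain.

## Fitness

Fitness is the unweighted arithmetic mean of ten Mann–Whitney AUCs: five
strata (whole sample, men, women, below the age median, at or above it)
crossed with two mortality horizons (3 and 6 years).  Age ties on the
median go to the older stratum so young/old is a partition.  The median is
recomputed from the cohort at hand rather than hard-coded (it is 78 in the
motivating population).  Strata overlap and differ in size; weights are
deliberately not applied so small subgroups (e.g. men) count as much as
the whole sample.  Ties in scores count ½, the standard Mann–Whitney
convention; the estimator is computed from midranks, algebraically equal
to exhaustive pair counting (property-tested against an O(n²) oracle and
scikit-learn).  A stratum degenerating to a single outcome class — only
possible on tiny synthetic cohorts — scores 0.5 with a warning rather than
aborting a whole GA run.

## The genetic algorithm

Defaults: population 1100, initial deficit counts 30–70, 3% elitism
(33 elites, 1067 couples), 3% mutation, at most 150 iterations, patience 7.

* **Initialization.** Fair-coin inclusion per deficit conditioned on the
  count band. Implemented by sampling the count from a truncated
  symmetric binomial and then a uniform subset of that size — identical in
  distribution to rejection sampling but exact even for extreme bands
  (e.g. a forced all-ones band), and O(1) per chromosome.
* **Selection.** Roulette wheel, p_i = fitness_i / Σ fitness_j, couples
  drawn i.i.d. with replacement; self-pairing is allowed (such couples
  produce a clone, possibly mutated).
* **Crossover.** Two interior cut points drawn uniformly without
  replacement and sorted; the child takes the outer segments from parent 1
  and the middle from parent 2.  One child per couple, so population size
  is conserved exactly (1067 children + 33 elites = 1100).
* **Mutation.** A per-child event: with probability 0.03 exactly one
  uniformly chosen allele flips.  A per-allele Bernoulli(0.03) would flip
  ~3 alleles per child — a much stronger operator than intended.
* **Replacement and termination.** Elites are the fittest incumbents (ties
  broken by lower index, the only deterministic choice that keeps runs
  bit-reproducible); children replace the rest.  The run stops at the
  iteration cap or when the best fitness has not improved by more than
  `improvement_tol` (default 1e-6, a guard against counting floating-point
  noise as progress) over the last `patience` iterations.  Deficit counts
  are constrained only at initialization; children may leave the 30–70
  band, and tests assert the implementation does not clamp them.
* **Multi-run driver.** n runs with seeds spawned from the master seed;
  the winner has the highest training fitness, ties broken by fewer
  deficits then lower run index (parsimony first, determinism second).

## Synthetic cohorts

The generator emulates the structure the method assumes, not any real
deficit list:

* **Ages** follow a truncated exponential-tilted density on [60, 104]
  whose tilt is solved (Brent's method) so the median is 78; a uniform
  would put the median at 82 and misplace the age split.
* **Deficit prevalence** is logistic in age,
  logit π_j = a_j + b_j·(age−78)/10, with baseline prevalence uniform on
  [0.03, 0.35]; 80% of deficits get slopes uniform on [0.3, 1.2] per
  decade (age-increasing), the rest on [−0.8, −0.15] — bounded away from 0
  so "age-decreasing" is empirically detectable at moderate n.
* **Mortality** is logistic in the causal deficits, age and sex:
  logit P = c_h + Σ w_j·deficit_j + 0.9·(age−78)/10 − 0.4·1[female], with
  w_j = `causal_effect_scale` · LogNormal(−0.2, 0.6) so a minority of
  causal deficits dominate and subset recovery is non-trivial.  The
  horizon intercepts are calibrated by bisection on the realized linear
  predictors, so expected mortality equals the targets (14.2% and 27.6%
  by default) exactly and the realized rates differ only by binomial
  noise (±1.1 points at 2 SD for n = 3363).  Six-year death is drawn
  conditionally on three-year death, making death_3y ≤ death_6y a
  structural invariant.
* **Missingness** is completely at random per cell, default 4%: under the
  10% person rule a 40-deficit index then yields ≈2% missing FIs,
  matching the sporadic missingness regime the method is designed for.
  Real missingness is rarely MCAR; nothing here exercises informative
  missingness, so passing tests say nothing about MNAR robustness.

`causal_effect_scale` (default 1.0) is the one knob beyond cohort shape:
2.0 gives the "strongly causal" regime used in recovery experiments, where
the true-model ten-stratum mean AUC is ≈0.9.

What the generator does **not** emulate: correlation between deficits
beyond their shared age dependence, domain structure, informative
missingness, and competing risks.  Recovery results on synthetic data
bound what the GA can do under favorable, independent-deficit conditions;
they do not certify performance on real cohorts.

## Evaluation

* **Bootstrap CIs** are percentile intervals from stratified resampling
  (cases and controls separately, N = 2000), preserving class balance per
  replicate.  BCa was not implemented; percentile is the cited technique
  and is exact enough at the sample sizes involved (coverage ≥ 90% at
  nominal 95% in simulation tests).
* **Index comparison** applies identical case/control resamples to both
  indices (paired), yielding a delta-AUC distribution; the two-sided
  p-value is 2·min(P(Δ\*≤0), P(Δ\*≥0)), capped at 1.
* **Adjusted odds ratios** come from a statsmodels logistic fit with the
  FI rescaled ×10, so exp(coef) is the OR per 0.1 FI; Wald 95% CI.
  Non-convergence and separation raise rather than returning garbage.
* **Random-index benchmark** draws uniform k-subsets, scores them with the
  identical ten-stratum fitness, and summarizes by deficit-count bin.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the GA at population 200 with
at most 60 iterations on cohorts of 1500–3363 individuals — the package's
reduced-scale reference configuration, chosen because every qualitative
property under test (monotone best-fitness trace, patience-based
convergence, causal recovery beyond the hypergeometric null, dominance
over 100 random 40-deficit indices) is already stable at this scale; the
full 1100-chromosome configuration is exposed as the default for real
analyses.  Bootstrap checks use N = 400–2000 replicates as noted per test.

## Known limitations

Single-child crossover discards the mirrored child; the deficit codebook
supports only scalar rules (no composite definitions); FIs are unweighted
ratios (no weighting or non-linear transforms); survival is dichotomized
at fixed horizons rather than modeled as time-to-event; and the GA's
hyperparameters, while faithful defaults, were not re-tuned here — on
other data they may trade accuracy against run time differently.
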