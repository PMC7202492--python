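"""Non-parametric AUC and the ten-stratum mean-AUC fitness function.

The fitness of a candidate frailty index is the arithmetic mean of ten
areas under the ROC curve: the whole sample plus four subsamples (men,
women, below the median age, at or above it), each evaluated against
3-year and 6-year mortality.  Averaging across strata rewards indices that
discriminate well for everyone rather than for the majority group only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .frailty_index import Chromosome, compute_fi
from .synthetic_cohort import Cohort

__all__ = ["StratumSet", "FitnessReport", "auc", "evaluate_fitness",
           "evaluate_population", "STRATA", "HORIZONS"]

STRATA = ("whole", "male", "female", "young", "old")
HORIZONS = ("3y", "6y")


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_case > score_control) + 0.5 P(tie).

    Individuals with missing (NaN) scores are dropped.  Computed from
    midranks, which is algebraically identical to counting all case-control
    pairs with ties at 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep].astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present to compute an AUC")
    r = rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class StratumSet:
    """Boolean masks for the five evaluation strata over one cohort.

    Age ties on the median go to the older stratum, so young/old partition
    the sample exactly as male/female do.
    """

    masks: dict[str, np.ndarray]
    median_age: float

    @classmethod
    def from_cohort(cls, cohort: Cohort, median_age: float | None = None) -> "StratumSet":
        age = cohort.age
        sex = cohort.sex
        med = float(np.median(age)) if median_age is None else float(median_age)
        masks = {
            "whole": np.ones(cohort.n, dtype=bool),
            "male": sex == "male",
            "female": sex == "female",
            "young": age < med,
            "old": age >= med,
        }
        return cls(masks=masks, median_age=med)


@dataclass
class FitnessReport:
    """The ten stratum-specific AUCs and their mean for one chromosome."""

    auc: dict[str, dict[str, float]]
    mean_auc: float
    n_effective: dict[str, dict[str, int]]
    excluded: bool = False

    def to_json(self) -> str:
        return json.dumps({"auc": self.auc, "mean_auc": self.mean_auc,
                           "n_effective": self.n_effective,
                           "excluded": self.excluded})


def _stratum_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    keep = ~np.isnan(scores)
    y = labels[keep]
    n_eff = int(keep.sum())
    if n_eff == 0 or y.min(initial=1) == y.max(initial=0):
        warnings.warn("stratum with a single outcome class; AUC set to 0.5",
                      stacklevel=3)
        return 0.5, n_eff
    return auc(scores[keep], y), n_eff


def evaluate_fitness(chromosome: Chromosome, cohort: Cohort,
                     strata: StratumSet | None = None,
                     max_person_missing_frac: float = 0.10,
                     max_cohort_missing_count: int | None = None) -> FitnessReport:
    """Ten-AUC fitness report for one chromosome.

    Computes the FI once, drops individuals with a missing FI within each
    stratum, and averages the ten AUCs without weights.  An FI vector
    flagged excluded (too many missing values) receives sentinel fitness 0
    so that selection purges it.
    """
    if strata is None:
        strata = StratumSet.from_cohort(cohort)
    fiv = compute_fi(chromosome, cohort, max_person_missing_frac,
                     max_cohort_missing_count)
    outcomes = {"3y": cohort.death_3y, "6y": cohort.death_6y}
    if fiv.excluded:
        return FitnessReport(auc={}, mean_auc=0.0, n_effective={}, excluded=True)
    aucs: dict[str, dict[str, float]] = {}
    n_eff: dict[str, dict[str, int]] = {}
    vals = []
    for name in STRATA:
        m = strata.masks[name]
        aucs[name] = {}
        n_eff[name] = {}
        for h in HORIZONS:
            a, n = _stratum_auc(fiv.values[m], outcomes[h][m])
            aucs[name][h] = a
            n_eff[name][h] = n
            vals.append(a)
    return FitnessReport(auc=aucs, mean_auc=float(np.mean(vals)),
                         n_effective=n_eff, excluded=False)


def evaluate_population(population: np.ndarray, cohort: Cohort,
                        strata: StratumSet | None = None,
                        max_person_missing_frac: float = 0.10,
                        max_cohort_missing_count: int | None = None) -> np.ndarray:
    """Mean-AUC fitness for every row of a (pop_size, n_deficits) 0/1 matrix.

    The FI matrix for all chromosomes is built with two matrix products,
    then each stratum/horizon AUC is computed per chromosome.  Agrees with
    ``evaluate_fitness`` row by row; empty (all-zero) and excluded
    chromosomes get fitness 0.
    """
    if strata is None:
        strata = StratumSet.from_cohort(cohort)
    pop = np.asarray(population, dtype=float)
    D = cohort.deficits
    n = D.shape[0]
    if max_cohort_missing_count is None:
        from .frailty_index import default_cohort_missing_limit
        max_cohort_missing_count = default_cohort_missing_limit(n)

    k = pop.sum(axis=1)                                   # included count per chromosome
    observed = (~np.isnan(D)).astype(float)
    present = np.nan_to_num(D, nan=0.0) @ pop.T           # n x m
    nonmiss = observed @ pop.T
    miss = k[None, :] - nonmiss
    with np.errstate(invalid="ignore", divide="ignore"):
        fi = present / nonmiss
    fi[miss > max_person_missing_frac * k[None, :]] = np.nan

    outcomes = {"3y": cohort.death_3y, "6y": cohort.death_6y}
    m_chrom = pop.shape[0]
    fitness = np.zeros(m_chrom)
    n_missing = np.isnan(fi).sum(axis=0)
    valid = (k > 0) & (n_missing <= max_cohort_missing_count)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in np.flatnonzero(valid):
            vals = []
            for name in STRATA:
                msk = strata.masks[name]
                for h in HORIZONS:
                    a, _ = _stratum_auc(fi[msk, i], outcomes[h][msk])
                    vals.append(a)
            fitness[i] = np.mean(vals)
    return fitness
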