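"""Test-sample evaluation of frailty indices.

Stratified-bootstrap AUC confidence intervals, paired bootstrap comparison
of two indices, covariate-adjusted odds ratios per 0.1 FI, and the
random-index simulation study (how does an optimized index compare with
indices assembled by chance?).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fitness import StratumSet, auc, evaluate_fitness
from .frailty_index import Chromosome
from .synthetic_cohort import Cohort

__all__ = ["BootstrapCI", "RandomFIStudyResult", "bootstrap_auc_ci",
           "compare_fis", "adjusted_or", "random_fi_study"]


@dataclass
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_boot: int
    stratified: bool
    seed: int
    n_degenerate_redrawn: int = 0


def _clean(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    keep = ~np.isnan(s)
    return s[keep], y[keep]


def _stratified_resample(n_case: int, n_ctrl: int, n_boot: int,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Index matrices resampling cases and controls separately with replacement."""
    return (rng.integers(n_case, size=(n_boot, n_case)),
            rng.integers(n_ctrl, size=(n_boot, n_ctrl)))


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000,
                     seed: int = 0) -> BootstrapCI:
    """Percentile 95% CI for the AUC via stratified bootstrap.

    Cases and controls are resampled separately with replacement (preserving
    class balance in every replicate), the Mann-Whitney AUC is recomputed per
    replicate, and the 2.5th/97.5th percentiles bound the interval.
    """
    s, y = _clean(scores, labels)
    cases, ctrls = s[y], s[~y]
    if cases.size == 0 or ctrls.size == 0:
        raise ValueError("both outcome classes must be present")
    point = auc(s, y)
    rng = np.random.default_rng(seed)
    ci, cj = _stratified_resample(cases.size, ctrls.size, n_boot, rng)
    reps = np.empty(n_boot)
    labels_rep = np.concatenate([np.ones(cases.size, bool), np.zeros(ctrls.size, bool)])
    for b in range(n_boot):
        reps[b] = auc(np.concatenate([cases[ci[b]], ctrls[cj[b]]]), labels_rep)
    lower, upper = np.percentile(reps, [2.5, 97.5])
    return BootstrapCI(point=point, lower=float(lower), upper=float(upper),
                       n_boot=n_boot, stratified=True, seed=seed)


def compare_fis(fi_a, fi_b, labels, n_boot: int = 2000, seed: int = 0) -> dict:
    """Paired stratified-bootstrap comparison of two indices' AUCs.

    Both indices are scored on the intersection of individuals with
    non-missing values; the same case/control resamples are applied to both,
    giving a bootstrap distribution of delta = AUC_a - AUC_b.  The two-sided
    p-value is 2 * min(P(delta* <= 0), P(delta* >= 0)).
    """
    a = np.asarray(fi_a, dtype=float)
    b = np.asarray(fi_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    keep = ~np.isnan(a) & ~np.isnan(b)
    if not keep.any():
        raise ValueError("no individuals with both indices non-missing")
    a, b, y = a[keep], b[keep], y[keep]
    delta = auc(a, y) - auc(b, y)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y)
    ctrl_idx = np.flatnonzero(~y)
    ci, cj = _stratified_resample(case_idx.size, ctrl_idx.size, n_boot, rng)
    labels_rep = np.concatenate([np.ones(case_idx.size, bool),
                                 np.zeros(ctrl_idx.size, bool)])
    deltas = np.empty(n_boot)
    for r in range(n_boot):
        rows = np.concatenate([case_idx[ci[r]], ctrl_idx[cj[r]]])
        deltas[r] = auc(a[rows], labels_rep) - auc(b[rows], labels_rep)
    lower, upper = np.percentile(deltas, [2.5, 97.5])
    p = 2.0 * min(float(np.mean(deltas <= 0)), float(np.mean(deltas >= 0)))
    return {"delta_auc": float(delta), "ci": (float(lower), float(upper)),
            "p_value": min(p, 1.0), "n_boot": n_boot, "seed": seed}


def adjusted_or(fi, outcome, covariates: pd.DataFrame) -> dict:
    """Odds ratio per 0.1-unit FI increase from an adjusted logistic model.

    The FI is multiplied by 10 before fitting so exp(coefficient) is the OR
    for a 0.1 increase.  ``covariates`` typically holds age, sex, a low-
    cognition flag and a slow-gait flag; any numeric/boolean columns work.
    Wald 95% CI; separation or non-convergence raises.
    """
    fi = np.asarray(fi, dtype=float)
    y = np.asarray(outcome, dtype=float)
    X = covariates.copy()
    for c in X.columns:
        if X[c].dtype == object:
            X[c] = (X[c] == "female").astype(float)  # sex coded female=1
        X[c] = X[c].astype(float)
    X.insert(0, "fi_per_0.1", fi * 10.0)
    keep = ~np.isnan(fi) & ~np.isnan(y) & ~X.isna().any(axis=1).to_numpy()
    X, y = X.loc[keep], y[keep]
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge (possible separation)")
    coef = float(res.params["fi_per_0.1"])
    lo, hi = res.conf_int().loc["fi_per_0.1"]
    return {"or_per_0.1": float(np.exp(coef)),
            "ci": (float(np.exp(lo)), float(np.exp(hi))),
            "coef": coef, "n": int(keep.sum())}


@dataclass
class RandomFIStudyResult:
    """Per-chromosome records and deficit-count-binned summaries."""

    records: pd.DataFrame          # chromosome_id, k, mean_auc
    summary: pd.DataFrame          # k-bin, n, q25, median, q75

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def random_fi_study(cohort: Cohort, n_fixed: int = 100, fixed_k: int = 40,
                    n_sweep: int = 2000, k_range: tuple[int, int] = (25, 108),
                    seed: int = 0, strata: StratumSet | None = None,
                    bin_width: int = 10) -> RandomFIStudyResult:
    """Benchmark randomly assembled indices against the optimized one.

    Generates ``n_fixed`` uniform random indices of exactly ``fixed_k``
    deficits plus ``n_sweep`` indices with sizes uniform over ``k_range``,
    scores each with the ten-stratum mean AUC, and summarizes the sweep by
    deficit-count bins (quartiles of mean AUC).
    """
    rng = np.random.default_rng(seed)
    if strata is None:
        strata = StratumSet.from_cohort(cohort)
    p = cohort.n_deficits
    rows = []
    ks = [fixed_k] * n_fixed + list(rng.integers(k_range[0], k_range[1] + 1,
                                                 size=n_sweep))
    for i, k in enumerate(ks):
        alleles = np.zeros(p, dtype=np.int8)
        alleles[rng.choice(p, size=int(k), replace=False)] = 1
        rep = evaluate_fitness(Chromosome(alleles), cohort, strata)
        rows.append({"chromosome_id": i, "k": int(k), "mean_auc": rep.mean_auc,
                     "study": "fixed" if i < n_fixed else "sweep"})
    records = pd.DataFrame(rows)
    sweep = records[records["study"] == "sweep"]
    if len(sweep):
        bins = (sweep["k"] // bin_width) * bin_width
        summary = (sweep.groupby(bins)["mean_auc"]
                   .agg(n="size", q25=lambda s: s.quantile(0.25), median="median",
                        q75=lambda s: s.quantile(0.75))
                   .reset_index().rename(columns={"k": "k_bin"}))
    else:
        summary = pd.DataFrame(columns=["k_bin", "n", "q25", "median", "q75"])
    return RandomFIStudyResult(records=records, summary=summary)
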