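import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from frailty_ga import Cohort, CohortSpec, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Hand-built 12-person cohort with 6 deficits and no missingness.

    Sized so every stratum retains both outcome classes at both horizons,
    and small enough that stratum AUCs can be recomputed by brute-force
    pair counting.
    """
    rng = np.random.default_rng(42)
    n, p = 12, 6
    age = np.array([62, 65, 70, 74, 76, 77, 79, 81, 84, 88, 92, 97], dtype=float)
    sex = np.array(["male", "female"] * 6)
    deficits = (rng.random((n, p)) < 0.35).astype(float)
    score = deficits.sum(axis=1) + 0.05 * (age - 78)
    death_3y = (score > np.quantile(score, 0.55)).astype(int)
    death_6y = np.maximum(death_3y, (score > np.quantile(score, 0.3)).astype(int))
    df = pd.concat(
        [pd.DataFrame({"id": np.arange(n), "age": age, "sex": sex}),
         pd.DataFrame(deficits, columns=[f"d{j+1:03d}" for j in range(p)]),
         pd.DataFrame({"death_3y": death_3y, "death_6y": death_6y})], axis=1)
    return Cohort(df)


@pytest.fixture(scope="session")
def medium_cohort() -> Cohort:
    """Synthetic 400-person cohort for fast GA unit tests."""
    return generate_cohort(CohortSpec(n_individuals=400, n_deficits=30,
                                      n_causal=5, causal_effect_scale=2.0,
                                      missing_rate=0.02, seed=5))


@pytest.fixture(scope="session")
def clean_cohort() -> Cohort:
    """Synthetic cohort without missingness (for exact vectorized checks)."""
    return generate_cohort(CohortSpec(n_individuals=300, n_deficits=20,
                                      n_causal=4, missing_rate=0.0, seed=9))


def brute_force_auc(scores, labels) -> float:
    """O(n^2) pair-counting AUC oracle: ties count 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep]
    cases, ctrls = s[y], s[~y]
    diff = cases[:, None] - ctrls[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
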