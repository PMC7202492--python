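"""Deficit-ratio frailty index with the two missing-data rules.

An FI is the number of deficits an individual exhibits divided by the number
of non-missing deficits considered.  Two guards handle missingness: an
individual whose missing deficits exceed 10% of those included gets a
missing FI, and an index with too many missing FIs across the cohort
(more than 7.5% of individuals by default) is flagged excluded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synthetic_cohort import Cohort

__all__ = ["Chromosome", "FIVector", "compute_fi", "fi_summary",
           "default_cohort_missing_limit"]


@dataclass(frozen=True, eq=False)
class Chromosome:
    """Binary inclusion vector over the candidate deficits.

    Allele 1 means the deficit counts toward the index; the chromosome is
    the genetic algorithm's unit of evolution and also the serialized form
    of any frailty index (optimized or hand-specified).
    """

    alleles: np.ndarray

    def __post_init__(self) -> None:
        a = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.int8))
        if a.ndim != 1 or not np.isin(a, (0, 1)).all():
            raise ValueError("alleles must be a 1-D 0/1 vector")
        object.__setattr__(self, "alleles", a)

    def __len__(self) -> int:
        return self.alleles.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromosome):
            return NotImplemented
        return np.array_equal(self.alleles, other.alleles)

    def __hash__(self) -> int:
        return hash(self.alleles.tobytes())

    @property
    def n_included(self) -> int:
        return int(self.alleles.sum())

    @property
    def included_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alleles)

    def to_string(self) -> str:
        return "".join(map(str, self.alleles.tolist()))

    @classmethod
    def from_string(cls, s: str) -> "Chromosome":
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))

    def to_names(self, deficit_names: list[str]) -> list[str]:
        return [deficit_names[i] for i in self.included_indices]

    def to_json(self, deficit_names: list[str]) -> str:
        return json.dumps({"deficits": self.to_names(deficit_names),
                           "alleles": self.to_string()})

    @classmethod
    def from_json(cls, payload: str, deficit_names: list[str] | None = None) -> "Chromosome":
        d = json.loads(payload)
        if "alleles" in d:
            return cls.from_string(d["alleles"])
        if deficit_names is None:
            raise ValueError("deficit_names required to decode a name-list chromosome")
        a = np.zeros(len(deficit_names), dtype=np.int8)
        idx = {n: i for i, n in enumerate(deficit_names)}
        for name in d["deficits"]:
            a[idx[name]] = 1
        return cls(a)

    @classmethod
    def from_names(cls, names: list[str], deficit_names: list[str]) -> "Chromosome":
        a = np.zeros(len(deficit_names), dtype=np.int8)
        idx = {n: i for i, n in enumerate(deficit_names)}
        for name in names:
            a[idx[name]] = 1
        return cls(a)


@dataclass
class FIVector:
    """Per-individual frailty-index values for one chromosome.

    ``values`` lie in [0, 1] with NaN for individuals failing the 10%
    missing-deficit rule; ``excluded`` is set when ``n_missing`` exceeds the
    cohort-level limit.
    """

    values: np.ndarray
    n_missing: int
    excluded: bool
    cohort_missing_limit: int = field(default=0)

    def to_csv_column(self) -> list[str]:
        return ["" if math.isnan(v) else f"{v:.6f}" for v in self.values]


def default_cohort_missing_limit(n_individuals: int, frac: float = 0.075) -> int:
    """Ceiling of frac * n: 2354 individuals at 7.5% -> 177."""
    return int(math.ceil(frac * n_individuals))


def compute_fi(chromosome: Chromosome, cohort: Cohort | np.ndarray,
               max_person_missing_frac: float = 0.10,
               max_cohort_missing_count: int | None = None) -> FIVector:
    """Deficit-ratio FI for every individual under one chromosome.

    FI_i = (# included deficits present) / (# included deficits non-missing).
    An individual whose missing included deficits strictly exceed
    ``max_person_missing_frac`` of the included count receives a missing FI.
    The vector is flagged ``excluded`` when the number of missing FIs
    strictly exceeds ``max_cohort_missing_count`` (default: ceil(7.5% of n)).
    """
    k = chromosome.n_included
    if k == 0:
        raise ValueError("chromosome includes no deficits; FI undefined")
    D = cohort.deficits if isinstance(cohort, Cohort) else np.asarray(cohort, dtype=float)
    if D.shape[1] != len(chromosome):
        raise ValueError("chromosome length does not match the deficit matrix")
    sub = D[:, chromosome.included_indices]
    miss = np.isnan(sub).sum(axis=1)
    nonmiss = k - miss
    present = np.nansum(sub, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fi = np.where(nonmiss > 0, present / np.maximum(nonmiss, 1), np.nan)
    fi[miss > max_person_missing_frac * k] = np.nan
    n_missing = int(np.isnan(fi).sum())
    if max_cohort_missing_count is None:
        max_cohort_missing_count = default_cohort_missing_limit(D.shape[0])
    return FIVector(values=fi, n_missing=n_missing,
                    excluded=n_missing > max_cohort_missing_count,
                    cohort_missing_limit=max_cohort_missing_count)


def fi_summary(fi: FIVector, age: np.ndarray | None = None,
               median_age: float | None = None) -> dict:
    """Descriptive summaries: max, mean, sample skewness, subgroup skewness.

    Skewness is the standardized third central moment (g1); a degenerate
    (constant) distribution reports 0.  When ``age`` is given the skewness is
    also reported below / at-or-above the age median.
    """
    v = fi.values[~np.isnan(fi.values)]
    if v.size < 2:
        raise ValueError("need at least two non-missing FI values")

    def skew(x: np.ndarray) -> float:
        if x.size < 2 or np.ptp(x) == 0:
            return 0.0
        return float(stats.skew(x, bias=True))

    out = {"max": float(v.max()), "mean": float(v.mean()), "skewness": skew(v),
           "n": int(v.size)}
    if age is not None:
        age = np.asarray(age, dtype=float)
        med = float(np.median(age)) if median_age is None else median_age
        keep = ~np.isnan(fi.values)
        out["skewness_young"] = skew(fi.values[keep & (age < med)])
        out["skewness_old"] = skew(fi.values[keep & (age >= med)])
        out["median_age"] = med
    return out
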