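"""Deficit preparation: codebook-driven dichotomization, train/test split,
and the size of the candidate frailty-index search space."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import Cohort

__all__ = [
    "CodebookEntry", "Codebook", "SplitResult",
    "apply_codebook", "split_train_test", "count_candidate_indices",
    "load_cohort",
]

_RULES = frozenset({"threshold_le", "threshold_ge", "equals", "already_binary"})


@dataclass(frozen=True)
class CodebookEntry:
    """Dichotomization rule for one deficit.

    ``threshold_le`` / ``threshold_ge`` are inclusive cuts in the raw
    variable's units (e.g. MMSE <= 27, walking speed <= 0.8 m/s);
    ``equals`` matches a code; ``already_binary`` passes 0/1 through.
    """

    name: str
    raw_variable: str
    rule: str
    cutoff: float | None = None
    domain_tag: str = ""

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {sorted(_RULES)}")
        if self.rule != "already_binary" and self.cutoff is None:
            raise ValueError(f"rule {self.rule!r} for {self.name!r} requires a cutoff")


@dataclass
class Codebook:
    entries: list[CodebookEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("deficit names in the codebook must be unique")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Codebook":
        """Read ``name,raw_variable,rule,cutoff,domain_tag`` rows."""
        df = pd.read_csv(path)
        entries = []
        for row in df.itertuples(index=False):
            cutoff = None if pd.isna(row.cutoff) else float(row.cutoff)
            tag = "" if pd.isna(getattr(row, "domain_tag", "")) else str(row.domain_tag)
            entries.append(CodebookEntry(str(row.name), str(row.raw_variable),
                                         str(row.rule), cutoff, tag))
        return cls(entries)


def apply_codebook(raw_table: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Re-codify raw variables into binary deficits.

    Returns one column per codebook entry, valued 1.0 where the rule fires,
    0.0 where it does not, and NaN where the raw value is missing.
    """
    out = {}
    for e in codebook.entries:
        if e.raw_variable not in raw_table.columns:
            raise KeyError(f"raw variable {e.raw_variable!r} not in table")
        raw = raw_table[e.raw_variable]
        if e.rule != "equals":
            vals = pd.to_numeric(raw, errors="coerce")
            bad = vals.isna() & raw.notna()
            if bad.any():
                raise ValueError(
                    f"non-numeric value under rule {e.rule!r} for {e.name!r}: "
                    f"{raw[bad].iloc[0]!r}")
        if e.rule == "threshold_le":
            deficit = (vals <= e.cutoff).astype(float)
        elif e.rule == "threshold_ge":
            deficit = (vals >= e.cutoff).astype(float)
        elif e.rule == "equals":
            deficit = (raw == e.cutoff).astype(float)
            vals = raw
        else:  # already_binary
            if not vals.dropna().isin([0, 1]).all():
                raise ValueError(f"{e.name!r} marked already_binary but has values "
                                 "outside {0, 1}")
            deficit = vals.astype(float)
        deficit[vals.isna() if e.rule != "equals" else raw.isna()] = np.nan
        out[e.name] = deficit
    return pd.DataFrame(out, index=raw_table.index)


@dataclass
class SplitResult:
    train: Cohort
    test: Cohort
    fraction: float
    seed: int


def split_train_test(cohort: Cohort, fraction: float = 0.70,
                     seed: int = 0) -> SplitResult:
    """Simple random split; train size is floor(fraction * n).

    Unstratified: with fraction 0.70 and n=3363 this yields the canonical
    2354 / 1009 training / test partition.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cohort.n)
    n_train = int(math.floor(fraction * cohort.n))
    return SplitResult(train=cohort.subset(np.sort(perm[:n_train])),
                       test=cohort.subset(np.sort(perm[n_train:])),
                       fraction=fraction, seed=seed)


def count_candidate_indices(n_deficits: int, k_min: int, k_max: int) -> int:
    """Exact number of deficit subsets of size k_min..k_max among n_deficits.

    Sum of binomial coefficients in exact integer arithmetic; with 109
    candidate deficits and subset sizes 30-70 the count exceeds 6.4e32,
    which is why exhaustive search is off the table.
    """
    if not 0 <= k_min <= k_max <= n_deficits:
        raise ValueError("need 0 <= k_min <= k_max <= n_deficits")
    return sum(math.comb(n_deficits, k) for k in range(k_min, k_max + 1))


def load_cohort(path: str | Path) -> Cohort:
    """Load a person-level cohort CSV (with optional JSON sidecar)."""
    return Cohort.from_csv(path)
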