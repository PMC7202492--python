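"""Six-phase genetic algorithm over deficit-inclusion chromosomes.

Phases per iteration: fitness evaluation (ten-stratum mean AUC), fitness-
proportionate ("roulette wheel") selection of parent couples, two-point
crossover producing one child per couple, low-probability single-allele
mutation, and replacement of everything but a small elite.  The elite
guarantees a non-decreasing best-fitness trace; the run stops at an
iteration cap or when the best fitness stalls for a patience window.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .fitness import StratumSet, evaluate_population
from .frailty_index import Chromosome
from .synthetic_cohort import Cohort

__all__ = ["GAConfig", "SelectionProbabilities", "GARunResult", "MultiRunResult",
           "init_population", "selection_probabilities", "select_couples",
           "crossover", "mutate", "replace", "check_termination",
           "run_ga", "multi_run"]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    Defaults follow the reference configuration: 1100 chromosomes seeded
    with 30-70 deficits each, 3% elitism (33 elites, 1067 couples), a 3%
    per-child mutation chance, and termination at 150 iterations or after
    7 iterations without best-fitness improvement.
    """

    population_size: int = 1100
    init_k_range: tuple[int, int] = (30, 70)
    elitism_frac: float = 0.03
    mutation_prob: float = 0.03
    max_iterations: int = 150
    patience: int = 7
    improvement_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.elitism_frac <= 1.0 or not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("elitism_frac and mutation_prob must lie in [0, 1]")
        k_min, k_max = self.init_k_range
        if not 0 <= k_min <= k_max:
            raise ValueError("init_k_range must be non-decreasing and non-negative")

    @property
    def elite_count(self) -> int:
        return int(round(self.elitism_frac * self.population_size))

    @property
    def n_couples(self) -> int:
        return self.population_size - self.elite_count

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        d = dict(d)
        if "init_k_range" in d:
            d["init_k_range"] = tuple(d["init_k_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GAConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["init_k_range"] = list(d["init_k_range"])
        return d


@dataclass(frozen=True)
class SelectionProbabilities:
    """Fitness-proportionate selection weights: p_i = f_i / sum_j f_j."""

    p: np.ndarray


def init_population(config: GAConfig, n_deficits: int,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Initial chromosomes: fair-coin inclusion conditioned on the size band.

    Each deficit enters a chromosome with probability 1/2, conditional on
    the total included count lying in ``init_k_range``.  Sampled directly
    from that conditional law (a truncated symmetric binomial size, then a
    uniform subset of that size), which is distribution-identical to
    rejection sampling and remains exact even for extreme bands.
    """
    k_min, k_max = config.init_k_range
    if k_max > n_deficits:
        raise ValueError("init_k_range exceeds the number of deficits")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ks = np.arange(k_min, k_max + 1)
    logw = np.array([math.lgamma(n_deficits + 1) - math.lgamma(k + 1)
                     - math.lgamma(n_deficits - k + 1) for k in ks])
    w = np.exp(logw - logw.max())
    w /= w.sum()
    sizes = rng.choice(ks, size=config.population_size, p=w)
    pop = np.zeros((config.population_size, n_deficits), dtype=np.int8)
    for i, k in enumerate(sizes):
        pop[i, rng.choice(n_deficits, size=k, replace=False)] = 1
    return pop


def selection_probabilities(fitnesses: np.ndarray) -> SelectionProbabilities:
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0):
        raise ValueError("fitnesses must be non-negative")
    total = f.sum()
    if total <= 0:
        raise ValueError("at least one fitness must be positive")
    return SelectionProbabilities(p=f / total)


def select_couples(probs: SelectionProbabilities, n_couples: int,
                   rng: np.random.Generator) -> np.ndarray:
    """n_couples parent pairs drawn i.i.d. with replacement; self-pairing allowed."""
    idx = rng.choice(probs.p.size, size=(n_couples, 2), replace=True, p=probs.p)
    return idx


def crossover(parent1: np.ndarray, parent2: np.ndarray,
              c1: int, c2: int) -> np.ndarray:
    """Two-point crossover: child = p1[:c1] + p2[c1:c2] + p1[c2:]."""
    n = parent1.shape[0]
    if not 1 <= c1 < c2 <= n - 1:
        raise ValueError("crossing-over points must satisfy 1 <= c1 < c2 <= n-1")
    child = parent1.copy()
    child[c1:c2] = parent2[c1:c2]
    return child


def mutate(child: np.ndarray, mutation_prob: float,
           rng: np.random.Generator) -> np.ndarray:
    """With probability ``mutation_prob``, flip one uniformly chosen allele."""
    if rng.random() < mutation_prob:
        child = child.copy()
        j = rng.integers(child.shape[0])
        child[j] = 1 - child[j]
    return child


def replace(population: np.ndarray, fitnesses: np.ndarray,
            children: np.ndarray, elite_count: int) -> np.ndarray:
    """Keep the ``elite_count`` fittest incumbents, replace the rest with children."""
    if children.shape[0] != population.shape[0] - elite_count:
        raise ValueError("children must number population_size - elite_count")
    # stable sort on -fitness: ties broken by lower index
    order = np.argsort(-np.asarray(fitnesses, dtype=float), kind="stable")
    elites = population[order[:elite_count]]
    return np.vstack([elites, children]).astype(np.int8)


def check_termination(best_trace: list[float], config: GAConfig
                      ) -> Literal["continue", "stop_max_iter", "stop_patience"]:
    """Stop at the iteration cap, or when the best fitness has not improved
    by more than ``improvement_tol`` over the last ``patience`` iterations."""
    if not best_trace:
        raise ValueError("trace must be non-empty")
    if len(best_trace) >= config.max_iterations:
        return "stop_max_iter"
    if len(best_trace) > config.patience:
        if best_trace[-1] - best_trace[-1 - config.patience] <= config.improvement_tol:
            return "stop_patience"
    return "continue"


@dataclass
class GARunResult:
    """Per-iteration trace and the final best chromosome of one GA run."""

    trace: list[dict]
    final_best: Chromosome
    final_best_fitness: float
    iterations_run: int
    converged_by: str
    seed: int

    def trace_jsonl(self) -> str:
        return "\n".join(json.dumps(rec) for rec in self.trace)


def run_ga(cohort: Cohort, config: GAConfig,
           strata: StratumSet | None = None) -> GARunResult:
    """Run the full algorithm on one cohort; reproducible from ``config.seed``.

    Each iteration evaluates the whole population, logs the best and average
    fitness, and (unless terminating) breeds the next generation.  Deficit
    counts are only constrained at initialization; crossover and mutation
    may move children outside the initial 30-70 band.
    """
    if strata is None:
        strata = StratumSet.from_cohort(cohort)
    rng = np.random.default_rng(config.seed)
    n_def = cohort.n_deficits
    pop = init_population(config, n_def, rng)

    trace: list[dict] = []
    best_trace: list[float] = []
    while True:
        fits = evaluate_population(pop, cohort, strata)
        b = int(np.argmax(fits))
        best_chrom = pop[b].copy()
        best_trace.append(float(fits[b]))
        trace.append({
            "iteration": len(trace) + 1,
            "best_auc": float(fits[b]),
            "mean_auc": float(fits.mean()),
            "best_deficit_count": int(best_chrom.sum()),
            "best_chromosome": "".join(map(str, best_chrom.tolist())),
        })
        verdict = check_termination(best_trace, config)
        if verdict != "continue":
            # the recorded best is the elite of the final generation
            i_best = int(np.argmax(best_trace))
            final = Chromosome.from_string(trace[i_best]["best_chromosome"])
            return GARunResult(trace=trace, final_best=final,
                               final_best_fitness=best_trace[i_best],
                               iterations_run=len(trace), converged_by=verdict,
                               seed=config.seed)

        probs = selection_probabilities(fits)
        couples = select_couples(probs, config.n_couples, rng)
        children = np.empty((config.n_couples, n_def), dtype=np.int8)
        for i, (a, c) in enumerate(couples):
            c1, c2 = np.sort(rng.choice(np.arange(1, n_def), size=2, replace=False))
            child = crossover(pop[a], pop[c], int(c1), int(c2))
            children[i] = mutate(child, config.mutation_prob, rng)
        pop = replace(pop, fits, children, config.elite_count)


@dataclass
class MultiRunResult:
    runs: list[GARunResult]
    best: Chromosome
    best_run_index: int
    best_fitness: float


def multi_run(cohort: Cohort, config: GAConfig, n_runs: int = 10,
              strata: StratumSet | None = None) -> MultiRunResult:
    """Repeat the GA ``n_runs`` times with derived seeds and pick the winner.

    Winner: highest final training fitness; ties broken by fewer deficits,
    then by lower run index.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.random.SeedSequence(config.seed).generate_state(n_runs) % (2**31)
    runs = [run_ga(cohort, dataclasses.replace(config, seed=int(s)), strata)
            for s in seeds]
    best_i = min(range(n_runs),
                 key=lambda i: (-runs[i].final_best_fitness,
                                runs[i].final_best.n_included, i))
    return MultiRunResult(runs=runs, best=runs[best_i].final_best,
                          best_run_index=best_i,
                          best_fitness=runs[best_i].final_best_fitness)
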