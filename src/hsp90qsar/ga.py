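"""Genetic-algorithm descriptor-subset selection with PLS cross-validated fitness (GA-PLS).

Each chromosome is a bit vector over the descriptor columns (1 = included).
Fitness is the cross-validated Q² of a PLS model restricted to the included
descriptors, with the component count chosen per subset to maximize the
cross-validated fit (capped at 6 components).  Selection is by tournament,
recombination by uniform crossover, variation by per-gene bit flips; elitism
keeps the best chromosomes, so best-ever fitness is monotone across
generations.  Parsimony is enforced by a hard subset-size cap rather than a
fitness penalty: oversized (and empty) chromosomes score −inf and are never
selected as best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import QSARDataset
from .linear_models import _pls_cv_press_per_component

__all__ = ["Chromosome", "GAConfig", "evolve"]


@dataclass
class Chromosome:
    """A descriptor-inclusion bit vector with its (lazily set) fitness."""

    genes: np.ndarray  # bool, length n_descriptors
    fitness: float | None = None

    def n_selected(self) -> int:
        return int(self.genes.sum())

    def selected_names(self, descriptor_names: list[str]) -> list[str]:
        return [d for d, g in zip(descriptor_names, self.genes) if g]


@dataclass
class GAConfig:
    """GA hyperparameters.  ``fitness_leave_out`` is 1 (LOO) or 3 (leave-3-out)."""

    population_size: int = 50
    n_generations: int = 100
    tournament_size: int = 2
    crossover_rate: float = 0.9
    mutation_rate_per_gene: float | None = None  # default 1/p, resolved at run time
    elitism_count: int = 2
    max_subset_size: int = 10
    fitness_leave_out: int = 1
    max_components: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.mutation_rate_per_gene is not None and not 0 <= self.mutation_rate_per_gene <= 1:
            raise ValueError("mutation_rate_per_gene must be in [0, 1]")
        if self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be < population_size")
        if self.fitness_leave_out < 1:
            raise ValueError("fitness_leave_out must be >= 1")


def evolve(dataset: QSARDataset, config: GAConfig) -> tuple[Chromosome, pd.DataFrame]:
    """Run the generational GA; returns the best-ever chromosome and a history table.

    The dataset should be preprocessed (no constant columns).  The initial
    population switches each gene on with probability min(10/p, 0.5).  With
    ``fitness_leave_out > 1`` the folds are one seeded disjoint partition into
    groups of that size, fixed for the whole run, so the fitness cache
    contract holds: identical gene vectors always yield identical fitness.
    History columns: generation, best_fitness, mean_fitness (mean over
    finite-fitness individuals).
    """
    p = dataset.n_descriptors
    if p == 0:
        raise ValueError("dataset has no descriptor columns")
    X = dataset.values
    y = dataset.activities
    n = dataset.n_compounds
    rng = np.random.default_rng(config.seed)
    mut_rate = config.mutation_rate_per_gene if config.mutation_rate_per_gene is not None else 1.0 / p

    lo = config.fitness_leave_out
    if lo == 1:
        folds = [np.array([i]) for i in range(n)]
    else:
        perm = np.random.default_rng([config.seed, 0]).permutation(n)
        folds = [perm[i : i + lo] for i in range(0, n, lo)]
    tss = float(((y - y.mean()) ** 2).sum())

    cache: dict[bytes, float] = {}

    def fitness(genes: np.ndarray) -> float:
        k = int(genes.sum())
        if k == 0 or k > config.max_subset_size:
            return -np.inf
        key = genes.tobytes()
        if key in cache:
            return cache[key]
        Xsub = X[:, genes]
        a_max = max(1, min(config.max_components, k, n - 2))
        press = _pls_cv_press_per_component(Xsub, y, folds, a_max)
        q2 = float((1 - press / tss).max())  # component count by best cross-validated fit
        cache[key] = q2
        return q2

    def random_genes() -> np.ndarray:
        prob = min(10.0 / p, 0.5)
        g = rng.random(p) < prob
        if not g.any():
            g[rng.integers(p)] = True
        return g

    population = [random_genes() for _ in range(config.population_size)]
    fitnesses = np.array([fitness(g) for g in population])
    best_idx = int(np.argmax(fitnesses))
    best = Chromosome(population[best_idx].copy(), float(fitnesses[best_idx]))
    history: list[tuple[int, float, float]] = []

    def record(gen: int) -> None:
        finite = fitnesses[np.isfinite(fitnesses)]
        mean = float(finite.mean()) if len(finite) else float("-inf")
        history.append((gen, best.fitness, mean))

    record(0)
    for gen in range(1, config.n_generations + 1):
        order = np.argsort(-fitnesses, kind="stable")
        next_pop = [population[i].copy() for i in order[: config.elitism_count]]
        while len(next_pop) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(config.population_size, size=config.tournament_size)
                winner = contenders[int(np.argmax(fitnesses[contenders]))]
                parents.append(population[winner])
            if rng.random() < config.crossover_rate:
                mask = rng.random(p) < 0.5  # uniform crossover
                child = np.where(mask, parents[0], parents[1])
            else:
                child = parents[0].copy()
            flip = rng.random(p) < mut_rate
            child = child ^ flip
            next_pop.append(child)
        population = next_pop
        fitnesses = np.array([fitness(g) for g in population])
        gen_best = int(np.argmax(fitnesses))
        if fitnesses[gen_best] > best.fitness:
            best = Chromosome(population[gen_best].copy(), float(fitnesses[gen_best]))
        record(gen)

    history_frame = pd.DataFrame(history, columns=["generation", "best_fitness", "mean_fitness"])
    return best, history_frame
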