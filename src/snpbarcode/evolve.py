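"""Genetic-algorithm operators and the full hybrid Taguchi-GA search loop.

Both the plain GA and the hybrid variant share the same elitist skeleton:
tournament selection fills a mating pool of the population size, every
sequential pair contributes two offspring to the pool (crossed over with
probability ``p_c`` by a uniform crossover swapping whole (SNP, genotype)
slots, copied through otherwise), every offspring-pool member is mutated
element-wise with probability ``p_m``, and the best M of parents plus
offspring survive.
The hybrid adds ``round(0.5 * M * p_c)`` Taguchi combines on pairs drawn
from the offspring pool before mutation, each contributing one refined
offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Barcode, FitnessEvaluator, random_barcode, repair_duplicates
from .dataset import CohortMatrix
from .taguchi import taguchi_combine

__all__ = [
    "EvolutionConfig",
    "RunResult",
    "tournament_select",
    "uniform_crossover",
    "mutate",
    "replace",
    "run_htga",
    "run_ga",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Search parameters; the study defaults are M=50, T=1000, p_c=0.3, p_m=0.05."""

    population_size: int = 50
    max_iterations: int = 1000
    crossover_rate: float = 0.3
    mutation_rate: float = 0.05
    barcode_order: int = 2
    algorithm: str = "htga"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be non-negative")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.barcode_order < 1:
            raise ValueError("barcode_order must be at least 1")
        if self.algorithm not in ("htga", "ga"):
            raise ValueError("algorithm must be 'htga' or 'ga'")


@dataclass
class RunResult:
    """Outcome of one search run.

    ``history[t]`` is the best fitness after iteration t (index 0 = the
    initial population); elitist replacement makes it non-decreasing.
    """

    best_barcode: Barcode
    best_fitness: int
    history: list[int] = field(default_factory=list)
    evaluations: int = 0
    seed: int = 0


def tournament_select(
    population: list[Barcode], fitnesses: list[int], rng: np.random.Generator
) -> Barcode:
    """Binary tournament: draw two members uniformly (with replacement across
    draws), return the fitter; the first drawn wins ties."""
    if not population:
        raise ValueError("population must not be empty")
    i = int(rng.integers(len(population)))
    j = int(rng.integers(len(population)))
    return population[i] if fitnesses[i] >= fitnesses[j] else population[j]


def uniform_crossover(
    parent1: Barcode, parent2: Barcode, rng: np.random.Generator, n_snps: int
) -> tuple[Barcode, Barcode]:
    """Uniform crossover on paired slots: a drawn bit of 1 swaps slot j's SNP
    index together with its genotype between the offspring; duplicated SNPs
    are repaired as in the Taguchi combine."""
    if parent1.order != parent2.order:
        raise ValueError("parents must have the same barcode order")
    m = parent1.order
    bits = rng.integers(0, 2, size=m)
    s1, g1 = list(parent1.snp_indices), list(parent1.genotype_codes)
    s2, g2 = list(parent2.snp_indices), list(parent2.genotype_codes)
    for j in range(m):
        if bits[j]:
            s1[j], s2[j] = s2[j], s1[j]
            g1[j], g2[j] = g2[j], g1[j]
    return (
        repair_duplicates(s1, g1, n_snps, rng),
        repair_duplicates(s2, g2, n_snps, rng),
    )


def mutate(
    barcode: Barcode, p_m: float, n_snps: int, rng: np.random.Generator
) -> Barcode:
    """Element-wise mutation over all 2m elements, slot by slot.

    For slot j, the SNP-index element mutates first (redrawn uniformly from
    SNPs unused anywhere in the current barcode; kept when none exists),
    then the genotype element (redrawn uniformly from {1, 2, 3}).
    """
    snps = list(barcode.snp_indices)
    genos = list(barcode.genotype_codes)
    for j in range(barcode.order):
        if rng.random() < p_m:
            unused = [s for s in range(1, n_snps + 1) if s not in snps]
            if unused:
                snps[j] = unused[int(rng.integers(len(unused)))]
        if rng.random() < p_m:
            genos[j] = int(rng.integers(1, 4))
    return Barcode(tuple(snps), tuple(genos))


def replace(
    parents: list[Barcode],
    parent_fitnesses: list[int],
    offspring: list[Barcode],
    offspring_fitnesses: list[int],
    M: int,
) -> tuple[list[Barcode], list[int]]:
    """Elitist replacement: the M fittest *distinct* chromosomes survive.

    Equal-fitness ties are broken by the deterministic barcode sort key so
    runs are reproducible irrespective of pool construction order.  Keeping
    the population duplicate-free preserves mid-rank building blocks (a
    barcode sharing one slot with the optimum stays alive even when a
    fitter, unrelated barcode would otherwise fill the population with
    copies of itself) and is what lets the elitist loop escape strong local
    optima.  When fewer than M distinct chromosomes exist, the best
    duplicates pad the population back to size M.
    """
    pool = list(zip(parents + offspring, parent_fitnesses + offspring_fitnesses))
    pool.sort(key=lambda item: (-item[1], item[0].sort_key()))
    seen: set[Barcode] = set()
    survivors: list[tuple[Barcode, int]] = []
    for b, f in pool:
        if b not in seen:
            seen.add(b)
            survivors.append((b, f))
            if len(survivors) == M:
                break
    i = 0
    while len(survivors) < M:
        survivors.append(pool[i])
        i += 1
    return [b for b, _ in survivors], [f for _, f in survivors]


def _run(config: EvolutionConfig, matrix: CohortMatrix, use_taguchi: bool) -> RunResult:
    if config.barcode_order > matrix.n_snps:
        raise ValueError("barcode_order exceeds the number of SNPs in the cohort")
    rng = np.random.default_rng(config.seed)
    evaluator = FitnessEvaluator(matrix)
    M = config.population_size
    n_snps = matrix.n_snps

    population = [
        random_barcode(config.barcode_order, n_snps, rng) for _ in range(M)
    ]
    fitnesses = [evaluator.fitness(b) for b in population]
    population, fitnesses = replace(population, fitnesses, [], [], M)
    history = [fitnesses[0]]

    n_combines = round(0.5 * M * config.crossover_rate)
    for _ in range(config.max_iterations):
        mating_pool = [
            tournament_select(population, fitnesses, rng) for _ in range(M)
        ]
        offspring: list[Barcode] = []
        for i in range(M // 2):
            c1, c2 = mating_pool[2 * i], mating_pool[2 * i + 1]
            if rng.random() < config.crossover_rate:
                c1, c2 = uniform_crossover(c1, c2, rng, n_snps)
            offspring.extend((c1, c2))
        if use_taguchi:
            for _ in range(n_combines):
                source = offspring if len(offspring) >= 2 else mating_pool
                i = int(rng.integers(len(source)))
                j = int(rng.integers(len(source) - 1))
                if j >= i:
                    j += 1
                child = taguchi_combine(
                    source[i], source[j], evaluator.fitness, rng, n_snps
                )
                offspring.append(child)
        offspring = [
            mutate(b, config.mutation_rate, n_snps, rng) for b in offspring
        ]
        offspring_fitnesses = [evaluator.fitness(b) for b in offspring]
        population, fitnesses = replace(
            population, fitnesses, offspring, offspring_fitnesses, M
        )
        history.append(fitnesses[0])

    return RunResult(
        best_barcode=population[0],
        best_fitness=fitnesses[0],
        history=history,
        evaluations=evaluator.evaluations,
        seed=config.seed,
    )


def run_htga(config: EvolutionConfig, matrix: CohortMatrix) -> RunResult:
    """Hybrid Taguchi-GA search (crossover followed by Taguchi refinement)."""
    if config.algorithm != "htga":
        raise ValueError("config.algorithm must be 'htga'")
    return _run(config, matrix, use_taguchi=True)


def run_ga(config: EvolutionConfig, matrix: CohortMatrix) -> RunResult:
    """Plain GA with the same operators and budget, Taguchi step skipped."""
    if config.algorithm != "ga":
        raise ValueError("config.algorithm must be 'ga'")
    return _run(config, matrix, use_taguchi=False)
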