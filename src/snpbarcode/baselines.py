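"""Particle-swarm baselines adapted to the discrete barcode search.

The swarm optimizers used for comparison operate on a continuous position
vector of length 2m per particle: m SNP coordinates in [1, n_snps] followed
by m genotype coordinates in [1, 3].  Positions are decoded to a valid
barcode (round, clamp, repair duplicate SNPs) before every fitness
evaluation.  This discrete encoding is this package's own construction —
the published comparison described no encoding — so the baseline results
characterize *a* PSO on the problem, not any specific prior implementation.

The plain variant uses an inertia weight decreasing linearly from w_max to
w_min; the chaotic variant modulates it with a logistic map
``z_{t+1} = 4 z_t (1 - z_t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Barcode, FitnessEvaluator, repair_duplicates
from .dataset import CohortMatrix
from .evolve import RunResult

__all__ = ["SwarmConfig", "run_pso", "run_cpso", "logistic_map"]

_LOGISTIC_FIXED_POINTS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm parameters; study defaults: 50 particles, 1000 iterations,
    inertia in [0.4, 0.9], learning factors c1 = c2 = 2."""

    population_size: int = 50
    max_iterations: int = 1000
    w_min: float = 0.4
    w_max: float = 0.9
    c1: float = 2.0
    c2: float = 2.0
    barcode_order: int = 2
    seed: int = 0
    variant: str = "pso"

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be at least 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be non-negative")
        if not 0 < self.w_min <= self.w_max:
            raise ValueError("require 0 < w_min <= w_max")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("learning factors must be non-negative")
        if self.barcode_order < 1:
            raise ValueError("barcode_order must be at least 1")
        if self.variant not in ("pso", "cpso"):
            raise ValueError("variant must be 'pso' or 'cpso'")


def logistic_map(z0: float, n: int) -> np.ndarray:
    """First ``n`` values of z_{t+1} = 4 z_t (1 - z_t) starting at z_0."""
    out = np.empty(n)
    z = z0
    for t in range(n):
        out[t] = z
        z = 4.0 * z * (1.0 - z)
    return out


def _decode(
    position: np.ndarray, m: int, n_snps: int, rng: np.random.Generator
) -> Barcode:
    snps = np.clip(np.rint(position[:m]), 1, n_snps).astype(int)
    genos = np.clip(np.rint(position[m:]), 1, 3).astype(int)
    return repair_duplicates(list(snps), list(genos), n_snps, rng)


def _run_swarm(config: SwarmConfig, matrix: CohortMatrix, chaotic: bool) -> RunResult:
    m = config.barcode_order
    n_snps = matrix.n_snps
    if m > n_snps:
        raise ValueError("barcode_order exceeds the number of SNPs in the cohort")
    rng = np.random.default_rng(config.seed)
    evaluator = FitnessEvaluator(matrix)
    N, T = config.population_size, config.max_iterations

    low = np.concatenate([np.ones(m), np.ones(m)])
    high = np.concatenate([np.full(m, n_snps), np.full(m, 3.0)])
    v_max = (high - low) / 2.0

    if chaotic:
        z = rng.uniform(0.0, 1.0)
        while any(abs(z - p) < 1e-12 for p in _LOGISTIC_FIXED_POINTS):
            z = rng.uniform(0.0, 1.0)

    x = rng.uniform(low, high, size=(N, 2 * m))
    v = np.zeros_like(x)
    pbest_x = x.copy()
    pbest_f = np.empty(N)
    gbest_f = -np.inf
    gbest_x = x[0].copy()
    gbest_barcode: Barcode | None = None
    for i in range(N):
        b = _decode(x[i], m, n_snps, rng)
        pbest_f[i] = evaluator.fitness(b)
        if pbest_f[i] > gbest_f:
            gbest_f, gbest_x, gbest_barcode = pbest_f[i], x[i].copy(), b
    history = [int(gbest_f)]

    for t in range(T):
        if chaotic:
            w = config.w_min + (config.w_max - config.w_min) * z
            z = 4.0 * z * (1.0 - z)
        else:
            frac = t / max(T - 1, 1)
            w = config.w_max - (config.w_max - config.w_min) * frac
        r1 = rng.random(size=(N, 2 * m))
        r2 = rng.random(size=(N, 2 * m))
        v = w * v + config.c1 * r1 * (pbest_x - x) + config.c2 * r2 * (gbest_x - x)
        v = np.clip(v, -v_max, v_max)
        x = np.clip(x + v, low, high)
        for i in range(N):
            b = _decode(x[i], m, n_snps, rng)
            f = evaluator.fitness(b)
            if f > pbest_f[i]:
                pbest_f[i], pbest_x[i] = f, x[i].copy()
            if f > gbest_f:
                gbest_f, gbest_x, gbest_barcode = f, x[i].copy(), b
        history.append(int(gbest_f))

    assert gbest_barcode is not None
    return RunResult(
        best_barcode=gbest_barcode,
        best_fitness=int(gbest_f),
        history=history,
        evaluations=evaluator.evaluations,
        seed=config.seed,
    )


def run_pso(config: SwarmConfig, matrix: CohortMatrix) -> RunResult:
    """Global-best PSO with linearly decreasing inertia."""
    if config.variant != "pso":
        raise ValueError("config.variant must be 'pso'")
    return _run_swarm(config, matrix, chaotic=False)


def run_cpso(config: SwarmConfig, matrix: CohortMatrix) -> RunResult:
    """PSO with logistic-map chaotic inertia weight."""
    if config.variant != "cpso":
        raise ValueError("config.variant must be 'cpso'")
    return _run_swarm(config, matrix, chaotic=True)
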