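"""Two-level orthogonal arrays and the Taguchi refinement operator.

The hybrid search inserts a statistical experimental-design step after
crossover: mixtures of two parent barcodes are laid out on a two-level
orthogonal array L_n(2^(n-1)), each run is scored by a signal-to-noise
ratio derived from the fitness, and a predicted-optimal offspring is
composed slot by slot from the level with the larger factor effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import Barcode, repair_duplicates

__all__ = [
    "OrthogonalArray",
    "build_orthogonal_array",
    "snr_value",
    "factor_effects",
    "taguchi_combine",
]


@dataclass(frozen=True)
class OrthogonalArray:
    """L_n(2^(n-1)) design: n = 2^k runs, n-1 columns, levels in {1, 2}."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", np.asarray(self.entries, dtype=np.int8))

    @property
    def n_runs(self) -> int:
        return self.entries.shape[0]

    @property
    def n_cols(self) -> int:
        return self.entries.shape[1]

    def __str__(self) -> str:
        header = "run\t" + "\t".join(str(c + 1) for c in range(self.n_cols))
        rows = [
            f"{i + 1}\t" + "\t".join(str(v) for v in row)
            for i, row in enumerate(self.entries)
        ]
        return "\n".join([header] + rows)


def _bit_reverse(value: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 1) | (value & 1)
        value >>= 1
    return out


def build_orthogonal_array(k: int) -> OrthogonalArray:
    """Standard two-level array with 2^k runs and 2^k - 1 columns.

    Column j corresponds to the non-empty subset of the k run-index bits
    obtained by bit-reversing j; the entry for run i is 1 plus the parity
    of ``popcount(i AND subset)``.  This ordering reproduces the canonical
    Taguchi layout (L4, L8, ...).
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    n = 2 ** k
    runs = np.arange(n)
    columns = []
    for j in range(1, n):
        subset = _bit_reverse(j, k)
        bits = runs & subset
        parity = np.zeros(n, dtype=np.int8)
        for b in range(k):
            parity ^= (bits >> b) & 1
        columns.append(1 + parity)
    return OrthogonalArray(np.stack(columns, axis=1))


def snr_value(y: float) -> float:
    """Sign-preserving square of a fitness value (larger-the-better)."""
    return y * y if y >= 0 else -(y * y)


def factor_effects(
    oa: OrthogonalArray, etas: np.ndarray, Q: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-factor, per-level sums of the SNR over the array's runs.

    Factor f (1..Q) is assigned to column f.  Returns ``(effects,
    best_levels)`` where ``effects[f-1, l-1]`` is the sum of eta over runs
    with factor f at level l, and ``best_levels[f-1]`` is the level with the
    larger effect (ties go to level 1).
    """
    etas = np.asarray(etas, dtype=float)
    if Q > oa.n_cols:
        raise ValueError(f"Q={Q} exceeds the array's {oa.n_cols} columns")
    if etas.shape != (oa.n_runs,):
        raise ValueError(f"expected {oa.n_runs} responses, got {etas.shape}")
    levels = oa.entries[:, :Q]
    effects = np.stack(
        [
            [etas[levels[:, f] == 1].sum(), etas[levels[:, f] == 2].sum()]
            for f in range(Q)
        ]
    )
    best_levels = np.where(effects[:, 0] >= effects[:, 1], 1, 2)
    return effects, best_levels


def _compose(
    parent1: Barcode,
    parent2: Barcode,
    levels: np.ndarray,
    n_snps: int,
    rng: np.random.Generator,
) -> Barcode:
    """Slot-wise mixture: level 1 takes the paired (SNP, genotype) from parent1."""
    snps = [
        parent1.snp_indices[j] if levels[j] == 1 else parent2.snp_indices[j]
        for j in range(parent1.order)
    ]
    genos = [
        parent1.genotype_codes[j] if levels[j] == 1 else parent2.genotype_codes[j]
        for j in range(parent1.order)
    ]
    return repair_duplicates(snps, genos, n_snps, rng)


def taguchi_combine(
    parent1: Barcode,
    parent2: Barcode,
    evaluate: Callable[[Barcode], float],
    rng: np.random.Generator,
    n_snps: int,
) -> Barcode:
    """One refined offspring from two parents via an orthogonal-array experiment.

    Each of the m paired (SNP, genotype) slots is one two-level factor
    (level 1 = parent1's slot, level 2 = parent2's).  The smallest array
    with at least m columns is used; every run's candidate is repaired if
    slot mixing duplicated an SNP, evaluated, and mapped to an SNR.  The
    returned offspring takes each slot from the level with the larger
    factor effect and is itself evaluated, so one combine costs exactly
    ``n_runs + 1`` fitness evaluations.
    """
    if parent1.order != parent2.order:
        raise ValueError("parents must have the same barcode order")
    Q = parent1.order
    k = 1
    while 2 ** k - 1 < Q:
        k += 1
    oa = build_orthogonal_array(k)
    etas = np.empty(oa.n_runs)
    for i in range(oa.n_runs):
        candidate = _compose(parent1, parent2, oa.entries[i], n_snps, rng)
        etas[i] = snr_value(evaluate(candidate))
    _, best_levels = factor_effects(oa, etas, Q)
    child = _compose(parent1, parent2, best_levels, n_snps, rng)
    evaluate(child)
    return child
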