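"""SNP barcodes and their case-control fitness.

An order-m barcode pairs m distinct SNP indices with one fixed genotype
code each; a sample carries the barcode iff it matches all m genotypes.
The search fitness is the number of controls carrying the barcode minus
the number of cases carrying it, so large positive values flag putatively
protective combinations (odds ratio below 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import CohortMatrix

__all__ = [
    "Barcode",
    "ContingencyTable",
    "matches",
    "contingency",
    "fitness",
    "random_barcode",
    "repair_duplicates",
    "FitnessEvaluator",
]


@dataclass(frozen=True)
class Barcode:
    """An order-m SNP barcode: m distinct 1-based SNP indices + genotype codes."""

    snp_indices: tuple[int, ...]
    genotype_codes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_indices", tuple(int(s) for s in self.snp_indices))
        object.__setattr__(
            self, "genotype_codes", tuple(int(g) for g in self.genotype_codes)
        )
        if len(self.snp_indices) != len(self.genotype_codes):
            raise ValueError("snp_indices and genotype_codes must have equal length")
        if not self.snp_indices:
            raise ValueError("barcode order must be at least 1")
        if len(set(self.snp_indices)) != len(self.snp_indices):
            raise ValueError("SNP indices within a barcode must be distinct")
        if any(s < 1 for s in self.snp_indices):
            raise ValueError("SNP indices are 1-based positive integers")
        if any(g not in (1, 2, 3) for g in self.genotype_codes):
            raise ValueError("genotype codes must be in {1, 2, 3}")

    @property
    def order(self) -> int:
        return len(self.snp_indices)

    def sort_key(self) -> tuple:
        """Deterministic tie-break order: (sorted SNP indices, genotype codes)."""
        return (tuple(sorted(self.snp_indices)), self.genotype_codes)

    def to_text(self) -> str:
        snps = ",".join(str(s) for s in self.snp_indices)
        genos = "-".join(str(g) for g in self.genotype_codes)
        return f"snps={snps} genotypes={genos}"

    @classmethod
    def from_text(cls, text: str) -> "Barcode":
        """Parse the report form, e.g. ``snps=1,10,17 genotypes=1-2-1``."""
        fields = dict(
            part.split("=", 1) for part in text.split() if "=" in part
        )
        if "snps" not in fields or "genotypes" not in fields:
            raise ValueError(f"malformed barcode text: {text!r}")
        try:
            snps = tuple(int(s) for s in fields["snps"].split(","))
            genos = tuple(int(g) for g in fields["genotypes"].split("-"))
        except ValueError as exc:
            raise ValueError(f"malformed barcode text: {text!r}") from exc
        return cls(snps, genos)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (cases, controls) x (barcode match, no match).

    tp = cases matching, fp = controls matching, fn = cases not matching,
    tn = controls not matching.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _column_indices(barcode: Barcode, n_snps: int) -> np.ndarray:
    cols = np.asarray(barcode.snp_indices, dtype=np.intp) - 1
    if cols.max() >= n_snps:
        raise IndexError(
            f"barcode SNP index {int(cols.max()) + 1} out of range for {n_snps} SNPs"
        )
    return cols


def matches(sample_genotypes: np.ndarray, barcode: Barcode) -> bool:
    """True iff the sample carries every (SNP, genotype) pair of the barcode."""
    sample = np.asarray(sample_genotypes)
    cols = _column_indices(barcode, sample.shape[0])
    return bool((sample[cols] == np.asarray(barcode.genotype_codes)).all())


def contingency(matrix: CohortMatrix, barcode: Barcode) -> ContingencyTable:
    """Count barcode carriers among cases and controls by exhaustive scan."""
    cols = _column_indices(barcode, matrix.n_snps)
    hit = (matrix.genotypes[:, cols] == np.asarray(barcode.genotype_codes, dtype=np.int8)).all(axis=1)
    tp = int(np.count_nonzero(hit & matrix.labels))
    fp = int(np.count_nonzero(hit & ~matrix.labels))
    return ContingencyTable(tp=tp, fp=fp, fn=matrix.n_cases - tp, tn=matrix.n_controls - fp)


def fitness(matrix: CohortMatrix, barcode: Barcode) -> int:
    """Controls carrying the barcode minus cases carrying it (fp - tp)."""
    table = contingency(matrix, barcode)
    return table.fp - table.tp


def random_barcode(m: int, n_snps: int, rng: np.random.Generator) -> Barcode:
    """Uniform random order-m barcode: SNPs without replacement, genotypes uniform."""
    if not 1 <= m <= n_snps:
        raise ValueError(f"barcode order must satisfy 1 <= m <= {n_snps}, got {m}")
    snps = rng.choice(n_snps, size=m, replace=False) + 1
    genos = rng.integers(1, 4, size=m)
    return Barcode(tuple(snps), tuple(genos))


def repair_duplicates(
    snps: list[int], genos: list[int], n_snps: int, rng: np.random.Generator
) -> Barcode:
    """Resolve duplicate SNP indices created by mixing two parents.

    Scans slots left to right; a slot whose SNP already appeared is replaced
    by a uniform draw from the SNP indices unused anywhere in the barcode,
    keeping the slot's genotype code.
    """
    seen: set[int] = set()
    duplicates: list[int] = []
    for j, s in enumerate(snps):
        if s in seen:
            duplicates.append(j)
        else:
            seen.add(s)
    if duplicates:
        unused = [s for s in range(1, n_snps + 1) if s not in seen]
        for j in duplicates:
            pick = int(rng.integers(len(unused)))
            snps[j] = unused.pop(pick)
    return Barcode(tuple(snps), tuple(genos))


class FitnessEvaluator:
    """Cached fitness oracle over one cohort.

    Precomputes, per (SNP, genotype), the boolean carrier vectors for cases
    and controls so an order-m barcode costs m boolean ANDs per group.  Also
    counts fitness evaluations for search-budget bookkeeping.
    """

    def __init__(self, matrix: CohortMatrix):
        self.matrix = matrix
        self.n_snps = matrix.n_snps
        G = matrix.genotypes
        case, ctrl = matrix.labels, ~matrix.labels
        # shape (n_snps, 3, n_group)
        self._case = np.stack(
            [[G[case, j] == g for g in (1, 2, 3)] for j in range(self.n_snps)]
        )
        self._ctrl = np.stack(
            [[G[ctrl, j] == g for g in (1, 2, 3)] for j in range(self.n_snps)]
        )
        self.evaluations = 0

    def contingency(self, barcode: Barcode) -> ContingencyTable:
        cols = _column_indices(barcode, self.n_snps)
        genos = np.asarray(barcode.genotype_codes) - 1
        tp = int(np.logical_and.reduce(self._case[cols, genos]).sum())
        fp = int(np.logical_and.reduce(self._ctrl[cols, genos]).sum())
        return ContingencyTable(
            tp=tp, fp=fp,
            fn=self.matrix.n_cases - tp, tn=self.matrix.n_controls - fp,
        )

    def fitness(self, barcode: Barcode) -> int:
        self.evaluations += 1
        table = self.contingency(barcode)
        return table.fp - table.tp
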