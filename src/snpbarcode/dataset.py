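"""Case-control genotype cohorts simulated from per-SNP genotype counts.

The study cohort is not distributed as raw genotypes: only the per-SNP,
per-group genotype counts (cases and controls, 5000 each) are published.
This module reconstructs a cohort with *exactly* those marginal counts:
for each SNP and each group the implied multiset of genotype codes is laid
out and assigned to samples by a seeded random permutation.  Columns are
therefore mutually independent by construction, and every single-SNP
association statistic recomputed from the generated matrix equals the one
computed from the source counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SNPDefinition",
    "CohortMatrix",
    "normalize_genotype_counts",
    "builtin_snp_table",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

GENOTYPE_CODES = (1, 2, 3)

CASE_LABEL = "case"
CONTROL_LABEL = "control"


@dataclass(frozen=True)
class SNPDefinition:
    """One SNP: identity plus per-genotype case/control counts.

    ``case_counts[g-1]`` / ``control_counts[g-1]`` give the number of cases /
    controls carrying genotype code ``g`` (1 = homozygous major,
    2 = heterozygous, 3 = homozygous minor).  The counts are the simulation
    marginals for :func:`generate_cohort`.
    """

    index: int
    rsid: str
    gene: str
    genotype_labels: tuple[str, str, str]
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.genotype_labels) != 3:
            raise ValueError("exactly 3 genotype labels required")
        for counts in (self.case_counts, self.control_counts):
            if len(counts) != 3 or any(c < 0 for c in counts):
                raise ValueError("counts must be 3 non-negative integers")

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)


@dataclass
class CohortMatrix:
    """Genotype codes for ``n_samples x n_snps`` plus case/control labels.

    ``genotypes`` holds codes in {1, 2, 3}; column ``j`` corresponds to
    ``snp_defs[j]`` (i.e. SNP index ``j + 1``).  ``labels`` is boolean,
    True for cases.
    """

    genotypes: np.ndarray
    labels: np.ndarray
    snp_defs: list[SNPDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.labels.shape != (self.genotypes.shape[0],):
            raise ValueError("labels length must match the number of samples")
        if self.genotypes.size and not np.isin(self.genotypes, GENOTYPE_CODES).all():
            raise ValueError("genotype codes must be in {1, 2, 3}")
        if self.snp_defs and len(self.snp_defs) != self.genotypes.shape[1]:
            raise ValueError("snp_defs must match the number of columns")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.labels).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortMatrix):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.labels, other.labels)
            and self.snp_defs == other.snp_defs
        )


def normalize_genotype_counts(
    raw_counts: tuple[int, int, int] | list[int], target_total: int
) -> tuple[int, int, int]:
    """Rescale three genotype counts so they sum exactly to ``target_total``.

    Uses largest-remainder (Hamilton) rounding on the exact proportions:
    floor every scaled count, then hand the remaining units to the largest
    fractional remainders, ties going to the lower genotype index.  Each
    returned count is within one unit of its unrounded proportional value.
    """
    raw = [int(c) for c in raw_counts]
    if len(raw) != 3 or any(c < 0 for c in raw):
        raise ValueError("raw_counts must be 3 non-negative integers")
    total = sum(raw)
    if total == 0:
        raise ValueError("cannot normalize an all-zero genotype distribution")
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    # exact integer arithmetic: floor(c * target / total) with remainder c*target % total
    scaled = [c * target_total for c in raw]
    floors = [s // total for s in scaled]
    remainders = [s % total for s in scaled]
    missing = target_total - sum(floors)
    # ties broken by lower genotype index: sort by (-remainder, index)
    order = sorted(range(3), key=lambda i: (-remainders[i], i))
    for i in order[:missing]:
        floors[i] += 1
    return tuple(floors)  # type: ignore[return-value]


def builtin_snp_table() -> list[SNPDefinition]:
    """The packaged 26-SNP growth-factor-gene table (5000 cases / 5000 controls).

    Counts are transcribed verbatim from the published per-genotype
    case/control distribution; every group sums to exactly 5000.
    """
    with resources.files("snpbarcode.data").joinpath("snp_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    defs = []
    for row in df.itertuples(index=False):
        defs.append(
            SNPDefinition(
                index=int(row.index),
                rsid=str(row.rsid),
                gene=str(row.gene),
                genotype_labels=(row.genotype1, row.genotype2, row.genotype3),
                case_counts=(int(row.case1), int(row.case2), int(row.case3)),
                control_counts=(int(row.control1), int(row.control2), int(row.control3)),
            )
        )
    return defs


def _column_codes(counts: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Exact multiset of genotype codes implied by ``counts``, randomly permuted."""
    column = np.repeat(np.array(GENOTYPE_CODES, dtype=np.int8), counts)
    return rng.permutation(column)

def generate_cohort(
    snp_defs: list[SNPDefinition], n_per_group: int = 5000, seed: int = 0
) -> CohortMatrix:
    """Simulate a case-control cohort whose marginals equal the SNP table.

    For each group and each SNP independently, the genotype counts are
    rescaled to ``n_per_group`` via :func:`normalize_genotype_counts`
    (identity when already at that total) and the exact multiset of codes is
    assigned to samples by a seeded permutation.  Child seeds are derived
    deterministically from ``(seed, snp_index, group)`` so columns are
    independent streams and the same seed reproduces the matrix bit for bit.

    Rows 0..n_per_group-1 are cases, the rest controls.
    """
    if not snp_defs:
        raise ValueError("snp_defs must not be empty")
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    genotypes = np.empty((2 * n_per_group, len(snp_defs)), dtype=np.int8)
    for j, snp in enumerate(snp_defs):
        for group, counts in ((0, snp.case_counts), (1, snp.control_counts)):
            scaled = normalize_genotype_counts(counts, n_per_group)
            rng = np.random.default_rng([seed, snp.index, group])
            rows = slice(0, n_per_group) if group == 0 else slice(n_per_group, None)
            genotypes[rows, j] = _column_codes(scaled, rng)
    labels = np.zeros(2 * n_per_group, dtype=bool)
    labels[:n_per_group] = True
    return CohortMatrix(genotypes=genotypes, labels=labels, snp_defs=list(snp_defs))


def write_cohort(matrix: CohortMatrix, path: str | Path) -> None:
    """Write a cohort as CSV: ``sample_id,label,<rsid_1>,...``."""
    if matrix.snp_defs:
        columns = [d.rsid for d in matrix.snp_defs]
    else:
        columns = [f"SNP{j + 1}" for j in range(matrix.n_snps)]
    df = pd.DataFrame(matrix.genotypes, columns=columns)
    df.insert(0, "label", np.where(matrix.labels, CASE_LABEL, CONTROL_LABEL))
    df.insert(0, "sample_id", [f"S{i + 1}" for i in range(matrix.n_samples)])
    df.to_csv(path, index=False)


def read_cohort(
    path: str | Path, snp_defs: list[SNPDefinition] | None = None
) -> CohortMatrix:
    """Read a cohort CSV written by :func:`write_cohort`.

    ``snp_defs``, when given, is attached after checking that the file's
    genotype columns match the table's rsIDs in order.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty cohort file") from exc
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    geno_cols = [c for c in df.columns if c not in ("sample_id", "label")]
    if not geno_cols:
        raise ValueError(f"{path}: no genotype columns")
    bad_label = ~df["label"].isin([CASE_LABEL, CONTROL_LABEL])
    if bad_label.any():
        row = int(np.flatnonzero(bad_label.to_numpy())[0])
        raise ValueError(
            f"{path}: row {row + 1}: label must be '{CASE_LABEL}' or '{CONTROL_LABEL}'"
        )
    genotypes = np.empty((len(df), len(geno_cols)), dtype=np.int8)
    for j, col in enumerate(geno_cols):
        values = pd.to_numeric(df[col], errors="coerce")
        valid = values.isin(GENOTYPE_CODES)
        if not valid.all():
            row = int(np.flatnonzero(~valid.to_numpy())[0])
            raise ValueError(
                f"{path}: row {row + 1}, column '{col}': "
                f"genotype code must be 1, 2 or 3 (got {df[col].iloc[row]!r})"
            )
        genotypes[:, j] = values.to_numpy(dtype=np.int8)
    if snp_defs is not None:
        expected = [d.rsid for d in snp_defs]
        if expected != geno_cols:
            raise ValueError(f"{path}: genotype columns do not match the SNP table")
    return CohortMatrix(
        genotypes=genotypes,
        labels=(df["label"] == CASE_LABEL).to_numpy(),
        snp_defs=list(snp_defs) if snp_defs is not None else [],
    )
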