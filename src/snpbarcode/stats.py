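"""Association statistics for SNP barcodes and the exhaustive-search oracle.

The 2x2 table splits the cohort by case/control status and barcode
carriage.  The odds ratio is (TP x TN) / (FP x FN); its 95% interval uses
the Woolf log-odds method, and the p-value is a Pearson chi-square test
without continuity correction (the method pair that reproduces the
published single-SNP and barcode statistics).  A zero cell or margin makes
the statistic undefined and is reported as missing rather than corrected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.stats import chi2, norm

from .core import Barcode, ContingencyTable, FitnessEvaluator
from .dataset import CohortMatrix, SNPDefinition

__all__ = [
    "UndefinedStatistic",
    "AssociationResult",
    "odds_ratio",
    "single_snp_odds_ratio",
    "confidence_interval",
    "p_value",
    "associate",
    "exhaustive_search",
    "report",
]


class UndefinedStatistic(ValueError):
    """Raised when a zero cell or margin leaves a statistic undefined."""


@dataclass(frozen=True)
class AssociationResult:
    """One report row: a barcode (or single-SNP genotype) and its statistics.

    Statistics that are undefined for the table (zero cells) are None and
    rendered as N/A.  ``difference`` is controls matching minus cases
    matching (fp - tp), the search fitness.
    """

    label: str
    contingency: ContingencyTable
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p: float | None
    barcode: Barcode | None = None

    @property
    def difference(self) -> int:
        return self.contingency.fp - self.contingency.tp


def odds_ratio(table: ContingencyTable) -> float:
    """(TP x TN) / (FP x FN), exact rational arithmetic then floated."""
    if table.fp == 0 or table.fn == 0:
        raise UndefinedStatistic("odds ratio undefined: zero denominator cell")
    return float(Fraction(table.tp * table.tn, table.fp * table.fn))


def single_snp_odds_ratio(snp: SNPDefinition, genotype: int) -> AssociationResult:
    """Association of one genotype (2 or 3) against the genotype-1 reference.

    The table pits (cases, controls) carrying the target genotype against
    those carrying the reference, so OR = (case_g x control_1) / (control_g x case_1).
    """
    if genotype not in (2, 3):
        raise ValueError("genotype must be 2 or 3 (1 is the reference)")
    g = genotype - 1
    table = ContingencyTable(
        tp=snp.case_counts[g],
        fp=snp.control_counts[g],
        fn=snp.case_counts[0],
        tn=snp.control_counts[0],
    )
    return _result(f"{snp.index}. {snp.rsid} {genotype}-{snp.genotype_labels[g]}", table)


def confidence_interval(
    table: ContingencyTable, level: float = 0.95
) -> tuple[float, float]:
    """Woolf log-odds interval: exp(ln OR +/- z * sqrt(sum of 1/cell))."""
    if min(table.tp, table.fp, table.fn, table.tn) == 0:
        raise UndefinedStatistic("confidence interval undefined: zero cell")
    log_or = np.log(odds_ratio(table))
    se = np.sqrt(1 / table.tp + 1 / table.fp + 1 / table.fn + 1 / table.tn)
    z = norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def p_value(table: ContingencyTable) -> float:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table."""
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    margins = ((tp + fp), (fn + tn), (tp + fn), (fp + tn))
    if min(margins) == 0:
        raise UndefinedStatistic("p-value undefined: zero margin")
    n = table.total
    stat = n * (tp * tn - fp * fn) ** 2 / (
        margins[0] * margins[1] * margins[2] * margins[3]
    )
    return float(chi2.sf(stat, df=1))


def _result(label: str, table: ContingencyTable, barcode: Barcode | None = None) -> AssociationResult:
    try:
        or_ = odds_ratio(table)
        lo, hi = confidence_interval(table)
        p = p_value(table)
    except UndefinedStatistic:
        or_ = lo = hi = p = None
    return AssociationResult(
        label=label, contingency=table,
        odds_ratio=or_, ci_low=lo, ci_high=hi, p=p, barcode=barcode,
    )


def associate(matrix: CohortMatrix, barcode: Barcode, label: str | None = None) -> AssociationResult:
    """Full association row for a barcode against a cohort."""
    from .core import contingency

    table = contingency(matrix, barcode)
    return _result(label or barcode.to_text(), table, barcode=barcode)


def exhaustive_search(
    matrix: CohortMatrix, m: int, max_candidates: int = 10 ** 6
) -> list[Barcode]:
    """Enumerate every order-m barcode and return all fitness maximizers.

    The candidate count is C(n_snps, m) x 3^m; the call refuses budgets
    above ``max_candidates``.  Maximizers come back in the deterministic
    barcode sort order, so the first element is the canonical optimum.
    """
    n_snps = matrix.n_snps
    if not 1 <= m <= n_snps:
        raise ValueError(f"order must satisfy 1 <= m <= {n_snps}")
    n_candidates = 3 ** m
    for i in range(m):
        n_candidates = n_candidates * (n_snps - i) // (i + 1)
    if n_candidates > max_candidates:
        raise ValueError(
            f"exhaustive search over {n_candidates} candidates exceeds the "
            f"budget of {max_candidates}"
        )
    evaluator = FitnessEvaluator(matrix)
    best_fitness: int | None = None
    best: list[Barcode] = []
    for snps in itertools.combinations(range(1, n_snps + 1), m):
        for genos in itertools.product((1, 2, 3), repeat=m):
            b = Barcode(snps, genos)
            f = evaluator.fitness(b)
            if best_fitness is None or f > best_fitness:
                best_fitness, best = f, [b]
            elif f == best_fitness:
                best.append(b)
    best.sort(key=lambda b: b.sort_key())
    return best


def _fmt_p(p: float) -> str:
    return "<.001" if p < 0.0005 else f"{p:.3f}"


_REPORT_COLUMNS = (
    "label",
    "combined_snp",
    "snp_genotypes",
    "control_number",
    "case_number",
    "difference",
    "OR",
    "CI95",
    "p_value",
)


def report(results: list[AssociationResult], path: str | Path) -> None:
    """Write association rows as TSV, one complementary 'Other' row per result.

    Numeric formatting is fixed: OR to 3 decimals, CI bounds to 2,
    p to 3 (``<.001`` below); undefined statistics print N/A.
    """
    lines = ["\t".join(_REPORT_COLUMNS)]
    for res in results:
        t = res.contingency
        if res.barcode is not None:
            combined = ",".join(str(s) for s in res.barcode.snp_indices)
            genos = "-".join(str(g) for g in res.barcode.genotype_codes)
        else:
            combined = genos = "N/A"
        or_ = f"{res.odds_ratio:.3f}" if res.odds_ratio is not None else "N/A"
        ci = (
            f"{res.ci_low:.2f}-{res.ci_high:.2f}"
            if res.ci_low is not None
            else "N/A"
        )
        p = _fmt_p(res.p) if res.p is not None else "N/A"
        lines.append(
            "\t".join(
                (
                    res.label, combined, genos,
                    str(t.fp), str(t.tp), str(res.difference), or_, ci, p,
                )
            )
        )
        lines.append(
            "\t".join(
                (
                    "Other", "N/A", "N/A",
                    str(t.tn), str(t.fn), "N/A", "N/A", "N/A", "N/A",
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
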