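"""Genotype-phenotype contingency analyses.

Two families of tests:

* truncating / nontruncating x phenotype — a 7x2 count table (a unit with
  k phenotypes contributes k cell increments), Pearson chi-square without
  continuity correction, then pairwise post hoc 2x2 chi-square tests for
  each of the C(7, 2) = 21 phenotype pairs at the Bonferroni-corrected
  level alpha / 21;
* domain distribution — phenotype counts of coding variants falling in the
  structural alpha (codons 156-204) vs beta (63-143) domains, and in the
  HIF-alpha vs Elongin B/C binding sites (codon 79 belongs to both and is
  counted in both columns); variants in neither region are tallied
  separately.

Multi-phenotype units contribute to multiple rows; the resulting
non-independence between rows is a property of the design and is carried
into reports rather than corrected for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import AnalysisUnit
from .datamodel import (
    ANALYSIS_PHENOTYPES,
    Phenotype,
    ValidationError,
    VariantGroup,
    annotate_domains,
)

__all__ = [
    "PairResult",
    "ContingencyResult",
    "build_group_table",
    "chi2_test",
    "posthoc_pairwise",
    "group_association",
    "domain_tables",
    "domain_tests",
    "bonferroni_alpha",
    "pair_count",
]


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise corrected significance level alpha / m."""
    if m < 1:
        raise ValidationError("number of tests must be >= 1")
    return alpha / m


def pair_count(k: int) -> int:
    """Number of unordered pairs among k categories, k(k-1)/2."""
    return comb(k, 2)


@dataclass
class PairResult:
    pair: tuple[str, str]
    chi2: float | None
    p: float | None
    significant: bool
    tested: bool = True


@dataclass
class ContingencyResult:
    table: pd.DataFrame
    chi2: float
    df: int
    p: float
    expected: pd.DataFrame
    posthoc: list[PairResult] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def corrected_alpha(self) -> float:
        return bonferroni_alpha(self.alpha, pair_count(len(self.table)))


def build_group_table(
    units: Sequence[AnalysisUnit],
    phenotypes: Sequence[Phenotype] | None = None,
) -> pd.DataFrame:
    """Phenotype x {truncating, nontruncating} count table.

    Units whose variant group is ``excluded`` (synonymous/UTR/intronic/
    unknown) do not contribute.
    """
    if phenotypes is None:
        phenotypes = ANALYSIS_PHENOTYPES
    cols = [VariantGroup.TRUNCATING.value, VariantGroup.NONTRUNCATING.value]
    table = pd.DataFrame(0, index=[p.value for p in phenotypes], columns=cols)
    n = 0
    for u in units:
        grp = u.group
        if grp is VariantGroup.EXCLUDED:
            continue
        n += 1
        for p in phenotypes:
            if p in u.phenotypes:
                table.loc[p.value, grp.value] += 1
    if n == 0:
        raise ValidationError("empty table: no units in the truncating/nontruncating grouping")
    return table


def chi2_test(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns (chi2, df, p) with df = (rows - 1)(cols - 1).  A zero marginal
    raises a :class:`ValidationError` naming the offending row or column.
    """
    frame = pd.DataFrame(table)
    values = frame.to_numpy(dtype=float)
    row_sums = values.sum(axis=1)
    col_sums = values.sum(axis=0)
    for label, total in zip(frame.index, row_sums):
        if total == 0:
            raise ValidationError(f"zero marginal in row {label!r}")
    for label, total in zip(frame.columns, col_sums):
        if total == 0:
            raise ValidationError(f"zero marginal in column {label!r}")
    chi2, p, df, _ = chi2_contingency(values, correction=False)
    return float(chi2), int(df), float(p)


def _expected(table: pd.DataFrame) -> pd.DataFrame:
    values = table.to_numpy(dtype=float)
    exp = np.outer(values.sum(axis=1), values.sum(axis=0)) / values.sum()
    return pd.DataFrame(exp, index=table.index, columns=table.columns)


def posthoc_pairwise(table: pd.DataFrame, alpha: float = 0.05) -> list[PairResult]:
    """2x2 chi-square for every pair of rows, Bonferroni-corrected.

    Significance level is alpha / C(k, 2).  Pairs with a degenerate 2x2
    (zero marginal) are reported untested.
    """
    rows = list(table.index)
    if len(rows) < 2:
        raise ValidationError("post hoc requires at least two phenotype rows")
    corrected = bonferroni_alpha(alpha, pair_count(len(rows)))
    results: list[PairResult] = []
    for a, b in combinations(rows, 2):
        sub = table.loc[[a, b]]
        try:
            chi2, _, p = chi2_test(sub)
        except ValidationError:
            results.append(PairResult((a, b), None, None, False, tested=False))
            continue
        results.append(PairResult((a, b), chi2, p, p <= corrected))
    return results


def group_association(
    units: Sequence[AnalysisUnit],
    phenotypes: Sequence[Phenotype] | None = None,
    alpha: float = 0.05,
) -> ContingencyResult:
    """Truncating/nontruncating x phenotype chi-square with post hoc grid."""
    table = build_group_table(units, phenotypes)
    chi2, df, p = chi2_test(table)
    return ContingencyResult(
        table=table,
        chi2=chi2,
        df=df,
        p=p,
        expected=_expected(table),
        posthoc=posthoc_pairwise(table, alpha),
        alpha=alpha,
    )


def domain_tables(
    units: Sequence[AnalysisUnit],
    phenotypes: Sequence[Phenotype] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-phenotype counts in structural and functional regions.

    Returns (structural, functional, outside): structural columns are the
    alpha and beta domains (disjoint); functional columns are the HIF-alpha
    and Elongin sites, with the shared codon 79 counted in both; ``outside``
    tallies phenotype occurrences of coding variants in neither structural
    domain.  Only variants with a codon present contribute.
    """
    if phenotypes is None:
        phenotypes = ANALYSIS_PHENOTYPES
    names = [p.value for p in phenotypes]
    structural = pd.DataFrame(0, index=names, columns=["alpha", "beta"])
    functional = pd.DataFrame(0, index=names, columns=["hif", "elongin"])
    outside = pd.Series(0, index=names, name="outside_structural")
    for u in units:
        v = u.variant
        if v is None or v.codon is None:
            continue
        flags = annotate_domains(v.codon)
        for p in phenotypes:
            if p not in u.phenotypes:
                continue
            if flags.in_alpha:
                structural.loc[p.value, "alpha"] += 1
            elif flags.in_beta:
                structural.loc[p.value, "beta"] += 1
            else:
                outside[p.value] += 1
            if flags.in_hif:
                functional.loc[p.value, "hif"] += 1
            if flags.in_elongin:
                functional.loc[p.value, "elongin"] += 1
    return structural, functional, outside


def domain_tests(
    units: Sequence[AnalysisUnit],
    phenotypes: Sequence[Phenotype] | None = None,
    alpha: float = 0.05,
) -> tuple[ContingencyResult, ContingencyResult, pd.Series]:
    """Chi-square + post hoc for the structural and functional domain tables."""
    structural, functional, outside = domain_tables(units, phenotypes)
    results = []
    for table in (structural, functional):
        chi2, df, p = chi2_test(table)
        results.append(
            ContingencyResult(
                table=table,
                chi2=chi2,
                df=df,
                p=p,
                expected=_expected(table),
                posthoc=posthoc_pairwise(table, alpha),
                alpha=alpha,
            )
        )
    return results[0], results[1], outside
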