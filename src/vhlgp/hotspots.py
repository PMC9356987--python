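"""Missense recurrence (hotspot) testing along the 213 VHL codons.

Under the null every missense observation is equally likely to hit any of
the 213 codons.  For each codon c with observed count k out of n_total
missense observations, the one-tailed p-value is the exact binomial tail

    p_raw[c] = P(X >= k),  X ~ Binomial(n_total, 1/213)

with Bonferroni correction over the m = 213 tests (significant iff
p <= alpha / 213); "highly significant" marks p-values four orders of
magnitude below the adjusted level, p <= (alpha / 213) * 1e-4.

The BLOSUM90-adjusted variant weights each observation by its substitution
radicality before tallying:

    w(ref, alt) = (b(ref, ref) - b(ref, alt)) / W_bar

where b is the BLOSUM90 entry and W_bar is the mean of b(r, r) - b(r, a)
over all 380 ordered non-identical amino-acid pairs, so the cohort-average
weight is ~1 and cumulative scores stay commensurate with counts.  Because
adjusted scores are non-integer, the binomial tail is extended continuously
through the regularized incomplete gamma function (the continuous Poisson
tail with rate s_total / 213); on integer scores this agrees with the
Poisson tail sum term-for-term.  The weight function is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort import AnalysisUnit
from .datamodel import N_CODONS, ValidationError, VariantType

__all__ = [
    "HotspotTable",
    "codon_counts",
    "binomial_hotspot_test",
    "blosum90_matrix",
    "radicality_weight",
    "blosum_adjust",
    "blosum_hotspot_test",
    "hotspot_analysis",
]

_STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"


def blosum90_matrix():
    """The BLOSUM90 substitution matrix (via Biopython's bundled copy)."""
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM90")


def radicality_weight(ref: str, alt: str, matrix) -> float:
    """Unnormalized substitution radicality, b(ref, ref) - b(ref, alt).

    Conservative substitutions (small diagonal-to-offdiagonal drop) receive
    small weights; radical ones large weights.  Always >= 0 for standard
    substitution matrices.
    """
    return float(matrix[ref, ref] - matrix[ref, alt])


def _mean_weight(matrix, weight_fn: Callable[[str, str, object], float]) -> float:
    total = 0.0
    count = 0
    for r in _STANDARD_AA:
        for a in _STANDARD_AA:
            if r == a:
                continue
            total += weight_fn(r, a, matrix)
            count += 1
    return total / count  # 380 ordered non-identical pairs


@dataclass
class HotspotTable:
    """Per-codon recurrence test results (codons 1..213)."""

    counts: np.ndarray  # integer missense tallies, length 213
    p_raw: np.ndarray
    n_total: int
    alpha: float
    m: int = N_CODONS
    scores: np.ndarray | None = None  # BLOSUM-adjusted cumulative scores
    p_blosum: np.ndarray | None = None
    s_total: float | None = None

    @property
    def adjusted_alpha(self) -> float:
        return self.alpha / self.m

    @property
    def significant(self) -> np.ndarray:
        return self.p_raw <= self.adjusted_alpha

    @property
    def highly_significant(self) -> np.ndarray:
        return self.p_raw <= self.adjusted_alpha * 1e-4

    @property
    def significant_blosum(self) -> np.ndarray | None:
        if self.p_blosum is None:
            return None
        return self.p_blosum <= self.adjusted_alpha

    def significant_codons(self) -> list[int]:
        return [int(c) + 1 for c in np.flatnonzero(self.significant)]

    def to_frame(self) -> pd.DataFrame:
        data = {
            "codon": np.arange(1, N_CODONS + 1),
            "count": self.counts,
            "p_raw": self.p_raw,
            "significant": self.significant,
            "highly_significant": self.highly_significant,
        }
        if self.scores is not None:
            data["blosum_score"] = self.scores
            data["p_blosum"] = self.p_blosum
            data["significant_blosum"] = self.significant_blosum
        return pd.DataFrame(data)


def codon_counts(units: Sequence[AnalysisUnit]) -> tuple[np.ndarray, int]:
    """Tally missense observations per codon.

    Only ``variant_type == missense`` with a codon present contributes; all
    other variant types are ignored.  Returns (counts[213], n_total).
    """
    counts = np.zeros(N_CODONS, dtype=int)
    for u in units:
        v = u.variant
        if v is not None and v.variant_type is VariantType.MISSENSE and v.codon:
            counts[v.codon - 1] += 1
    return counts, int(counts.sum())


def binomial_hotspot_test(
    counts: np.ndarray,
    n_total: int | None = None,
    alpha: float = 0.05,
) -> HotspotTable:
    """Exact one-tailed binomial test per codon against the uniform null."""
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (N_CODONS,):
        raise ValidationError(f"counts must have length {N_CODONS}")
    if n_total is None:
        n_total = int(counts.sum())
    if n_total < 1:
        raise ValidationError("no missense observations; empty result")
    # P(X >= k) = sf(k - 1); k = 0 gives exactly 1
    p_raw = stats.binom.sf(counts - 1, n_total, 1.0 / N_CODONS)
    return HotspotTable(counts=counts, p_raw=p_raw, n_total=n_total, alpha=alpha)


def blosum_adjust(
    observations: Iterable[tuple[int, str, str]],
    matrix=None,
    weight_fn: Callable[[str, str, object], float] = radicality_weight,
) -> tuple[np.ndarray, float]:
    """Accumulate mean-normalized substitution-radicality scores per codon.

    ``observations`` are (codon, ref_aa, alt_aa) triples for missense
    observations only; stop-gain targets are rejected.  Returns
    (scores[213], s_total).
    """
    if matrix is None:
        matrix = blosum90_matrix()
    w_bar = _mean_weight(matrix, weight_fn)
    scores = np.zeros(N_CODONS, dtype=float)
    for codon, ref, alt in observations:
        if alt == "*" or ref == "*":
            raise ValidationError(
                f"stop-involving observation at codon {codon} is not missense"
            )
        if not 1 <= codon <= N_CODONS:
            raise ValidationError(f"codon {codon} outside 1..{N_CODONS}")
        scores[codon - 1] += weight_fn(ref, alt, matrix) / w_bar
    return scores, float(scores.sum())


def blosum_hotspot_test(
    scores: np.ndarray,
    s_total: float | None = None,
    alpha: float = 0.05,
) -> np.ndarray:
    """Continuous one-tailed tail probabilities for non-integer scores.

    With rate lam = s_total / 213, the tail P(X >= s) of a Poisson variable
    extends to real s > 0 as the regularized incomplete gamma function
    ``gammainc(s, lam)`` (s = 0 gives 1).  Strictly decreasing in the score
    at fixed rate, and equal to the Poisson tail sum at integer scores.
    """
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0):
        raise ValidationError("negative BLOSUM-adjusted scores")
    if s_total is None:
        s_total = float(scores.sum())
    if s_total <= 0:
        raise ValidationError("total adjusted score must be positive")
    lam = s_total / N_CODONS
    p = np.ones_like(scores)
    positive = scores > 0
    p[positive] = special.gammainc(scores[positive], lam)
    return p


def hotspot_analysis(
    units: Sequence[AnalysisUnit],
    alpha: float = 0.05,
    matrix=None,
    weight_fn: Callable[[str, str, object], float] = radicality_weight,
) -> HotspotTable:
    """Run the raw and BLOSUM90-adjusted hotspot tests on one analysis view."""
    counts, n_total = codon_counts(units)
    table = binomial_hotspot_test(counts, n_total, alpha=alpha)
    observations = [
        (u.variant.codon, u.variant.ref_aa, u.variant.alt_aa)
        for u in units
        if u.variant is not None
        and u.variant.variant_type is VariantType.MISSENSE
        and u.variant.codon
    ]
    scores, s_total = blosum_adjust(observations, matrix=matrix, weight_fn=weight_fn)
    table.scores = scores
    table.s_total = s_total
    table.p_blosum = blosum_hotspot_test(scores, s_total, alpha=alpha)
    return table
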