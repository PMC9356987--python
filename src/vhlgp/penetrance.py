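"""Age-related penetrance from isolated-phenotype patients.

The cohort records only one onset age per patient (the age at the first
VHL manifestation), so per-phenotype onset distributions are estimated
from patients with exactly one phenotype: for those patients the recorded
onset age is unambiguously the onset of that phenotype.  Each phenotype's
onset-age empirical CDF is the penetrance curve among affected,
isolated-phenotype patients (no censoring model: every included patient is
affected by construction).

All phenotype pairs are then compared with two-sided two-sample
Kolmogorov-Smirnov tests at the Bonferroni-corrected level alpha / m,
m = k(k-1)/2 for k phenotypes.  Exact p-values are used when
n1 * n2 <= 10,000, the asymptotic distribution otherwise; D is computed on
the pooled step functions, so integer-year ties are handled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .cohort import AnalysisUnit
from .datamodel import Phenotype, ValidationError
from .gp_assoc import bonferroni_alpha, pair_count

__all__ = [
    "PenetranceCurves",
    "KSGrid",
    "isolated_onset_ages",
    "penetrance_curves",
    "ecdf",
    "median_onset",
    "pairwise_ks",
    "EXACT_KS_LIMIT",
    "DEFAULT_MIN_N",
]

#: Exact two-sample KS p-values when n1 * n2 is at most this.
EXACT_KS_LIMIT = 10_000
#: Phenotypes with fewer isolated-onset observations are dropped.
DEFAULT_MIN_N = 5


def isolated_onset_ages(
    patients: Sequence[AnalysisUnit],
    min_n: int = DEFAULT_MIN_N,
) -> tuple[dict[Phenotype, np.ndarray], dict[Phenotype, int]]:
    """Onset ages per phenotype from single-phenotype patients.

    A patient contributes iff it carries exactly one phenotype and has an
    onset age (pairwise deletion for the missing ones).  Phenotypes with
    fewer than ``min_n`` observations are dropped with a warning; the
    dropped map reports their counts.
    """
    ages: dict[Phenotype, list[float]] = {}
    for u in patients:
        if len(u.phenotypes) != 1 or u.age_onset is None:
            continue
        (phen,) = u.phenotypes
        ages.setdefault(phen, []).append(float(u.age_onset))
    kept: dict[Phenotype, np.ndarray] = {}
    dropped: dict[Phenotype, int] = {}
    for phen, values in ages.items():
        if len(values) < min_n:
            dropped[phen] = len(values)
        else:
            kept[phen] = np.sort(np.asarray(values))
    if dropped:
        warnings.warn(
            "phenotypes dropped from penetrance (too few isolated patients): "
            + ", ".join(f"{p.value} (n={n})" for p, n in dropped.items()),
            stacklevel=2,
        )
    return kept, dropped


def ecdf(ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: unique ages and cumulative fractions."""
    ages = np.sort(np.asarray(ages, dtype=float))
    if ages.size == 0:
        raise ValidationError("empty sample for ECDF")
    x, counts = np.unique(ages, return_counts=True)
    return x, np.cumsum(counts) / ages.size


def median_onset(ages: np.ndarray) -> float:
    """Age at which the onset ECDF first reaches 0.5."""
    x, f = ecdf(ages)
    return float(x[np.searchsorted(f, 0.5)])


@dataclass
class PenetranceCurves:
    ages: dict[Phenotype, np.ndarray]
    min_n: int
    dropped: dict[Phenotype, int] = field(default_factory=dict)

    @property
    def n(self) -> dict[Phenotype, int]:
        return {p: int(a.size) for p, a in self.ages.items()}

    def median_ages(self) -> dict[Phenotype, float]:
        return {p: median_onset(a) for p, a in self.ages.items()}

    def curve_frame(self) -> pd.DataFrame:
        rows = []
        for p, a in self.ages.items():
            x, f = ecdf(a)
            rows.extend(
                {"phenotype": p.value, "age": xi, "cdf": fi} for xi, fi in zip(x, f)
            )
        return pd.DataFrame(rows)


def penetrance_curves(
    patients: Sequence[AnalysisUnit],
    min_n: int = DEFAULT_MIN_N,
) -> PenetranceCurves:
    ages, dropped = isolated_onset_ages(patients, min_n=min_n)
    return PenetranceCurves(ages=ages, min_n=min_n, dropped=dropped)


@dataclass
class KSGrid:
    phenotypes: list[str]
    d: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    m: int
    alpha: float
    untested: list[tuple[str, str]] = field(default_factory=list)

    @property
    def corrected_alpha(self) -> float:
        return bonferroni_alpha(self.alpha, self.m)


def pairwise_ks(
    age_map: Mapping[Phenotype, np.ndarray],
    alpha: float = 0.05,
    exact_limit: int = EXACT_KS_LIMIT,
) -> KSGrid:
    """All-pairs two-sided two-sample KS tests with Bonferroni correction.

    m = k(k-1)/2 comparisons for k phenotypes; significance at alpha / m.
    Pairs where either sample has fewer than 2 observations are reported
    untested.
    """
    phens = list(age_map)
    if len(phens) < 2:
        raise ValidationError("pairwise KS requires at least two phenotypes")
    names = [p.value if isinstance(p, Phenotype) else str(p) for p in phens]
    m = pair_count(len(phens))
    corrected = bonferroni_alpha(alpha, m)
    d = pd.DataFrame(np.nan, index=names, columns=names)
    p = pd.DataFrame(np.nan, index=names, columns=names)
    sig = pd.DataFrame(False, index=names, columns=names)
    np.fill_diagonal(d.values, 0.0)
    np.fill_diagonal(p.values, 1.0)
    untested: list[tuple[str, str]] = []
    for (pa, na), (pb, nb) in combinations(zip(phens, names), 2):
        xa, xb = np.asarray(age_map[pa]), np.asarray(age_map[pb])
        if xa.size < 2 or xb.size < 2:
            untested.append((na, nb))
            continue
        method = "exact" if xa.size * xb.size <= exact_limit else "asymp"
        res = ks_2samp(xa, xb, alternative="two-sided", method=method)
        d.loc[na, nb] = d.loc[nb, na] = float(res.statistic)
        p.loc[na, nb] = p.loc[nb, na] = float(res.pvalue)
        flag = res.pvalue <= corrected
        sig.loc[na, nb] = sig.loc[nb, na] = bool(flag)
    return KSGrid(
        phenotypes=names, d=d, p=p, significant=sig, m=m, alpha=alpha,
        untested=untested,
    )


def plot_curves(curves: PenetranceCurves, path=None):  # pragma: no cover - optional
    """Step-plot of the onset ECDFs (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for phen, a in curves.ages.items():
        x, f = ecdf(a)
        ax.step(x, f, where="post", label=f"{phen.value} (n={a.size})")
    ax.axhline(0.5, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("age of onset (years)")
    ax.set_ylabel("cumulative fraction of patients")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
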