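"""Pairwise phenotype co-occurrence ratios.

For phenotypes *a*, *b* with raw pair counts ``C[a, b]`` (units carrying
both; ``C[a, a]`` is the count of *a*), the conditional ratio is

    r[a, b] = C[a, b] / C[a, a]

i.e. the fraction of *a*-carrying units that also carry *b*.  Each row of
``r`` (diagonal excluded) is then min-max scaled to [0, 1] "per
manifestation", and the scaled values are banded:

    low (0, 0.33], moderate (0.33, 0.66], high (0.66, 1]

A constant row cannot be scaled; it is set to 0 and flagged degenerate.
The raw and conditional matrices are always emitted alongside the scaled
one so alternative scalings can be audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import AnalysisUnit
from .datamodel import ANALYSIS_PHENOTYPES, Phenotype, ValidationError

__all__ = ["CooccurrenceMatrix", "cooccurrence", "BANDS"]

#: Band edges on the scaled ratio: (label, inclusive upper bound).
BANDS = (("low", 0.33), ("moderate", 0.66), ("high", 1.0))


def band_of(value: float) -> str:
    for label, upper in BANDS:
        if value <= upper + 1e-12:
            return label
    return "high"


@dataclass
class CooccurrenceMatrix:
    phenotypes: list[str]
    counts: pd.DataFrame  # symmetric raw pair counts, diagonal = marginals
    conditional: pd.DataFrame  # r[a, b] = C[a, b] / C[a, a]
    scaled: pd.DataFrame  # per-row min-max of r over b != a, diagonal NaN
    bands: pd.DataFrame  # band labels from the scaled matrix
    degenerate_rows: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def cooccurrence(
    units: Sequence[AnalysisUnit],
    phenotypes: Sequence[Phenotype] | None = None,
) -> CooccurrenceMatrix:
    """Count pairwise phenotype co-occurrence and scale per manifestation.

    Phenotypes with zero carrying units are dropped with a warning.  Every
    unit must have a non-empty phenotype set (guaranteed upstream by the
    admission rules).
    """
    if phenotypes is None:
        phenotypes = ANALYSIS_PHENOTYPES
    for u in units:
        if not u.phenotypes:
            raise ValidationError(f"unit {u.unit_id} has an empty phenotype set")

    names = [p.value for p in phenotypes]
    member = np.array(
        [[p in u.phenotypes for p in phenotypes] for u in units], dtype=int
    )
    if member.size == 0:
        member = member.reshape(0, len(names))
    counts = member.T @ member  # C[a,b]; diagonal = marginals

    keep = counts.diagonal() > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(
            f"phenotypes with zero units dropped from co-occurrence: {dropped}",
            stacklevel=2,
        )
    names = [n for n, k in zip(names, keep) if k]
    counts = counts[np.ix_(keep, keep)]

    diag = counts.diagonal().astype(float)
    r = counts / diag[:, None]

    k = len(names)
    s = np.full((k, k), np.nan)
    degenerate: list[str] = []
    off = ~np.eye(k, dtype=bool)
    for i in range(k):
        row = r[i, off[i]]
        if row.size == 0:
            continue
        lo, hi = row.min(), row.max()
        if hi - lo <= 0:
            s[i, off[i]] = 0.0
            degenerate.append(names[i])
        else:
            s[i, off[i]] = (r[i, off[i]] - lo) / (hi - lo)

    bands = pd.DataFrame("", index=names, columns=names)
    for i in range(k):
        for j in range(k):
            if i != j and not np.isnan(s[i, j]):
                bands.iloc[i, j] = band_of(s[i, j])

    as_df = lambda m: pd.DataFrame(m, index=names, columns=names)
    conditional = as_df(r.copy())
    np.fill_diagonal(conditional.values, 1.0)
    return CooccurrenceMatrix(
        phenotypes=names,
        counts=as_df(counts),
        conditional=conditional,
        scaled=as_df(s),
        bands=bands,
        degenerate_rows=degenerate,
        dropped=dropped,
    )
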