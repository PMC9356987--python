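"""Cohort summary surface: demographics, phenotype and variant-type
frequencies, and phenotype counts within the truncating / nontruncating
strata, at each analysis level.

Fractions are always reported with their denominator; age statistics use
pairwise deletion (each statistic uses every unit carrying the field it
needs, with no imputation), so denominators differ between fields.
Phenotype fractions may sum to more than 1 because units carry several
phenotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import AnalysisUnit, CohortViews
from .datamodel import (
    ANALYSIS_PHENOTYPES,
    DeNovo,
    Phenotype,
    Resolution,
    Sex,
    VariantGroup,
    VariantType,
)

__all__ = ["SummaryTable", "summarize", "round_pct"]


def round_pct(value: float, ndigits: int = 1) -> float:
    """Percentage rounding, half away from zero (report parity)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def _age_block(values: Sequence[float]) -> dict:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return {"n": 0, "mean": None, "median": None, "min": None, "max": None}
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def _count_block(count: int, denominator: int) -> dict:
    pct = round_pct(100.0 * count / denominator) if denominator else None
    return {"count": count, "denominator": denominator, "pct": pct}


@dataclass
class SummaryTable:
    """Nested per-level summary; see :func:`summarize`."""

    levels: dict[str, dict] = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.levels, indent=2, **kwargs)

    def phenotype_frame(self, level: str) -> pd.DataFrame:
        block = self.levels[level]["phenotypes"]
        return pd.DataFrame(block).T

    def group_table(self, level: str) -> pd.DataFrame:
        """7x2 phenotype x truncating/nontruncating count table."""
        block = self.levels[level]["group_strata"]
        frame = pd.DataFrame(
            {
                g: {p: block[g]["phenotypes"][p]["count"] for p in block[g]["phenotypes"]}
                for g in ("truncating", "nontruncating")
            }
        )
        return frame.loc[[p.value for p in ANALYSIS_PHENOTYPES]]


def _summarize_level(units: Sequence[AnalysisUnit], level: Resolution) -> dict:
    n = len(units)
    out: dict = {"n_units": n}

    if level is Resolution.PATIENT:
        sexed = [u for u in units if u.sex is not Sex.UNKNOWN]
        n_sex = len(sexed)
        out["sex"] = {
            "denominator": n_sex,
            "male": _count_block(sum(u.sex is Sex.MALE for u in sexed), n_sex),
            "female": _count_block(sum(u.sex is Sex.FEMALE for u in sexed), n_sex),
        }
        out["ages"] = {
            "age_onset": _age_block([u.age_onset for u in units]),
            "age_death": _age_block([u.age_death for u in units]),
            "last_known_age": _age_block([u.last_known_age for u in units]),
        }
        out["de_novo_confirmed"] = sum(u.de_novo is DeNovo.CONFIRMED for u in units)

    out["phenotypes"] = {
        p.value: _count_block(sum(p in u.phenotypes for u in units), n)
        for p in ANALYSIS_PHENOTYPES
    }
    out["variant_types"] = {
        vt.value: _count_block(
            sum(u.variant.variant_type is vt for u in units), n
        )
        for vt in VariantType
        if any(u.variant.variant_type is vt for u in units)
    }

    strata: dict = {}
    for grp in (VariantGroup.TRUNCATING, VariantGroup.NONTRUNCATING):
        members = [u for u in units if u.group is grp]
        strata[grp.value] = {
            "n": len(members),
            "phenotypes": {
                p.value: _count_block(
                    sum(p in u.phenotypes for u in members), len(members)
                )
                for p in ANALYSIS_PHENOTYPES
            },
        }
    out["group_strata"] = strata
    return out


def summarize(views: CohortViews) -> SummaryTable:
    """Compute the summary table for the patient, family and variant views."""
    return SummaryTable(
        levels={
            "patient": _summarize_level(views.patients, Resolution.PATIENT),
            "family": _summarize_level(views.families, Resolution.FAMILY),
            "variant": _summarize_level(views.variants, Resolution.VARIANT),
        }
    )
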