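"""Synthetic cohort generator emulating the curated datasheet schema.

Cohorts are generated family-first: each kindred draws a latent genotype
class (a variant group plus a protein-domain preference — the classical
type 1 / type 2 structure), one germline variant consistent with that
class (with optional planted codon hotspots for missense draws), and then
members whose phenotype sets are conditionally independent Bernoulli draws
given the class.  Onset ages come from per-phenotype location-scale
distributions rounded to integer years, the granularity of
literature-derived data.  Field-level missingness, untested kindred
members (exercising the familial-variant rescue), common population
variants, and the four resolution tags are all emulated; publication bias
and cross-source duplicate patients are not.

Ground truth (latent class per case, planted hotspots, onset parameters)
is returned alongside the datasheet so recovery tests can score the
pipeline.

The protein reference sequence used for p. descriptions is synthetic (a
fixed random 213-mer, not the real VHL sequence); parsing and grouping
never depend on the actual residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .cohort import DATASHEET_COLUMNS
from .datamodel import (
    ALPHA_DOMAIN,
    ANALYSIS_PHENOTYPES,
    BETA_DOMAIN,
    N_CODONS,
    Phenotype,
    Resolution,
    VariantGroup,
    VariantType,
    load_hpo_table,
)

__all__ = [
    "OnsetParams",
    "GenotypeClass",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "planted_cluster_config",
    "planted_hotspot_config",
    "published_counts_fixture",
    "PUBLISHED_GROUP_COUNTS",
]

_AA_1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
_AA20 = "ARNDCQEGHILKMFPSTWYV"

# Synthetic 213-residue reference (fixed seed, independent of cohort seed).
_REF_SEQ = "".join(
    _AA20[i] for i in np.random.default_rng(20220510).integers(0, 20, N_CODONS)
)

#: Cohort-scale variant-type frequencies used as generator defaults
#: (patient-level shares of the common truncating/nontruncating types).
DEFAULT_VARIANT_TYPE_PROBS: dict[VariantType, float] = {
    VariantType.MISSENSE: 0.624,
    VariantType.STOP_GAINED: 0.080,
    VariantType.FRAMESHIFT: 0.078,
    VariantType.DELETION: 0.078,
    VariantType.EXON_LOSS: 0.073,
    VariantType.SPLICE_SITE: 0.038,
    VariantType.INFRAME_INDEL: 0.020,
    VariantType.SYNONYMOUS: 0.014,
    VariantType.UTR: 0.006,
    VariantType.DELINS: 0.003,
    VariantType.STOP_LOST: 0.003,
    VariantType.START_LOST: 0.001,
    VariantType.INTRON: 0.001,
}

_TYPES_BY_GROUP = {
    VariantGroup.TRUNCATING: (
        VariantType.STOP_GAINED,
        VariantType.FRAMESHIFT,
        VariantType.DELETION,
        VariantType.EXON_LOSS,
        VariantType.SPLICE_SITE,
        VariantType.START_LOST,
    ),
    VariantGroup.NONTRUNCATING: (
        VariantType.MISSENSE,
        VariantType.INFRAME_INDEL,
        VariantType.DELINS,
        VariantType.STOP_LOST,
    ),
}

_EXCLUDED_EMITTED = (VariantType.SYNONYMOUS, VariantType.UTR, VariantType.INTRON)

_EXON_BOUNDARIES = (340, 463, 553)  # coding positions used for splice/intron c. strings


class OnsetParams(BaseModel):
    """Location-scale parameters (years) of one phenotype's onset ages."""

    loc: float
    scale: float = Field(gt=0)


class GenotypeClass(BaseModel):
    """A latent genotype class: variant group, domain preference, phenotype rates."""

    name: str
    weight: float = Field(gt=0)
    group: VariantGroup
    domain: Literal["alpha", "beta", "any"] = "any"
    phenotype_probs: dict[Phenotype, float]

    @field_validator("phenotype_probs")
    @classmethod
    def _probs_in_unit_interval(cls, value):
        for phen, p in value.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"P({phen.value}) = {p} outside [0, 1]")
        return value

    @field_validator("group")
    @classmethod
    def _group_analysable(cls, value):
        if value is VariantGroup.EXCLUDED:
            raise ValueError("genotype classes must be truncating or nontruncating")
        return value


def _default_classes() -> list[GenotypeClass]:
    # Type 1-like: truncating, beta-domain, CHB/RCC-elevated, PPGL rare.
    # Type 2-like: nontruncating, alpha-domain, PPGL-dominant with PNET.
    return [
        GenotypeClass(
            name="type1_like",
            weight=0.65,
            group=VariantGroup.TRUNCATING,
            domain="beta",
            phenotype_probs={
                Phenotype.CHB: 0.70,
                Phenotype.RA: 0.38,
                Phenotype.RCC: 0.40,
                Phenotype.RCT: 0.20,
                Phenotype.PCT: 0.35,
                Phenotype.PPGL: 0.08,
                Phenotype.PNET: 0.04,
            },
        ),
        GenotypeClass(
            name="type2_like",
            weight=0.35,
            group=VariantGroup.NONTRUNCATING,
            domain="alpha",
            phenotype_probs={
                Phenotype.CHB: 0.40,
                Phenotype.RA: 0.30,
                Phenotype.RCC: 0.22,
                Phenotype.RCT: 0.10,
                Phenotype.PCT: 0.18,
                Phenotype.PPGL: 0.75,
                Phenotype.PNET: 0.15,
            },
        ),
    ]


def _default_onsets() -> dict[Phenotype, OnsetParams]:
    # Medians: PPGL and RA before 18; CHB 36; RCC 44; PCT 27.
    return {
        Phenotype.PPGL: OnsetParams(loc=16, scale=9),
        Phenotype.RA: OnsetParams(loc=16, scale=10),
        Phenotype.CHB: OnsetParams(loc=36, scale=13),
        Phenotype.RCC: OnsetParams(loc=44, scale=11),
        Phenotype.PCT: OnsetParams(loc=27, scale=12),
        Phenotype.RCT: OnsetParams(loc=30, scale=13),
        Phenotype.PNET: OnsetParams(loc=30, scale=12),
    }


class SimulationConfig(BaseModel):
    """Fully seeded description of one synthetic cohort."""

    seed: int = 0
    n_families: int = Field(default=400, gt=0)
    family_size_p: float = Field(default=0.75, gt=0, le=1)  # size ~ Geometric(p)
    resolution_mix: dict[Resolution, float] = Field(
        default_factory=lambda: {
            Resolution.PATIENT: 0.70,
            Resolution.FAMILY: 0.15,
            Resolution.VARIANT: 0.10,
            Resolution.TUMOR: 0.05,
        }
    )
    variant_type_probs: dict[VariantType, float] = Field(
        default_factory=lambda: dict(DEFAULT_VARIANT_TYPE_PROBS)
    )
    hotspot_codons: list[tuple[int, float]] = Field(
        default_factory=lambda: [(167, 10.0), (161, 6.0)]
    )
    classes: list[GenotypeClass] = Field(default_factory=_default_classes)
    onset_model: dict[Phenotype, OnsetParams] = Field(default_factory=_default_onsets)
    missingness: dict[str, float] = Field(
        default_factory=lambda: {
            "age_onset": 0.45,
            "age_death": 0.92,
            "last_known_age": 0.30,
            "sex": 0.35,
        }
    )
    excluded_type_rate: float = Field(default=0.02, ge=0, le=1)
    common_variant_rate: float = Field(default=0.01, ge=0, le=1)
    label_noise: float = Field(default=0.0, ge=0, le=1)
    unconfirmed_member_rate: float = Field(default=0.2, ge=0, le=1)
    de_novo_rate: float = Field(default=0.034, ge=0, le=1)
    male_rate: float = Field(default=0.524, ge=0, le=1)

    @model_validator(mode="after")
    def _validate(self):
        if abs(sum(self.resolution_mix.values()) - 1.0) > 1e-9:
            raise ValueError("resolution_mix probabilities must sum to 1")
        for p in self.missingness.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("missingness probabilities must lie in [0, 1]")
        for codon, mult in self.hotspot_codons:
            if not 1 <= codon <= N_CODONS:
                raise ValueError(f"hotspot codon {codon} outside 1..{N_CODONS}")
            if mult <= 0:
                raise ValueError("hotspot multiplier must be positive")
        total = sum(self.variant_type_probs.values())
        if total <= 0:
            raise ValueError("variant_type_probs must have positive mass")
        return self


@dataclass
class GroundTruth:
    """Planted structure exported next to the datasheet."""

    class_by_case: dict[str, str]
    hotspot_codons: list[tuple[int, float]]
    onset_model: dict[str, tuple[float, float]]
    class_names: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_by_case": self.class_by_case,
                "hotspot_codons": self.hotspot_codons,
                "onset_model": self.onset_model,
                "class_names": self.class_names,
            },
            indent=2,
        )


def _codon_weights(domain: str, hotspots, for_missense: bool) -> np.ndarray:
    weights = np.zeros(N_CODONS)
    if domain == "alpha":
        allowed = sorted(ALPHA_DOMAIN)
    elif domain == "beta":
        allowed = sorted(BETA_DOMAIN)
    else:
        allowed = range(1, N_CODONS + 1)
    for c in allowed:
        weights[c - 1] = 1.0
    if for_missense:
        for codon, mult in hotspots:
            if weights[codon - 1] > 0:
                weights[codon - 1] *= mult
    return weights / weights.sum()


def _hgvs_for(vt: VariantType, codon: int | None, rng) -> tuple[str, str, str]:
    """(hgvs_c, hgvs_p, declared_type) strings for a drawn variant."""
    ref1 = _REF_SEQ[(codon or 1) - 1]
    ref3 = _AA_1TO3[ref1]
    if vt is VariantType.MISSENSE:
        alt1 = rng.choice([a for a in _AA20 if a != ref1])
        return "", f"p.{ref3}{codon}{_AA_1TO3[alt1]}", "missense"
    if vt is VariantType.STOP_GAINED:
        return "", f"p.{ref3}{codon}Ter", "stop gained"
    if vt is VariantType.SYNONYMOUS:
        return "", f"p.{ref3}{codon}=", "synonymous"
    if vt is VariantType.FRAMESHIFT:
        return "", f"p.{ref3}{codon}fs", "frameshift"
    if vt is VariantType.INFRAME_INDEL:
        return "", f"p.{ref3}{codon}del", "inframe indel"
    if vt is VariantType.DELINS:
        alt1 = rng.choice([a for a in _AA20 if a != ref1])
        return "", f"p.{ref3}{codon}delins{_AA_1TO3[alt1]}", "delins"
    if vt is VariantType.DELETION:
        return "c.1_553del", "", "deletion"
    if vt is VariantType.EXON_LOSS:
        return "", "", "exon loss"
    if vt is VariantType.SPLICE_SITE:
        pos = int(rng.choice(_EXON_BOUNDARIES))
        return f"c.{pos}+1G>A", "", "splice site"
    if vt is VariantType.INTRON:
        pos = int(rng.choice(_EXON_BOUNDARIES))
        return f"c.{pos}+{int(rng.integers(10, 60))}C>T", "", "intron"
    if vt is VariantType.UTR:
        return f"c.-{int(rng.integers(5, 60))}C>T", "", "utr"
    if vt is VariantType.STOP_LOST:
        return "", "p.Ter214GlnextTer15", "stop lost"
    if vt is VariantType.START_LOST:
        return "", "p.Met1?", "start lost"
    raise ValueError(f"unsupported generated type {vt}")


def _draw_variant(cls: GenotypeClass, config: SimulationConfig, rng):
    if rng.random() < config.excluded_type_rate:
        probs = np.array([config.variant_type_probs.get(t, 0.0) for t in _EXCLUDED_EMITTED])
        if probs.sum() == 0:
            probs = np.ones(len(_EXCLUDED_EMITTED))
        vt = _EXCLUDED_EMITTED[rng.choice(len(_EXCLUDED_EMITTED), p=probs / probs.sum())]
    else:
        types = _TYPES_BY_GROUP[cls.group]
        probs = np.array([config.variant_type_probs.get(t, 0.0) for t in types])
        if probs.sum() == 0:
            probs = np.ones(len(types))
        vt = types[rng.choice(len(types), p=probs / probs.sum())]
    codon = None
    if vt in (
        VariantType.MISSENSE,
        VariantType.STOP_GAINED,
        VariantType.SYNONYMOUS,
        VariantType.FRAMESHIFT,
        VariantType.INFRAME_INDEL,
        VariantType.DELINS,
    ):
        weights = _codon_weights(
            cls.domain, config.hotspot_codons, for_missense=vt is VariantType.MISSENSE
        )
        codon = int(rng.choice(N_CODONS, p=weights)) + 1
    return _hgvs_for(vt, codon, rng)


def _phenotype_set(cls: GenotypeClass, config: SimulationConfig, rng) -> set[Phenotype]:
    source = cls
    if config.label_noise > 0 and len(config.classes) > 1 and rng.random() < config.label_noise:
        others = [c for c in config.classes if c.name != cls.name]
        source = others[rng.choice(len(others))]
    return {
        phen for phen, p in source.phenotype_probs.items() if rng.random() < p
    }


_HPO_BY_GROUP: dict[Phenotype, list[str]] | None = None


def _hpo_terms_for(phenotypes: set[Phenotype], rng) -> str:
    global _HPO_BY_GROUP
    if _HPO_BY_GROUP is None:
        _HPO_BY_GROUP = {}
        for hpo_id, group in load_hpo_table().items():
            _HPO_BY_GROUP.setdefault(group, []).append(hpo_id)
        for terms in _HPO_BY_GROUP.values():
            terms.sort()
    terms = []
    for phen in sorted(phenotypes, key=lambda p: p.value):
        options = _HPO_BY_GROUP[phen]
        terms.append(options[rng.choice(len(options))])
    return ";".join(terms)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one datasheet and its planted ground truth.

    The same config (including seed) always produces byte-identical output.
    Returns (rows, ground_truth) where ``rows`` carries exactly the
    documented datasheet columns as strings.
    """
    rng = np.random.default_rng(config.seed)
    class_weights = np.array([c.weight for c in config.classes], dtype=float)
    class_weights = class_weights / class_weights.sum()
    resolutions = list(config.resolution_mix)
    res_probs = np.array([config.resolution_mix[r] for r in resolutions])

    rows: list[dict] = []
    class_by_case: dict[str, str] = {}

    def onset_ages(phens: set[Phenotype]) -> dict[Phenotype, int]:
        out = {}
        for phen in sorted(phens, key=lambda p: p.value):
            params = config.onset_model.get(phen)
            if params is None:
                continue
            out[phen] = int(round(max(0.0, rng.normal(params.loc, params.scale))))
        return out

    for fam_idx in range(config.n_families):
        cls = config.classes[rng.choice(len(config.classes), p=class_weights)]
        hgvs_c, hgvs_p, declared = _draw_variant(cls, config, rng)
        common = rng.random() < config.common_variant_rate
        af = f"{rng.uniform(0.011, 0.05):.4f}" if common else ""
        resolution = resolutions[rng.choice(len(resolutions), p=res_probs)]
        kindred = f"K{fam_idx + 1:05d}"
        size = int(rng.geometric(config.family_size_p)) if resolution is Resolution.PATIENT else 1

        if resolution is Resolution.PATIENT:
            for member in range(size):
                case_id = f"P{fam_idx + 1:05d}_{member + 1}"
                phens = _phenotype_set(cls, config, rng)
                onsets = onset_ages(phens)
                onset = min(onsets.values()) if onsets else None
                confirmed = member == 0 or rng.random() >= config.unconfirmed_member_rate
                sex = "male" if rng.random() < config.male_rate else "female"
                if rng.random() < config.missingness.get("sex", 0.0):
                    sex = ""
                onset_cell = (
                    ""
                    if onset is None or rng.random() < config.missingness.get("age_onset", 0.0)
                    else str(onset)
                )
                last_known = ""
                if rng.random() >= config.missingness.get("last_known_age", 0.0):
                    base = onset if onset is not None else 30
                    last_known = str(int(base + rng.integers(0, 15)))
                age_death = ""
                if rng.random() >= config.missingness.get("age_death", 0.0):
                    base = onset if onset is not None else 30
                    age_death = str(int(base + rng.integers(5, 30)))
                de_novo = (
                    "confirmed"
                    if member == 0 and rng.random() < config.de_novo_rate
                    else "unknown"
                )
                rows.append(
                    {
                        "case_id": case_id,
                        "source_id": f"SIM{fam_idx % 40 + 1:03d}",
                        "resolution": "patient",
                        "kindred_id": kindred,
                        "hgvs_c": hgvs_c if confirmed else "",
                        "hgvs_p": hgvs_p if confirmed else "",
                        "variant_type": declared if confirmed else "",
                        "genotype_confirmed": "true" if confirmed else "false",
                        "de_novo": de_novo,
                        "sex": sex,
                        "age_onset": onset_cell,
                        "age_death": age_death,
                        "last_known_age": last_known,
                        "gnomad_af": af if confirmed else "",
                        "hpo_terms": _hpo_terms_for(phens, rng),
                    }
                )
                class_by_case[case_id] = cls.name
        else:
            case_id = f"{resolution.value[0].upper()}{fam_idx + 1:05d}"
            phens = _phenotype_set(cls, config, rng)
            if resolution is Resolution.TUMOR and phens:
                phens = {sorted(phens, key=lambda p: p.value)[0]}
            rows.append(
                {
                    "case_id": case_id,
                    "source_id": f"SIM{fam_idx % 40 + 1:03d}",
                    "resolution": resolution.value,
                    "kindred_id": kindred if resolution is Resolution.FAMILY else "",
                    "hgvs_c": hgvs_c,
                    "hgvs_p": hgvs_p,
                    "variant_type": declared,
                    "genotype_confirmed": "true",
                    "de_novo": "unknown",
                    "sex": "",
                    "age_onset": "",
                    "age_death": "",
                    "last_known_age": "",
                    "gnomad_af": af,
                    "hpo_terms": _hpo_terms_for(phens, rng),
                }
            )
            class_by_case[case_id] = cls.name

    frame = pd.DataFrame(rows, columns=list(DATASHEET_COLUMNS))
    truth = GroundTruth(
        class_by_case=class_by_case,
        hotspot_codons=list(config.hotspot_codons),
        onset_model={
            p.value: (o.loc, o.scale) for p, o in config.onset_model.items()
        },
        class_names=[c.name for c in config.classes],
    )
    return frame, truth


def planted_cluster_config(
    n_clusters: int,
    n_families: int = 200,
    noise: float = 0.1,
    label_noise: float = 0.0,
    seed: int = 0,
    all_missense: bool = False,
) -> SimulationConfig:
    """Config with K classes, each dominated by one distinct phenotype.

    The class-defining (dominant) phenotype is always present; background
    phenotypes — those that define no class — appear independently with
    probability ``noise``, while other classes' defining phenotypes never do
    (planted structure keeps the class-defining phenotypes exclusive).
    ``label_noise`` instead swaps a member's phenotype draw to a random
    other class.  Used for eigengap / clustering recovery experiments.
    """
    if not 2 <= n_clusters <= len(ANALYSIS_PHENOTYPES):
        raise ValueError("n_clusters must be between 2 and 7")
    dominants = [Phenotype.PPGL, Phenotype.CHB, Phenotype.RA, Phenotype.RCC,
                 Phenotype.PCT, Phenotype.RCT, Phenotype.PNET][:n_clusters]
    background = [p for p in ANALYSIS_PHENOTYPES if p not in dominants]
    classes = []
    for i, dom in enumerate(dominants):
        probs = {p: noise for p in background}
        probs[dom] = 1.0
        classes.append(
            GenotypeClass(
                name=f"planted_{dom.value}",
                weight=1.0,
                group=(
                    VariantGroup.NONTRUNCATING
                    if dom is Phenotype.PPGL or all_missense
                    else VariantGroup.TRUNCATING
                ),
                domain="alpha" if dom is Phenotype.PPGL else "beta",
                phenotype_probs=probs,
            )
        )
    probs = dict(DEFAULT_VARIANT_TYPE_PROBS)
    if all_missense:
        probs = {VariantType.MISSENSE: 1.0}
    return SimulationConfig(
        seed=seed,
        n_families=n_families,
        classes=classes,
        resolution_mix={Resolution.PATIENT: 1.0},
        label_noise=label_noise,
        common_variant_rate=0.0,
        excluded_type_rate=0.0,
        unconfirmed_member_rate=0.0,
        variant_type_probs=probs,
        missingness={"age_onset": 0.0, "age_death": 1.0, "last_known_age": 1.0, "sex": 0.0},
    )


def planted_hotspot_config(
    codon: int = 167,
    multiplier: float = 10.0,
    n_families: int = 450,
    seed: int = 0,
) -> SimulationConfig:
    """All-missense cohort with a uniform codon background and one planted
    hotspot at ``multiplier`` times the uniform rate."""
    cls = GenotypeClass(
        name="missense_background",
        weight=1.0,
        group=VariantGroup.NONTRUNCATING,
        domain="any",
        phenotype_probs={Phenotype.CHB: 0.6, Phenotype.RA: 0.3, Phenotype.RCC: 0.3},
    )
    return SimulationConfig(
        seed=seed,
        n_families=n_families,
        classes=[cls],
        hotspot_codons=[(codon, multiplier)],
        variant_type_probs={VariantType.MISSENSE: 1.0},
        resolution_mix={Resolution.PATIENT: 1.0},
        common_variant_rate=0.0,
        excluded_type_rate=0.0,
        unconfirmed_member_rate=0.0,
    )


# ---------------------------------------------------------------------------
# Deterministic fixture reproducing the published 7x2 count tables
# ---------------------------------------------------------------------------

#: Published phenotype x truncating/nontruncating counts at each level.
PUBLISHED_GROUP_COUNTS: dict[str, dict[str, dict[Phenotype, int]]] = {
    "patient": {
        "truncating": {
            Phenotype.PNET: 31, Phenotype.PPGL: 72, Phenotype.CHB: 519,
            Phenotype.RA: 250, Phenotype.RCC: 269, Phenotype.RCT: 134,
            Phenotype.PCT: 269,
        },
        "nontruncating": {
            Phenotype.PNET: 112, Phenotype.PPGL: 688, Phenotype.CHB: 676,
            Phenotype.RA: 466, Phenotype.RCC: 363, Phenotype.RCT: 167,
            Phenotype.PCT: 277,
        },
    },
    "family": {
        "truncating": {
            Phenotype.PNET: 34, Phenotype.PPGL: 90, Phenotype.CHB: 563,
            Phenotype.RA: 319, Phenotype.RCC: 334, Phenotype.RCT: 153,
            Phenotype.PCT: 169,
        },
        "nontruncating": {
            Phenotype.PNET: 98, Phenotype.PPGL: 511, Phenotype.CHB: 587,
            Phenotype.RA: 433, Phenotype.RCC: 348, Phenotype.RCT: 161,
            Phenotype.PCT: 259,
        },
    },
    "variant": {
        "truncating": {
            Phenotype.PNET: 36, Phenotype.PPGL: 63, Phenotype.CHB: 197,
            Phenotype.RA: 142, Phenotype.RCC: 152, Phenotype.RCT: 83,
            Phenotype.PCT: 104,
        },
        "nontruncating": {
            Phenotype.PNET: 66, Phenotype.PPGL: 158, Phenotype.CHB: 177,
            Phenotype.RA: 168, Phenotype.RCC: 125, Phenotype.RCT: 84,
            Phenotype.PCT: 105,
        },
    },
}

_REPRESENTATIVE_HPO = {
    Phenotype.PNET: "HP:0030088",
    Phenotype.PPGL: "HP:0002666",
    Phenotype.CHB: "HP:0009713",
    Phenotype.RA: "HP:0009594",
    Phenotype.RCC: "HP:0005584",
    Phenotype.RCT: "HP:0000107",
    Phenotype.PCT: "HP:0001737",
}


def published_counts_fixture(level: str = "patient") -> pd.DataFrame:
    """Deterministic pseudo-cohort reproducing a published 7x2 count block.

    Each (phenotype, group) cell becomes that many single-phenotype cases,
    so the aggregated phenotype x truncating/nontruncating table equals the
    published block exactly (cell counts are what the chi-square consumes;
    the construction does not reproduce the published multi-phenotype
    patient totals).  ``level`` selects the patient, family, or variant
    block; rows are emitted at the matching resolution.  Every row carries
    a distinct variant so the fixture also survives variant-level
    aggregation unchanged.
    """
    if level not in PUBLISHED_GROUP_COUNTS:
        raise ValueError(f"unknown level {level!r}")
    block = PUBLISHED_GROUP_COUNTS[level]
    resolution = {"patient": "patient", "family": "family", "variant": "variant"}[level]
    rows = []
    i = 0
    n_missense = 0
    for group_name, cells in block.items():
        truncating = group_name == "truncating"
        for phen in ANALYSIS_PHENOTYPES:
            for _ in range(cells[phen]):
                i += 1
                if truncating:
                    hgvs_c, hgvs_p = f"c.{i}_553del", ""
                else:
                    codon = n_missense % N_CODONS + 1
                    ref = _REF_SEQ[codon - 1]
                    alts = [a for a in _AA20 if a != ref]
                    alt = alts[(n_missense // N_CODONS) % len(alts)]
                    hgvs_c = ""
                    hgvs_p = f"p.{_AA_1TO3[ref]}{codon}{_AA_1TO3[alt]}"
                    n_missense += 1
                rows.append(
                    {
                        "case_id": f"PUB_{level}_{i:05d}",
                        "source_id": "PUBLISHED",
                        "resolution": resolution,
                        "kindred_id": f"PUBK{i:05d}",
                        "hgvs_c": hgvs_c,
                        "hgvs_p": hgvs_p,
                        "variant_type": "",
                        "genotype_confirmed": "true",
                        "de_novo": "unknown",
                        "sex": "",
                        "age_onset": "",
                        "age_death": "",
                        "last_known_age": "",
                        "gnomad_af": "",
                        "hpo_terms": _REPRESENTATIVE_HPO[phen],
                    }
                )
    return pd.DataFrame(rows, columns=list(DATASHEET_COLUMNS))
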