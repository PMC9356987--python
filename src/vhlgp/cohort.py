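"""Datasheet loading, exclusion filtering, and the three analysis views.

A curated cohort arrives as one delimited row per case, tagged with a
resolution (patient / family / variant / tumor).  Analyses run at three
aggregation levels:

* patient-based — one unit per patient-resolution case;
* family-based — patient cases aggregated by kindred within their source
  publication, plus family-resolution cases; a family is admitted only if at
  least one member carries a genetically confirmed variant, and clinically
  diagnosed but untested members are assumed to carry the familial variant;
* variant-based — one unit per unique variant across all four resolutions.

Every admitted unit must have both a variant and at least one mapped VHL
phenotype group; everything dropped lands in an exclusion ledger with a
reason code, so kept + ledger always reconstruct the input.
"""

from __future__ import annotations

import io
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .datamodel import (
    CaseRecord,
    DeNovo,
    Phenotype,
    Resolution,
    Sex,
    ValidationError,
    VariantAnnotation,
    VariantGroup,
    VhlError,
    classify_variant,
    group_variant,
    map_phenotypes,
    normalize_variant_key,
)

__all__ = [
    "DATASHEET_COLUMNS",
    "DatasheetError",
    "AnalysisUnit",
    "ExclusionLedger",
    "CohortViews",
    "load_datasheet",
    "apply_exclusions",
    "aggregate_families",
    "aggregate_variants",
    "build_views",
    "COMMON_AF_THRESHOLD",
]

#: Mandatory datasheet columns, in canonical order.
DATASHEET_COLUMNS = (
    "case_id",
    "source_id",
    "resolution",
    "kindred_id",
    "hgvs_c",
    "hgvs_p",
    "variant_type",
    "genotype_confirmed",
    "de_novo",
    "sex",
    "age_onset",
    "age_death",
    "last_known_age",
    "gnomad_af",
    "hpo_terms",
)

#: Variants with a global minor allele frequency above this are treated as
#: common population variants unlikely to cause disease (strict inequality).
COMMON_AF_THRESHOLD = 0.01


class DatasheetError(VhlError):
    """Raised when the datasheet cannot be loaded; carries row-level errors."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        self.row_errors = row_errors or []
        detail = "" if not self.row_errors else "\n" + "\n".join(self.row_errors)
        super().__init__(message + detail)


@dataclass
class AnalysisUnit:
    """A patient, family, or unique variant admitted to analysis."""

    unit_id: str
    level: Resolution
    phenotypes: frozenset[Phenotype]
    variant: VariantAnnotation
    member_case_ids: tuple[str, ...] = ()
    # demographics carried only at patient level
    sex: Sex = Sex.UNKNOWN
    de_novo: DeNovo = DeNovo.UNKNOWN
    age_onset: float | None = None
    age_death: float | None = None
    last_known_age: float | None = None

    @property
    def group(self) -> VariantGroup:
        return group_variant(self.variant)


@dataclass
class ExclusionLedger:
    """Dropped records with reason codes; emitted alongside every analysis."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)  # (case_id, level, reason)

    def add(self, case_id: str, level: str, reason: str) -> None:
        self.entries.append((case_id, level, reason))

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for _, _, reason in self.entries:
            out[reason] += 1
        return dict(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["case_id", "level", "reason"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CohortViews:
    patients: list[AnalysisUnit]
    families: list[AnalysisUnit]
    variants: list[AnalysisUnit]
    ledger: ExclusionLedger


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f", ""}


def _parse_bool(token: str, row_label: str, errors: list[str]) -> bool:
    key = token.strip().lower()
    if key in _TRUE_TOKENS:
        return True
    if key in _FALSE_TOKENS:
        return False
    errors.append(f"{row_label}: unparseable boolean {token!r}")
    return False


def _parse_age(token: str, column: str, row_label: str, errors: list[str]) -> float | None:
    token = token.strip()
    if not token:
        return None
    try:
        value = float(token)
    except ValueError:
        errors.append(f"{row_label}: non-numeric {column} {token!r}")
        return None
    if value < 0:
        errors.append(f"{row_label}: negative {column} {token!r}")
        return None
    return value


def _split_cell(cell: str) -> list[str]:
    return [part.strip() for part in cell.split(";") if part.strip()]


def load_datasheet(source, *, hpo_table=None) -> list[CaseRecord]:
    """Read a delimited datasheet into :class:`CaseRecord` objects.

    ``source`` is a path or text buffer; the delimiter (TSV or CSV) is
    sniffed.  The ``hpo_terms`` cell is split on ``;``; blank cells become
    absent values.  Compound-heterozygous records may carry two
    ``;``-separated descriptors in ``hgvs_c``/``hgvs_p`` (and matching
    ``gnomad_af`` entries).  Malformed ages and invalid codons raise a
    :class:`DatasheetError` naming the offending rows.
    """
    if isinstance(source, (str,)) and "\n" in source:
        source = io.StringIO(source)
    frame = pd.read_csv(source, sep=None, engine="python", dtype=str, comment="#").fillna("")
    missing = [c for c in DATASHEET_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasheetError(f"missing mandatory columns: {', '.join(missing)}")

    records: list[CaseRecord] = []
    errors: list[str] = []
    for idx, row in frame.iterrows():
        label = f"row {idx + 2} (case_id={row['case_id'] or '?'})"  # +2: header + 1-based
        try:
            resolution = Resolution(row["resolution"].strip().lower())
        except ValueError:
            errors.append(f"{label}: unknown resolution {row['resolution']!r}")
            continue
        sex = row["sex"].strip().lower() or "unknown"
        de_novo = row["de_novo"].strip().lower() or "unknown"
        try:
            sex = Sex(sex)
        except ValueError:
            errors.append(f"{label}: unknown sex {row['sex']!r}")
            sex = Sex.UNKNOWN
        try:
            de_novo = DeNovo(de_novo)
        except ValueError:
            errors.append(f"{label}: unknown de_novo {row['de_novo']!r}")
            de_novo = DeNovo.UNKNOWN

        hgvs_c_parts = _split_cell(row["hgvs_c"])
        hgvs_p_parts = _split_cell(row["hgvs_p"])
        af_parts = _split_cell(row["gnomad_af"])
        n_variants = max(len(hgvs_c_parts), len(hgvs_p_parts), 1)
        variants: list[VariantAnnotation] = []
        declared = row["variant_type"].strip() or None
        for i in range(n_variants):
            hgvs_c = hgvs_c_parts[i] if i < len(hgvs_c_parts) else None
            hgvs_p = hgvs_p_parts[i] if i < len(hgvs_p_parts) else None
            af_token = af_parts[i] if i < len(af_parts) else ""
            af = None
            if af_token:
                try:
                    af = float(af_token)
                except ValueError:
                    errors.append(f"{label}: non-numeric gnomad_af {af_token!r}")
            if not any((hgvs_c, hgvs_p, declared)):
                continue
            try:
                variants.append(
                    classify_variant(hgvs_c, hgvs_p, declared_type=declared, gnomad_af=af)
                )
            except ValidationError as exc:
                errors.append(f"{label}: {exc}")

        hpo_terms = set(_split_cell(row["hpo_terms"]))
        phenotypes, unmapped = map_phenotypes(hpo_terms, table=hpo_table)

        records.append(
            CaseRecord(
                case_id=row["case_id"].strip() or f"row{idx + 2}",
                source_id=row["source_id"].strip(),
                resolution=resolution,
                kindred_id=row["kindred_id"].strip() or None,
                variants=variants,
                genotype_confirmed=_parse_bool(row["genotype_confirmed"], label, errors),
                de_novo=de_novo,
                sex=sex,
                age_onset=_parse_age(row["age_onset"], "age_onset", label, errors),
                age_death=_parse_age(row["age_death"], "age_death", label, errors),
                last_known_age=_parse_age(row["last_known_age"], "last_known_age", label, errors),
                hpo_terms=hpo_terms,
                phenotypes=phenotypes,
                unmapped_terms=unmapped,
            )
        )
    if errors:
        raise DatasheetError(f"{len(errors)} row-level validation error(s)", errors)
    return records


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------


def _family_key(record: CaseRecord) -> tuple[str, str]:
    # kindred ids are scoped per source; a singleton patient is its own kindred
    return (record.source_id, record.kindred_id or f"__case__{record.case_id}")


def _rescue_familial_variants(records: Sequence[CaseRecord]) -> None:
    """Fill the confirmed familial variant into untested kindred members.

    Clinically diagnosed members without genetic testing are assumed to carry
    the familial variant (analysis-only assumption; the loader never edits
    the datasheet).  Applies only within (source, kindred) groups that have
    exactly one distinct confirmed variant.
    """
    confirmed: dict[tuple[str, str], list[VariantAnnotation]] = defaultdict(list)
    for rec in records:
        if rec.kindred_id and rec.genotype_confirmed and rec.variants:
            confirmed[_family_key(rec)].append(rec.variants[0])
    for rec in records:
        if rec.variants or not rec.kindred_id:
            continue
        candidates = confirmed.get(_family_key(rec), [])
        keys = {normalize_variant_key(v) for v in candidates}
        if len(keys) == 1:
            rec.variants = [candidates[0]]
            rec.variant_inherited = True


def apply_exclusions(
    records: Sequence[CaseRecord],
    af_threshold: float = COMMON_AF_THRESHOLD,
) -> tuple[list[CaseRecord], ExclusionLedger]:
    """Apply the cohort admission rules; return (kept, ledger).

    Reason codes: ``common_population_variant`` (gnomAD AF strictly above the
    1% threshold), ``no_variant`` (no descriptor and not rescued by the
    familial-variant rule), ``no_phenotype`` (no mapped VHL phenotype group).
    Compound-heterozygous records with one common allele keep only the rare
    allele and remain admitted (the patient is considered heterozygous).
    """
    _rescue_familial_variants(records)
    kept: list[CaseRecord] = []
    ledger = ExclusionLedger()
    for rec in records:
        level = rec.resolution.value
        rare = [
            v
            for v in rec.variants
            if v.gnomad_af is None or v.gnomad_af <= af_threshold
        ]
        if rec.variants and not rare:
            ledger.add(rec.case_id, level, "common_population_variant")
            continue
        if not rare:
            ledger.add(rec.case_id, level, "no_variant")
            continue
        if not rec.phenotypes:
            ledger.add(rec.case_id, level, "no_phenotype")
            continue
        rec.variants = rare[:1] if len(rec.variants) > 1 else rare
        kept.append(rec)
    return kept, ledger


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _patient_unit(rec: CaseRecord) -> AnalysisUnit:
    return AnalysisUnit(
        unit_id=rec.case_id,
        level=Resolution.PATIENT,
        phenotypes=frozenset(rec.phenotypes),
        variant=rec.variant,
        member_case_ids=(rec.case_id,),
        sex=rec.sex,
        de_novo=rec.de_novo,
        age_onset=rec.age_onset,
        age_death=rec.age_death,
        last_known_age=rec.last_known_age,
    )


def aggregate_families(
    patient_records: Iterable[CaseRecord],
    family_records: Iterable[CaseRecord],
) -> tuple[list[AnalysisUnit], ExclusionLedger]:
    """Aggregate patient cases into kindreds and append family-resolution cases.

    One unit per (source, kindred); phenotypes are the union over members;
    the familial variant is the genetically confirmed members' variant.  A
    kindred with no genetically confirmed member is excluded, as is one whose
    confirmed members carry distinct variants (flagged
    ``conflicting_family_variant``).
    """
    units: list[AnalysisUnit] = []
    ledger = ExclusionLedger()
    groups: dict[tuple[str, str], list[CaseRecord]] = defaultdict(list)
    for rec in patient_records:
        groups[_family_key(rec)].append(rec)

    for (source_id, kindred), members in groups.items():
        confirmed = [m for m in members if m.genotype_confirmed and m.variants]
        if not confirmed:
            for m in members:
                ledger.add(m.case_id, "family", "no_confirmed_member")
            continue
        keys = {normalize_variant_key(m.variants[0]) for m in confirmed}
        if len(keys) > 1:
            for m in members:
                ledger.add(m.case_id, "family", "conflicting_family_variant")
            continue
        phenotypes = frozenset().union(*(m.phenotypes for m in members))
        unit_id = f"{source_id}:{kindred}"
        units.append(
            AnalysisUnit(
                unit_id=unit_id,
                level=Resolution.FAMILY,
                phenotypes=phenotypes,
                variant=confirmed[0].variants[0],
                member_case_ids=tuple(m.case_id for m in members),
            )
        )

    for rec in family_records:
        if not rec.genotype_confirmed:
            ledger.add(rec.case_id, "family", "no_confirmed_member")
            continue
        units.append(
            AnalysisUnit(
                unit_id=rec.case_id,
                level=Resolution.FAMILY,
                phenotypes=frozenset(rec.phenotypes),
                variant=rec.variant,
                member_case_ids=(rec.case_id,),
            )
        )
    return units, ledger


def aggregate_variants(records: Iterable[CaseRecord]) -> list[AnalysisUnit]:
    """One unit per unique variant, phenotype union across all resolutions."""
    by_key: dict[str, list[CaseRecord]] = defaultdict(list)
    for rec in records:
        if rec.variants:
            by_key[normalize_variant_key(rec.variants[0])].append(rec)
    units = []
    for key, members in by_key.items():
        phenotypes = frozenset().union(*(m.phenotypes for m in members))
        units.append(
            AnalysisUnit(
                unit_id=key,
                level=Resolution.VARIANT,
                phenotypes=phenotypes,
                variant=members[0].variants[0],
                member_case_ids=tuple(m.case_id for m in members),
            )
        )
    return units


def build_views(
    records: Sequence[CaseRecord],
    af_threshold: float = COMMON_AF_THRESHOLD,
) -> CohortViews:
    """Run exclusions and assemble the patient / family / variant views.

    Units are filtered again after aggregation so that every admitted unit
    carries both a variant and at least one mapped phenotype group.
    """
    kept, ledger = apply_exclusions(records, af_threshold=af_threshold)
    patient_recs = [r for r in kept if r.resolution is Resolution.PATIENT]
    family_recs = [r for r in kept if r.resolution is Resolution.FAMILY]

    patients = [_patient_unit(r) for r in patient_recs]
    families, fam_ledger = aggregate_families(patient_recs, family_recs)
    ledger.entries.extend(fam_ledger.entries)
    variants = aggregate_variants(kept)

    def _admit(units: list[AnalysisUnit]) -> list[AnalysisUnit]:
        admitted = []
        for u in units:
            if u.variant is None:
                ledger.add(u.unit_id, u.level.value, "no_variant_after_aggregation")
            elif not u.phenotypes:
                ledger.add(u.unit_id, u.level.value, "no_phenotype_after_aggregation")
            else:
                admitted.append(u)
        return admitted

    return CohortViews(
        patients=_admit(patients),
        families=_admit(families),
        variants=_admit(variants),
        ledger=ledger,
    )
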