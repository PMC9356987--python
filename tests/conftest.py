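"""Shared fixtures: handcrafted mini-datasheets and unit factories."""

from __future__ import annotations

import io

import pytest

from vhlgp import (
    AnalysisUnit,
    Phenotype,
    Resolution,
    VariantAnnotation,
    VariantType,
    build_views,
    load_datasheet,
    published_counts_fixture,
)

HEADER = (
    "case_id\tsource_id\tresolution\tkindred_id\thgvs_c\thgvs_p\tvariant_type\t"
    "genotype_confirmed\tde_novo\tsex\tage_onset\tage_death\tlast_known_age\t"
    "gnomad_af\thpo_terms"
)


def sheet(*rows: str) -> io.StringIO:
    return io.StringIO("\n".join((HEADER,) + rows) + "\n")


@pytest.fixture
def tiny_sheet() -> io.StringIO:
    return sheet(
        "P1\tPMID1\tpatient\tK1\t\tp.Arg167Trp\t\ttrue\tunknown\tmale\t30\t\t45\t\tHP:0002666",
        "P2\tPMID1\tpatient\tK1\t\t\t\tfalse\tunknown\tfemale\t25\t\t\t\tHP:0009713",
        "P3\tPMID2\tpatient\t\t\tp.Arg161Ter\t\ttrue\tconfirmed\tmale\t12\t\t\t\tHP:0009713;HP:0009594",
    )


@pytest.fixture
def unit_factory():
    """Build an AnalysisUnit from a phenotype set and a variant description."""

    counter = {"n": 0}

    def make(
        phenotypes,
        variant_type: VariantType = VariantType.MISSENSE,
        codon: int | None = 167,
        ref_aa: str | None = "R",
        alt_aa: str | None = "W",
        level: Resolution = Resolution.PATIENT,
        **kwargs,
    ) -> AnalysisUnit:
        counter["n"] += 1
        if variant_type is not VariantType.MISSENSE:
            ref_aa = alt_aa = None
        variant = VariantAnnotation(
            hgvs_p=f"synthetic-{counter['n']}",
            variant_type=variant_type,
            codon=codon,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
        )
        return AnalysisUnit(
            unit_id=f"U{counter['n']}",
            level=level,
            phenotypes=frozenset(
                p if isinstance(p, Phenotype) else Phenotype(p) for p in phenotypes
            ),
            variant=variant,
            **kwargs,
        )

    return make


@pytest.fixture(scope="session")
def published_patient_views():
    frame = published_counts_fixture("patient")
    records = load_datasheet(io.StringIO(frame.to_csv(sep="\t", index=False)))
    return build_views(records)


@pytest.fixture(scope="session")
def published_family_views():
    frame = published_counts_fixture("family")
    records = load_datasheet(io.StringIO(frame.to_csv(sep="\t", index=False)))
    return build_views(records)
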