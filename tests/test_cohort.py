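"""Datasheet loading, exclusion rules, and the three aggregation views."""

from __future__ import annotations

import pytest

from vhlgp import (
    DatasheetError,
    Phenotype,
    Resolution,
    build_views,
    load_datasheet,
)
from vhlgp.cohort import aggregate_families, aggregate_variants, apply_exclusions

from conftest import sheet


def test_load_well_formed_rows(tiny_sheet):
    records = load_datasheet(tiny_sheet)
    assert len(records) == 3
    assert records[0].phenotypes == {Phenotype.PPGL}
    assert records[2].phenotypes == {Phenotype.CHB, Phenotype.RA}
    assert records[0].age_onset == 30.0


def test_negative_age_names_the_row():
    with pytest.raises(DatasheetError, match=r"case_id=P1.*negative age_onset"):
        load_datasheet(
            sheet("P1\tS1\tpatient\t\t\tp.Arg167Trp\t\ttrue\tunknown\tmale\t-4\t\t\t\tHP:0002666")
        )


def test_missing_mandatory_column():
    import io

    with pytest.raises(DatasheetError, match="hpo_terms"):
        load_datasheet(io.StringIO("case_id\tsource_id\nX\tY\n"))


def test_empty_hpo_terms_kept_then_excluded():
    records = load_datasheet(
        sheet("P1\tS1\tpatient\t\t\tp.Arg167Trp\t\ttrue\tunknown\tmale\t30\t\t\t\t")
    )
    assert records[0].phenotypes == set()
    kept, ledger = apply_exclusions(records)
    assert kept == []
    assert ledger.reasons() == {"no_phenotype": 1}


class TestCommonVariantExclusion:
    def test_af_above_threshold_excluded(self):
        records = load_datasheet(
            sheet("P1\tS1\tpatient\t\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t0.02\tHP:0002666")
        )
        kept, ledger = apply_exclusions(records)
        assert kept == []
        assert ledger.reasons() == {"common_population_variant": 1}

    def test_af_at_boundary_kept(self):
        # the >1% rule is strict: exactly 1% stays in
        records = load_datasheet(
            sheet("P1\tS1\tpatient\t\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t0.01\tHP:0002666")
        )
        kept, ledger = apply_exclusions(records)
        assert len(kept) == 1 and len(ledger) == 0

    def test_compound_het_keeps_rare_allele(self):
        records = load_datasheet(
            sheet(
                "P1\tS1\tpatient\t\t\tp.Arg167Trp;p.Pro25Leu\t\ttrue\tunknown\t\t\t\t\t0.0001;0.03\tHP:0002666"
            )
        )
        assert len(records[0].variants) == 2
        kept, ledger = apply_exclusions(records)
        assert len(kept) == 1 and len(ledger) == 0
        (variant,) = kept[0].variants
        assert variant.hgvs_p == "p.Arg167Trp"


class TestFamilialRescue:
    def test_untested_member_inherits_confirmed_variant(self):
        records = load_datasheet(
            sheet(
                "P1\tS1\tpatient\tK1\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t\tHP:0002666",
                "P2\tS1\tpatient\tK1\t\t\t\tfalse\tunknown\t\t\t\t\t\tHP:0009713",
            )
        )
        kept, ledger = apply_exclusions(records)
        assert len(kept) == 2
        assert kept[1].variant_inherited
        assert kept[1].variant.hgvs_p == "p.Arg167Trp"

    def test_kindreds_scoped_per_source(self):
        # same kindred label in another source publication is a different family
        records = load_datasheet(
            sheet(
                "P1\tS1\tpatient\tK1\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t\tHP:0002666",
                "P2\tS2\tpatient\tK1\t\t\t\tfalse\tunknown\t\t\t\t\t\tHP:0009713",
            )
        )
        kept, ledger = apply_exclusions(records)
        assert len(kept) == 1
        assert ledger.reasons() == {"no_variant": 1}


class TestFamilyAggregation:
    def test_union_of_member_phenotypes(self):
        records = load_datasheet(
            sheet(
                "P1\tS1\tpatient\tK1\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t\tHP:0009713",
                "P2\tS1\tpatient\tK1\t\t\t\tfalse\tunknown\t\t\t\t\t\tHP:0009594",
            )
        )
        kept, _ = apply_exclusions(records)
        units, ledger = aggregate_families(kept, [])
        assert len(units) == 1
        assert units[0].phenotypes == {Phenotype.CHB, Phenotype.RA}
        assert units[0].variant.hgvs_p == "p.Arg167Trp"
        assert len(units[0].member_case_ids) == 2

    def test_no_confirmed_member_excluded(self):
        records = load_datasheet(
            sheet(
                "P1\tS1\tpatient\tK1\t\tp.Arg167Trp\t\tfalse\tunknown\t\t\t\t\t\tHP:0009713",
            )
        )
        units, ledger = aggregate_families(records, [])
        assert units == []
        assert ledger.reasons() == {"no_confirmed_member": 1}

    def test_conflicting_confirmed_variants_flagged(self):
        records = load_datasheet(
            sheet(
                "P1\tS1\tpatient\tK1\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t\tHP:0009713",
                "P2\tS1\tpatient\tK1\t\tp.Tyr98His\t\ttrue\tunknown\t\t\t\t\t\tHP:0009594",
            )
        )
        units, ledger = aggregate_families(records, [])
        assert units == []
        assert ledger.reasons() == {"conflicting_family_variant": 2}

    def test_singleton_patient_becomes_equivalent_family(self):
        records = load_datasheet(
            sheet("P1\tS1\tpatient\t\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t\tHP:0002666")
        )
        units, _ = aggregate_families(records, [])
        assert len(units) == 1
        assert units[0].phenotypes == records[0].phenotypes

    def test_adding_member_never_removes_phenotypes(self):
        base = [
            "P1\tS1\tpatient\tK1\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t\tHP:0009713",
        ]
        extra = "P2\tS1\tpatient\tK1\t\t\t\tfalse\tunknown\t\t\t\t\t\tHP:0009594"
        small, _ = aggregate_families(
            apply_exclusions(load_datasheet(sheet(*base)))[0], []
        )
        large, _ = aggregate_families(
            apply_exclusions(load_datasheet(sheet(*base, extra)))[0], []
        )
        assert small[0].phenotypes <= large[0].phenotypes


class TestVariantAggregation:
    def test_same_variant_unions_phenotypes(self):
        records = load_datasheet(
            sheet(
                "P1\tS1\tpatient\t\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t\tHP:0002666",
                "P2\tS2\tpatient\t\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t\tHP:0002666",
                "V1\tS3\tvariant\t\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t\tHP:0030088",
            )
        )
        units = aggregate_variants(records)
        assert len(units) == 1
        assert units[0].phenotypes == {Phenotype.PPGL, Phenotype.PNET}

    def test_distinct_variants_stay_separate(self):
        records = load_datasheet(
            sheet(
                "P1\tS1\tpatient\t\t\tp.Arg167Trp\t\ttrue\tunknown\t\t\t\t\t\tHP:0002666",
                "P2\tS1\tpatient\t\t\tp.Tyr98His\t\ttrue\tunknown\t\t\t\t\t\tHP:0009713",
            )
        )
        assert len(aggregate_variants(records)) == 2

    def test_tumor_only_variant_in_variant_view_only(self):
        records = load_datasheet(
            sheet("T1\tS1\ttumor\t\t\tp.Ser80Ile\t\ttrue\tunknown\t\t\t\t\t\tHP:0002666")
        )
        views = build_views(records)
        assert views.patients == [] and views.families == []
        assert len(views.variants) == 1


def test_record_conservation_by_reason_code(tiny_sheet):
    records = load_datasheet(tiny_sheet)
    kept, ledger = apply_exclusions(records)
    assert len(kept) + len(ledger) == len(records)


def test_build_views_deterministic(tiny_sheet):
    import copy, io

    text = tiny_sheet.getvalue()
    v1 = build_views(load_datasheet(io.StringIO(text)))
    v2 = build_views(load_datasheet(io.StringIO(text)))
    assert [u.unit_id for u in v1.patients] == [u.unit_id for u in v2.patients]
    assert [u.phenotypes for u in v1.families] == [u.phenotypes for u in v2.families]
    assert sorted(u.unit_id for u in v1.variants) == sorted(
        u.unit_id for u in v2.variants
    )
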