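"""Variant parsing/classification, domain annotation, phenotype mapping."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vhlgp import (
    Phenotype,
    ValidationError,
    VariantAnnotation,
    VariantGroup,
    VariantType,
    annotate_domains,
    classify_variant,
    group_variant,
    map_phenotypes,
)
from vhlgp.datamodel import (
    ALPHA_DOMAIN,
    BETA_DOMAIN,
    ELONGIN_BINDING_SITE,
    GXEEX_REPEAT,
    HIF_BINDING_SITE,
    N_CODONS,
    load_hpo_table,
    normalize_variant_key,
)


@pytest.mark.parametrize(
    "hgvs_c, hgvs_p, declared, expected_type, codon, ref, alt",
    [
        (None, "p.Arg167Trp", None, VariantType.MISSENSE, 167, "R", "W"),
        (None, "p.R167W", None, VariantType.MISSENSE, 167, "R", "W"),
        (None, "p.Arg161Ter", None, VariantType.STOP_GAINED, 161, "R", "*"),
        (None, "p.(Arg161*)", None, VariantType.STOP_GAINED, 161, "R", "*"),
        ("c.340+1G>A", None, None, VariantType.SPLICE_SITE, None, None, None),
        ("c.341-2A>G", None, None, VariantType.SPLICE_SITE, None, None, None),
        ("c.340+15C>T", None, None, VariantType.INTRON, None, None, None),
        ("c.-20C>T", None, None, VariantType.UTR, None, None, None),
        ("c.*5A>G", None, None, VariantType.UTR, None, None, None),
        (None, "p.Ser65fs", None, VariantType.FRAMESHIFT, 65, "S", None),
        (None, "p.Leu63Profs*10", None, VariantType.FRAMESHIFT, 63, "L", None),
        (None, "p.Met1?", None, VariantType.START_LOST, 1, "M", None),
        (None, "p.Met1Val", None, VariantType.START_LOST, 1, "M", "V"),
        (None, "p.Ter214GlnextTer15", None, VariantType.STOP_LOST, None, "*", None),
        (None, "p.Gly93=", None, VariantType.SYNONYMOUS, 93, "G", "G"),
        (None, "p.Val74del", None, VariantType.INFRAME_INDEL, 74, "V", None),
        (None, "p.Val74_Gly76del", None, VariantType.INFRAME_INDEL, 74, "V", None),
        (None, "p.Val74_His115del", None, VariantType.DELETION, 74, "V", None),
        (None, "p.Val74delinsGly", None, VariantType.DELINS, 74, "V", None),
        ("c.1_553del", None, None, VariantType.DELETION, None, None, None),
        (None, None, "exon loss", VariantType.EXON_LOSS, None, None, None),
        (None, None, "Missense", VariantType.MISSENSE, None, None, None),
        (None, "garbled", None, VariantType.UNKNOWN, None, None, None),
    ],
)
def test_classify_variant(hgvs_c, hgvs_p, declared, expected_type, codon, ref, alt):
    ann = classify_variant(hgvs_c, hgvs_p, declared)
    assert ann.variant_type is expected_type
    assert ann.codon == codon
    if expected_type is VariantType.MISSENSE and codon is not None:
        assert (ann.ref_aa, ann.alt_aa) == (ref, alt)


def test_classify_requires_some_descriptor():
    with pytest.raises(ValidationError):
        classify_variant(None, None, None)


def test_codon_out_of_range_rejected():
    with pytest.raises(ValidationError, match="outside"):
        classify_variant(hgvs_p="p.Arg250Trp")


def test_missense_with_identical_residues_rejected():
    with pytest.raises(ValidationError):
        VariantAnnotation(
            variant_type=VariantType.MISSENSE, codon=10, ref_aa="A", alt_aa="A"
        )


@pytest.mark.parametrize(
    "vtype, expected",
    [
        (VariantType.STOP_GAINED, VariantGroup.TRUNCATING),
        (VariantType.FRAMESHIFT, VariantGroup.TRUNCATING),
        (VariantType.DELETION, VariantGroup.TRUNCATING),
        (VariantType.EXON_LOSS, VariantGroup.TRUNCATING),
        (VariantType.SPLICE_SITE, VariantGroup.TRUNCATING),
        (VariantType.START_LOST, VariantGroup.TRUNCATING),
        (VariantType.MISSENSE, VariantGroup.NONTRUNCATING),
        (VariantType.INFRAME_INDEL, VariantGroup.NONTRUNCATING),
        (VariantType.DELINS, VariantGroup.NONTRUNCATING),
        (VariantType.STOP_LOST, VariantGroup.NONTRUNCATING),
        (VariantType.SYNONYMOUS, VariantGroup.EXCLUDED),
        (VariantType.UTR, VariantGroup.EXCLUDED),
        (VariantType.INTRON, VariantGroup.EXCLUDED),
        (VariantType.UNKNOWN, VariantGroup.EXCLUDED),
    ],
)
def test_group_variant_total_mapping(vtype, expected):
    ann = VariantAnnotation(
        variant_type=vtype,
        codon=100 if vtype is VariantType.MISSENSE else None,
        ref_aa="A" if vtype is VariantType.MISSENSE else None,
        alt_aa="V" if vtype is VariantType.MISSENSE else None,
    )
    assert group_variant(ann) is expected


def test_every_variant_type_is_grouped():
    covered = set()
    for vtype in VariantType:
        ann = VariantAnnotation(
            variant_type=vtype,
            codon=100 if vtype is VariantType.MISSENSE else None,
            ref_aa="A" if vtype is VariantType.MISSENSE else None,
            alt_aa="V" if vtype is VariantType.MISSENSE else None,
        )
        covered.add(group_variant(ann))
    assert covered == set(VariantGroup)


class TestDomains:
    def test_codon_167_alpha_only(self):
        flags = annotate_domains(167)
        assert flags.in_alpha and not flags.in_beta
        assert not flags.in_hif and not flags.in_elongin and not flags.in_repeat

    def test_codon_79_triple_membership(self):
        flags = annotate_domains(79)
        assert flags.in_beta and flags.in_hif and flags.in_elongin
        assert not flags.in_alpha

    def test_codon_30_repeat_only(self):
        flags = annotate_domains(30)
        assert flags.in_repeat
        assert not any([flags.in_alpha, flags.in_beta, flags.in_hif, flags.in_elongin])

    @pytest.mark.parametrize("codon", [0, -1, 214, 1000])
    def test_out_of_range(self, codon):
        with pytest.raises(ValidationError):
            annotate_domains(codon)

    def test_exhaustive_consistency_with_set_arithmetic(self):
        # independent re-statement of the interval/set definitions
        alpha = set(range(156, 205))
        beta = set(range(63, 144))
        hif = {67, 69, 75, 77, 78, 79, 88, 91, 98, 99, 105, 106, 107, 108,
               109, 110, 111, 112, 115, 117}
        elongin = {79, 153, 159, 161, 162, 163, 165, 166, 174, 177, 178, 184}
        repeat = set(range(14, 54))
        for codon in range(1, N_CODONS + 1):
            flags = annotate_domains(codon)
            assert flags.in_alpha == (codon in alpha)
            assert flags.in_beta == (codon in beta)
            assert flags.in_hif == (codon in hif)
            assert flags.in_elongin == (codon in elongin)
            assert flags.in_repeat == (codon in repeat)

    def test_functional_sites_nest_in_structural_domains(self):
        assert HIF_BINDING_SITE <= BETA_DOMAIN | {67, 69, 75}
        assert HIF_BINDING_SITE <= set(range(63, 144))
        assert (ELONGIN_BINDING_SITE - {79}) <= ALPHA_DOMAIN | {153}
        assert GXEEX_REPEAT == frozenset(range(14, 54))


class TestPhenotypeMapping:
    def test_single_term(self):
        groups, unmapped = map_phenotypes({"HP:0009713"})
        assert groups == {Phenotype.CHB}
        assert unmapped == set()

    def test_two_members_of_one_group_collapse(self):
        groups, _ = map_phenotypes({"HP:0009713", "HP:0006880"})
        assert groups == {Phenotype.CHB}

    def test_empty(self):
        assert map_phenotypes(set()) == (set(), set())

    def test_unmapped_reported_not_dropped(self):
        groups, unmapped = map_phenotypes({"HP:0009713", "HP:9999999"})
        assert groups == {Phenotype.CHB}
        assert unmapped == {"HP:9999999"}

    def test_chb_contains_required_terms(self):
        table = load_hpo_table()
        for term in ("HP:0009713", "HP:0006880", "HP:0010797"):
            assert table[term] is Phenotype.CHB

    def test_each_term_maps_to_exactly_one_group(self):
        table = load_hpo_table()
        assert all(isinstance(group, Phenotype) for group in table.values())
        assert set(table.values()) == set(Phenotype)

    @settings(max_examples=50, derandomize=True)
    @given(
        terms=st.lists(
            st.sampled_from(sorted(load_hpo_table()) + ["HP:0000001"]),
            max_size=8,
        )
    )
    def test_idempotent_and_order_independent(self, terms):
        groups, unmapped = map_phenotypes(terms)
        again, unmapped2 = map_phenotypes(sorted(terms, reverse=True))
        assert (groups, unmapped) == (again, unmapped2)
        # idempotence: mapping the collapsed groups' member terms changes nothing
        assert map_phenotypes(set(terms))[0] == groups


def test_variant_key_normalization():
    a = classify_variant(hgvs_p="p.Arg167Trp")
    b = classify_variant(hgvs_p=" p.ARG167TRP ")
    assert normalize_variant_key(a) == normalize_variant_key(b) == "p.r167w"
    c = classify_variant(hgvs_c="c.340+1G>A")
    assert normalize_variant_key(c) == "c.340+1g>a"
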