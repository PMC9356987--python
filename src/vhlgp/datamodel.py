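"""Domain types for germline VHL variant cohorts.

The VHL tumor-suppressor protein (transcript NM_000551.3) has 213 codons.
This module defines the vocabulary every analysis stage shares: variant
annotations parsed from HGVS-style c./p. descriptions, the truncating /
nontruncating grouping, the protein domain map (structural alpha/beta
domains, HIF-alpha and Elongin B/C binding sites, the (GXEEX)8 repeat),
the combined phenotype groups built from Human Phenotype Ontology terms,
and the curated case record.

HGVS parsing here is deliberately "HGVS-lite": a regular grammar for
protein substitutions / frameshifts / in-frame indels / extension variants
and for coding-DNA intronic and UTR offsets.  It does not validate
descriptions against the transcript sequence.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "N_CODONS",
    "VariantType",
    "VariantGroup",
    "Phenotype",
    "Resolution",
    "Sex",
    "DeNovo",
    "VariantAnnotation",
    "DomainFlags",
    "CaseRecord",
    "VhlError",
    "VariantParseError",
    "ValidationError",
    "ALPHA_DOMAIN",
    "BETA_DOMAIN",
    "HIF_BINDING_SITE",
    "ELONGIN_BINDING_SITE",
    "GXEEX_REPEAT",
    "ANALYSIS_PHENOTYPES",
    "classify_variant",
    "group_variant",
    "annotate_domains",
    "map_phenotypes",
    "load_hpo_table",
    "normalize_variant_key",
]

#: Length of the VHL protein in codons (NM_000551.3).
N_CODONS = 213


class VhlError(Exception):
    """Base class for errors raised by this package."""


class VariantParseError(VhlError):
    """A variant description could not be interpreted."""


class ValidationError(VhlError):
    """Input violated a documented contract (e.g. codon out of range)."""


class VariantType(str, Enum):
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    DELETION = "deletion"
    EXON_LOSS = "exon_loss"
    SPLICE_SITE = "splice_site"
    INFRAME_INDEL = "inframe_indel"
    DELINS = "delins"
    SYNONYMOUS = "synonymous"
    INTRON = "intron"
    UTR = "utr"
    START_LOST = "start_lost"
    STOP_LOST = "stop_lost"
    UNKNOWN = "unknown"


class VariantGroup(str, Enum):
    TRUNCATING = "truncating"
    NONTRUNCATING = "nontruncating"
    EXCLUDED = "excluded"


#: Variant types predicted to truncate or abolish the protein.
TRUNCATING_TYPES = frozenset(
    {
        VariantType.STOP_GAINED,
        VariantType.FRAMESHIFT,
        VariantType.DELETION,
        VariantType.EXON_LOSS,
        VariantType.SPLICE_SITE,
        VariantType.START_LOST,
    }
)
#: Variant types leaving the reading frame intact.
NONTRUNCATING_TYPES = frozenset(
    {
        VariantType.MISSENSE,
        VariantType.INFRAME_INDEL,
        VariantType.DELINS,
        VariantType.STOP_LOST,
    }
)
#: Types excluded from the truncating/nontruncating contingency analyses.
EXCLUDED_TYPES = frozenset(
    {
        VariantType.SYNONYMOUS,
        VariantType.UTR,
        VariantType.INTRON,
        VariantType.UNKNOWN,
    }
)


class Phenotype(str, Enum):
    """Combined VHL phenotype groups (each aggregates several HPO terms)."""

    CHB = "CHB"  # CNS hemangioblastoma
    RA = "RA"  # retinal angioma
    PPGL = "PPGL"  # pheochromocytoma / paraganglioma
    RCC = "RCC"  # renal cell carcinoma
    PNET = "PNET"  # pancreatic neuroendocrine tumor
    ELST = "ELST"  # endolymphatic sac tumor
    PCT = "PCT"  # pancreatic cysts or tumors
    RCT = "RCT"  # renal cysts or tumors
    ECT = "ECT"  # epididymal cysts or tumors
    OCT = "OCT"  # ovarian cysts or tumors


#: The seven groups carried through the statistical analyses.
ANALYSIS_PHENOTYPES = (
    Phenotype.PNET,
    Phenotype.PPGL,
    Phenotype.CHB,
    Phenotype.RA,
    Phenotype.RCC,
    Phenotype.RCT,
    Phenotype.PCT,
)


class Resolution(str, Enum):
    PATIENT = "patient"
    FAMILY = "family"
    VARIANT = "variant"
    TUMOR = "tumor"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class DeNovo(str, Enum):
    CONFIRMED = "confirmed"  # both parental tests negative
    NO = "no"
    UNKNOWN = "unknown"


# ---------------------------------------------------------------------------
# Protein domain map
# ---------------------------------------------------------------------------

#: Structural alpha domain, codons 156-204 inclusive.
ALPHA_DOMAIN = frozenset(range(156, 205))
#: Structural beta domain, codons 63-143 inclusive.
BETA_DOMAIN = frozenset(range(63, 144))
#: HIF-alpha binding site residues.
HIF_BINDING_SITE = frozenset(
    {67, 69, 75, 77, 78, 79, 88, 91, 98, 99} | set(range(105, 113)) | {115, 117}
)
#: Elongin B/C binding site residues (codon 79 is shared with the HIF site).
ELONGIN_BINDING_SITE = frozenset(
    {79, 153, 159, 161, 162, 163, 165, 166, 174, 177, 178, 184}
)
#: (GXEEX)8 tandem repeat, codons 14-53 inclusive.
GXEEX_REPEAT = frozenset(range(14, 54))


@dataclass(frozen=True)
class DomainFlags:
    in_alpha: bool
    in_beta: bool
    in_hif: bool
    in_elongin: bool
    in_repeat: bool


def annotate_domains(codon: int) -> DomainFlags:
    """Flag the structural and functional regions containing ``codon``.

    Raises :class:`ValidationError` if the codon is outside 1..213.  All five
    flags may be false (codons outside every region).
    """
    if not isinstance(codon, (int,)) or isinstance(codon, bool):
        raise ValidationError(f"codon must be an integer, got {codon!r}")
    if not 1 <= codon <= N_CODONS:
        raise ValidationError(f"codon {codon} outside 1..{N_CODONS}")
    return DomainFlags(
        in_alpha=codon in ALPHA_DOMAIN,
        in_beta=codon in BETA_DOMAIN,
        in_hif=codon in HIF_BINDING_SITE,
        in_elongin=codon in ELONGIN_BINDING_SITE,
        in_repeat=codon in GXEEX_REPEAT,
    )


# ---------------------------------------------------------------------------
# Variant annotation
# ---------------------------------------------------------------------------

_AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Sec": "U",
}
_AA_1 = set("ACDEFGHIKLMNPQRSTVWYU*")


def _aa1(token: str) -> str:
    """Canonicalize an amino-acid token to its one-letter code."""
    if token in _AA_3TO1:
        return _AA_3TO1[token]
    if token in ("*", "X", "Ter"):
        return "*"
    if len(token) == 1 and token.upper() in _AA_1:
        return token.upper()
    raise VariantParseError(f"unrecognized amino-acid token {token!r}")


@dataclass(frozen=True)
class VariantAnnotation:
    """A parsed and classified VHL variant.

    ``codon`` is the 1-based protein residue (first residue number of the
    p. description) and must lie in 1..213 when present.
    """

    hgvs_c: str | None = None
    hgvs_p: str | None = None
    variant_type: VariantType = VariantType.UNKNOWN
    codon: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    gnomad_af: float | None = None

    def __post_init__(self) -> None:
        if self.codon is not None and not 1 <= self.codon <= N_CODONS:
            raise ValidationError(
                f"codon {self.codon} outside 1..{N_CODONS} "
                f"(variant {self.hgvs_p or self.hgvs_c!r})"
            )
        if self.variant_type is VariantType.MISSENSE:
            # A parsed p. substitution always carries codon/ref/alt; an
            # annotation typed missense by the declared-type fallback may
            # lack them (it then simply cannot enter codon-level tallies).
            fields = (self.codon, self.ref_aa, self.alt_aa)
            if any(f is not None for f in fields) and not all(
                f is not None for f in fields
            ):
                raise ValidationError(
                    f"missense variant requires codon/ref/alt together "
                    f"({self.hgvs_p or self.hgvs_c!r})"
                )
            if self.ref_aa is not None and self.ref_aa == self.alt_aa:
                raise ValidationError(
                    f"missense with identical ref/alt amino acids "
                    f"({self.hgvs_p!r})"
                )
        if self.gnomad_af is not None and not 0.0 <= self.gnomad_af <= 1.0:
            raise ValidationError(f"gnomad_af {self.gnomad_af} outside [0, 1]")

    @property
    def group(self) -> VariantGroup:
        return group_variant(self)


def group_variant(annotation: VariantAnnotation) -> VariantGroup:
    """Map a variant to the truncating / nontruncating / excluded grouping.

    Stop-gained, frameshift, deletion, exon-loss, splice-site and start-lost
    variants are truncating; missense, in-frame indels, delins and stop-lost
    are nontruncating; synonymous, UTR, intronic and unparseable variants are
    excluded from the grouping.  The mapping is total over variant types.
    """
    vt = annotation.variant_type
    if vt in TRUNCATING_TYPES:
        return VariantGroup.TRUNCATING
    if vt in NONTRUNCATING_TYPES:
        return VariantGroup.NONTRUNCATING
    return VariantGroup.EXCLUDED


_P_DESC_RE = re.compile(
    r"^(?P<ref>[A-Z][a-z]{2}|[A-Z*])(?P<pos>\d+)(?P<rest>.*)$"
)
_P_RANGE_RE = re.compile(
    r"^_(?P<ref2>[A-Z][a-z]{2}|[A-Z*])(?P<pos2>\d+)(?P<op>del|dup|ins|delins)"
)
_C_INTRON_RE = re.compile(r"[cg]?\.?\*?-?\d+(?P<sign>[+-])(?P<offset>\d+)")

_DECLARED_TYPE_ALIASES: dict[str, VariantType] = {
    "missense": VariantType.MISSENSE,
    "missense variant": VariantType.MISSENSE,
    "stop gained": VariantType.STOP_GAINED,
    "stop gain": VariantType.STOP_GAINED,
    "nonsense": VariantType.STOP_GAINED,
    "frameshift": VariantType.FRAMESHIFT,
    "frameshift variant": VariantType.FRAMESHIFT,
    "deletion": VariantType.DELETION,
    "exon loss": VariantType.EXON_LOSS,
    "exon loss variant": VariantType.EXON_LOSS,
    "exon deletion": VariantType.EXON_LOSS,
    "splice": VariantType.SPLICE_SITE,
    "splice site": VariantType.SPLICE_SITE,
    "splice site variant": VariantType.SPLICE_SITE,
    "inframe indel": VariantType.INFRAME_INDEL,
    "inframe deletion": VariantType.INFRAME_INDEL,
    "inframe insertion": VariantType.INFRAME_INDEL,
    "delins": VariantType.DELINS,
    "synonymous": VariantType.SYNONYMOUS,
    "synonymous variant": VariantType.SYNONYMOUS,
    "intron": VariantType.INTRON,
    "intron variant": VariantType.INTRON,
    "utr": VariantType.UTR,
    "utr region variant": VariantType.UTR,
    "start lost": VariantType.START_LOST,
    "stop lost": VariantType.STOP_LOST,
    "unknown": VariantType.UNKNOWN,
}

#: In-frame deletions spanning more than this many residues are classed as
#: (truncating) deletions rather than in-frame indels.
INFRAME_DELETION_MAX_SPAN = 5


def _normalize_declared(declared: str) -> VariantType:
    key = re.sub(r"[_\-]+", " ", declared.strip().lower())
    key = re.sub(r"\s+", " ", key)
    if key in _DECLARED_TYPE_ALIASES:
        return _DECLARED_TYPE_ALIASES[key]
    try:
        return VariantType(key.replace(" ", "_"))
    except ValueError:
        return VariantType.UNKNOWN


def _parse_p(desc: str) -> dict | None:
    """Parse a protein-level description; return fields or None."""
    body = desc.strip()
    body = re.sub(r"^p\.", "", body)
    body = body.strip("()")
    if not body or body in ("?", "0"):
        return None
    m = _P_DESC_RE.match(body)
    if not m:
        return None
    ref = _aa1(m.group("ref"))
    pos = int(m.group("pos"))
    rest = m.group("rest")

    out: dict = {"codon": pos, "ref_aa": ref, "alt_aa": None, "type": None}

    if "fs" in rest:
        out["type"] = VariantType.FRAMESHIFT
        return out
    if rest == "=":
        out["type"] = VariantType.SYNONYMOUS
        out["alt_aa"] = ref
        return out
    if rest in ("?", ""):
        if ref == "M" and pos == 1:
            out["type"] = VariantType.START_LOST
        else:
            return None
        return out
    range_m = _P_RANGE_RE.match(rest)
    if range_m:
        pos2 = int(range_m.group("pos2"))
        op = range_m.group("op")
        span = pos2 - pos + 1
        if op == "delins":
            out["type"] = VariantType.DELINS
        elif op == "del" and span > INFRAME_DELETION_MAX_SPAN:
            out["type"] = VariantType.DELETION
        else:
            out["type"] = VariantType.INFRAME_INDEL
        return out
    if rest.startswith("delins"):
        out["type"] = VariantType.DELINS
        return out
    if rest.startswith(("del", "dup", "ins")):
        out["type"] = VariantType.INFRAME_INDEL
        return out
    if "ext" in rest:
        out["type"] = VariantType.STOP_LOST if ref == "*" else VariantType.UNKNOWN
        return out
    # plain substitution target
    try:
        alt = _aa1(rest)
    except VariantParseError:
        return None
    out["alt_aa"] = alt
    if ref == "M" and pos == 1 and alt != ref:
        out["type"] = VariantType.START_LOST
    elif alt == "*":
        out["type"] = VariantType.STOP_GAINED
    elif ref == "*":
        out["type"] = VariantType.STOP_LOST
    elif alt == ref:
        out["type"] = VariantType.SYNONYMOUS
    else:
        out["type"] = VariantType.MISSENSE
    return out


def _parse_c(desc: str) -> VariantType | None:
    """Infer a variant type from a coding-DNA description alone."""
    body = desc.strip()
    body = re.sub(r"^c\.", "", body)
    if not body:
        return None
    if body.startswith("-") or body.startswith("*"):
        return VariantType.UTR
    m = _C_INTRON_RE.search("c." + body)
    if m:
        return (
            VariantType.SPLICE_SITE
            if int(m.group("offset")) <= 2
            else VariantType.INTRON
        )
    if "delins" in body:
        return VariantType.DELINS
    if "del" in body:
        return VariantType.DELETION
    return None


def classify_variant(
    hgvs_c: str | None = None,
    hgvs_p: str | None = None,
    declared_type: str | None = None,
    gnomad_af: float | None = None,
) -> VariantAnnotation:
    """Parse HGVS-style descriptions into a classified :class:`VariantAnnotation`.

    The protein description, when parseable, determines the variant type and
    the affected codon (first residue number).  Coding-DNA-only descriptions
    cover intronic/splice-site (offset |1|,|2| from the exon boundary) and UTR
    patterns.  ``declared_type`` is the fallback when neither description is
    informative; a record that cannot be interpreted at all is returned with
    ``variant_type=unknown`` rather than raising, so the caller can ledger it.

    A residue number outside 1..213 raises :class:`ValidationError`, except
    for stop-lost variants described at the natural stop (residue 214), whose
    codon is recorded as absent.
    """
    if not any(x is not None and str(x).strip() for x in (hgvs_c, hgvs_p, declared_type)):
        raise ValidationError("at least one of hgvs_c, hgvs_p, declared_type is required")

    hgvs_c = hgvs_c.strip() if hgvs_c and hgvs_c.strip() else None
    hgvs_p = hgvs_p.strip() if hgvs_p and hgvs_p.strip() else None

    parsed = _parse_p(hgvs_p) if hgvs_p else None
    vt: VariantType | None = None
    codon = ref_aa = alt_aa = None
    if parsed is not None:
        vt = parsed["type"]
        codon, ref_aa, alt_aa = parsed["codon"], parsed["ref_aa"], parsed["alt_aa"]
        if vt is VariantType.STOP_LOST and codon == N_CODONS + 1:
            codon = None  # description at the natural stop codon
    if vt is None and hgvs_c:
        vt = _parse_c(hgvs_c)
        codon = ref_aa = alt_aa = None
    if vt is None and declared_type:
        vt = _normalize_declared(declared_type)
    if vt is None:
        vt = VariantType.UNKNOWN
    if vt is not VariantType.MISSENSE and vt is not VariantType.SYNONYMOUS \
            and vt is not VariantType.STOP_GAINED and parsed is None:
        ref_aa = alt_aa = None
    return VariantAnnotation(
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        variant_type=vt,
        codon=codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        gnomad_af=gnomad_af,
    )


def normalize_variant_key(annotation: VariantAnnotation) -> str:
    """Identity key for variant-level aggregation.

    Case-insensitive, whitespace-stripped; three-letter amino-acid codes in
    p. descriptions are canonicalized to one-letter before keying; the c.
    description is preferred when present.
    """
    if annotation.hgvs_c:
        return re.sub(r"\s+", "", annotation.hgvs_c).lower()
    if annotation.hgvs_p:
        body = re.sub(r"\s+", "", annotation.hgvs_p)
        names = "|".join(n for n in _AA_3TO1 if n != "Sec")
        body = re.sub(
            f"(?i)({names})",
            lambda m: _AA_3TO1[m.group(0).title()],
            body,
        )
        return body.lower()
    return f"type:{annotation.variant_type.value}"


# ---------------------------------------------------------------------------
# Phenotype mapping
# ---------------------------------------------------------------------------

_HPO_TABLE_CACHE: dict[str, Phenotype] | None = None


def load_hpo_table(path: str | None = None) -> dict[str, Phenotype]:
    """Load the HPO term -> phenotype-group mapping.

    By default the bundled versioned TSV (columns ``hpo_id``, ``group``) is
    used; pass a path to extend or replace it.  Each term maps to exactly one
    group.
    """
    global _HPO_TABLE_CACHE
    if path is None and _HPO_TABLE_CACHE is not None:
        return dict(_HPO_TABLE_CACHE)
    if path is None:
        source = resources.files("vhlgp.data").joinpath("hpo_groups.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    table: dict[str, Phenotype] = {}
    reader = csv.DictReader(
        (line for line in text.splitlines() if line and not line.startswith("#")),
        delimiter="\t",
    )
    for row in reader:
        hpo_id = row["hpo_id"].strip()
        group = Phenotype(row["group"].strip())
        if hpo_id in table and table[hpo_id] is not group:
            raise ValidationError(f"HPO term {hpo_id} mapped to two groups")
        table[hpo_id] = group
    if path is None:
        _HPO_TABLE_CACHE = dict(table)
    return table


def map_phenotypes(
    hpo_terms: Iterable[str],
    table: Mapping[str, Phenotype] | None = None,
) -> tuple[set[Phenotype], set[str]]:
    """Collapse HPO terms onto combined phenotype groups.

    Returns ``(groups, unmapped)``.  Mapping is idempotent and
    order-independent; duplicate terms collapse; unmapped terms are reported,
    never silently dropped.
    """
    if table is None:
        table = load_hpo_table()
    groups: set[Phenotype] = set()
    unmapped: set[str] = set()
    for term in hpo_terms:
        term = term.strip()
        if not term:
            continue
        if term in table:
            groups.add(table[term])
        else:
            unmapped.add(term)
    return groups, unmapped


# ---------------------------------------------------------------------------
# Case record
# ---------------------------------------------------------------------------


@dataclass
class CaseRecord:
    """One curated case from the datasheet.

    ``variants`` may hold two annotations for compound-heterozygous records;
    exclusion filtering reduces it to at most one (the rare allele).
    ``phenotypes`` are the mapped groups; raw HPO ids are kept alongside.
    """

    case_id: str
    source_id: str
    resolution: Resolution
    kindred_id: str | None = None
    variants: list[VariantAnnotation] = field(default_factory=list)
    genotype_confirmed: bool = False
    de_novo: DeNovo = DeNovo.UNKNOWN
    sex: Sex = Sex.UNKNOWN
    age_onset: float | None = None
    age_death: float | None = None
    last_known_age: float | None = None
    hpo_terms: set[str] = field(default_factory=set)
    phenotypes: set[Phenotype] = field(default_factory=set)
    unmapped_terms: set[str] = field(default_factory=set)
    variant_inherited: bool = False  # set by the familial-variant rule

    @property
    def variant(self) -> VariantAnnotation | None:
        return self.variants[0] if self.variants else None
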