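# Methods

This note documents the statistical procedures, the modelling assumptions
behind the synthetic-cohort generator, and the numerical and design choices
made where the problem left the design open.

## Cohort model and admission rules

A curated cohort is a list of cases at four resolutions: *patient*
(individual-level data), *family* (data aggregated by kindred), *variant*
(data aggregated by unique variant), and *tumor* (single-tumor-type
reports). Analyses run at three levels:

* **patient** — patient-resolution cases only;
* **family** — patient cases grouped by their kindred ID *within one source
  publication* (the same kindred label in two papers is two families; a
  cross-source merge requires an explicit curated alias), plus
  family-resolution cases. A family is admitted only if at least one member
  is genetically confirmed; clinically diagnosed but untested members are
  assumed to carry the familial variant for analysis only. Kindreds whose
  confirmed members carry distinct variants cannot be resolved and are
  excluded with a `conflicting_family_variant` flag.
* **variant** — one unit per unique variant across all four resolutions,
  keyed on the whitespace-stripped, case-folded description with
  three-letter amino-acid codes canonicalized to one letter (c. preferred
  over p. when both exist).

Admission requires both a variant and at least one mapped phenotype group.
Variants with gnomAD global MAF strictly above 1% are removed as common
population variants; in compound-heterozygous records with one common
allele, only the common allele is removed and the patient is kept as
heterozygous for the rare one. Every dropped record lands in an exclusion
ledger with a reason code, so kept + excluded always reconstructs the
input. Missing demographics are handled by pairwise deletion: each
statistic uses all units carrying the fields it needs; nothing is imputed.

## Variant classification

HGVS parsing is deliberately "HGVS-lite": a regular grammar covering
protein substitutions (missense / synonymous / stop-gained), frameshifts,
in-frame del/dup/ins/delins, start-lost (`p.Met1?` and Met1 substitutions),
stop-lost (`ext` variants at the natural stop), and coding-DNA intronic and
UTR offsets (±1, 2 from an exon boundary → splice site; deeper → intronic).
There is no transcript-sequence validation — descriptions are taken at
face value, with codons checked against the 1-based 1..213 protein range.
A `variant_type` column in the datasheet serves as fallback for
descriptions the grammar cannot interpret (e.g. "exon loss"); a record
with no interpretable descriptor is typed `unknown` and carried to the
ledger, never silently dropped.

In-frame p.-level deletions spanning more than 5 residues are classed as
(truncating) deletions rather than in-frame indels; the cutoff is a
package choice — single-residue and short in-frame deletions behave like
local perturbations, while multi-residue losses remove substantial
structure. Start-lost is grouped truncating (loss of initiation);
stop-lost and in-frame delins nontruncating; synonymous, UTR, intronic and
unknown variants are excluded from the truncating/nontruncating analyses.

The protein domain map: α-domain codons 156–204, β-domain 63–143 (both
inclusive), HIF-α binding site {67, 69, 75, 77–79, 88, 91, 98–99, 105–112,
115, 117}, Elongin B/C binding site {79, 153, 159, 161–163, 165–166, 174,
177–178, 184} (codon 79 belongs to both functional sites and counts in
both), and the (GXEEX)8 repeat 14–53.

Phenotype mapping collapses HPO terms onto ten combined groups (CHB, RA,
PPGL, RCC, PNET, ELST, PCT, RCT, ECT, OCT) through a bundled, versioned
TSV that users can extend; seven groups (PNET, PPGL, CHB, RA, RCC, RCT,
PCT) enter the statistical analyses. Two deliberate parent-term
assignments: "Hemangioblastoma" belongs to CHB (not RA) and
"Neuroendocrine neoplasm" to PPGL (not PNET). Unmapped terms are reported,
never dropped. No ontology-graph traversal is performed — the table is a
fixed term → group map, and curation-time reasoning over the HPO DAG is
upstream of this package.

## Co-occurrence ratio

The ratio formula is a package design choice (only the scaling to [0, 1]
per manifestation and the banding are externally fixed): we use the
conditional co-occurrence `r[a,b] = C[a,b] / C[a,a]` — the fraction of
*a*-carrying units that also carry *b* — as the simplest statistic
consistent with pairwise likelihoods per manifestation and an asymmetric
per-row heatmap. Each row of `r` (diagonal excluded) is min–max scaled;
bands are low [0, 0.33], moderate (0.33, 0.66], high (0.66, 1]. A constant
row cannot be scaled: it is set to 0 and flagged degenerate. The raw and
conditional matrices are always emitted beside the scaled one so
alternative scalings can be audited. Whether to scale before or after
excluding the diagonal is not externally determined; we exclude the
diagonal. No significance testing is attached — bands are descriptive.

## Hotspot tests

Null: each of the *n* missense observations hits any of the 213 codons
with equal probability. Per codon the one-tailed exact binomial tail
`P(X ≥ k)` is computed (scipy's survival function; validated in tests
against an independent log-space pmf-summation oracle), Bonferroni
corrected over m = 213 (α/213 = 2.35 × 10⁻⁴ at α = 0.05); "highly
significant" marks p ≤ (α/213) × 10⁻⁴, i.e. four orders of magnitude
below the corrected level.

BLOSUM90 weighting is a package design choice anchored to two
constraints: adjusted cumulative scores must remain commensurate with raw
counts (published family-level thresholds are non-integer), and more
radical substitutions should count more. Each observation contributes
`w = (b(ref,ref) − b(ref,alt)) / W̄`, where `b` is the BLOSUM90 entry and
`W̄` averages `b(r,r) − b(r,a)` over all 380 ordered non-identical
amino-acid pairs, making the cohort-average weight ≈ 1. The weight
function is a pluggable argument so alternatives (e.g. a shifted
`−b(ref,alt)`) can be swapped. Because adjusted scores are non-integer,
the one-tailed tail is extended continuously as the regularized incomplete
gamma function with rate `s_total / 213` — the continuous Poisson tail,
which agrees with the Poisson sum term-for-term at integer scores and is
strictly decreasing in the score. This is documented as an approximation
to a binomial test on adjusted counts. The BLOSUM90 matrix itself is
Biopython's bundled copy of the standard NCBI matrix; any
substitution-matrix mapping (e.g. read from an NCBI-format file) can be
passed instead.

Published minimum significant counts (≥21 for patients at n = 1339) are
treated as observed minima, not analytic thresholds: the exact
Binomial(1339, 1/213) tail already clears the corrected level at k = 18,
so the printed values reflect the counts actually observed among
significant codons in that dataset.

## Contingency analyses

Pearson χ² without continuity correction throughout — the published
headline statistic on the 7×2 patient table reproduces only without
Yates' correction, and corrected and uncorrected tests coincide
asymptotically at these counts. A unit with k phenotypes increments k
row cells; the resulting non-independence between rows is a property of
the design (units are not partitioned by phenotype) and is inherited
knowingly — reported p-values condition on the table as constructed.
Post-hoc comparisons are 2×2 χ² tests for each of the C(7,2) = 21
phenotype pairs at α/21 ≈ 0.00238; degenerate pairs (zero marginal) are
reported untested rather than erroring the batch. Domain tests count
phenotype occurrences of coding variants in the α vs β structural
domains (disjoint) and in the HIF-α vs Elongin functional sites (codon 79
counts in both); variants in neither structural domain are tallied
separately. Units and observations coincide in these tables because each
admitted unit carries exactly one variant.

## Penetrance

The datasheet records one onset age per patient (first manifestation), so
per-phenotype onset distributions use only patients with exactly one
phenotype, for whom the recorded age unambiguously belongs to that
phenotype. The penetrance curve is the onset-age ECDF among these
affected, isolated-phenotype patients — deliberately not a Kaplan–Meier
estimate: there is no censoring model because every included subject is
affected by construction, and unaffected carriers are not observable in
literature-aggregated data. The median-onset age is the first age at
which the ECDF reaches 0.5. Phenotypes with fewer than `min_n` isolated
observations (default 5, configurable; the rule's exact published value
is unstated) are dropped with a warning, and the KS comparison set is
data-driven accordingly. Pairwise two-sided two-sample KS tests use exact
p-values when n₁·n₂ ≤ 10⁴ and the asymptotic distribution otherwise;
D is computed on the pooled step functions so integer-year ties are
legitimate (scipy falls back to the asymptotic p-value with a warning in
the rare tie patterns its exact routine cannot handle). Significance is
Bonferroni-corrected at α/m with m = k(k−1)/2 pairs.

## Spectral clustering

The patient graph is complete, with edge weights the Jaccard similarity
of phenotype sets; patients without any mapped phenotype are excluded
upstream. No k-nearest-neighbor sparsification is applied — phenotype
sets are tiny and the full affinity is already highly structured.
The spectrum of the symmetric normalized Laplacian
`L = I − D^(−1/2) A D^(−1/2)` is computed densely; the eigengap heuristic
ranks `g_i = λ_{i+1} − λ_i` for i = 2..k_max (K = 1 is excluded as
uninformative; k_max default 15) and returns the two largest-gap positions
as candidate cluster counts, ties breaking toward smaller K. Clustering at
each K follows the Ng–Jordan–Weiss procedure: bottom-K eigenvectors, rows
renormalized to unit length, k-means with a fixed seed and 10 restarts
(best inertia wins), so results are deterministic given (data, K, seed).
Many patients share identical phenotype sets, producing affinity ties; no
jitter is added — determinism is preferred. Genotype never enters the
clustering; it appears only in the per-cluster profiles (phenotype
fractions, truncating/nontruncating counts, α/β/neither domain counts,
codon histograms) computed afterwards, so any genotype contrast between
clusters is a genuine genotype–phenotype association, not an artifact of
the similarity.

## Synthetic cohorts

The generator emulates the datasheet schema family-first. Each kindred
draws a latent genotype class — by default a type 1-like class
(truncating, β-domain; CHB/RCC elevated, PPGL rare) with weight 0.65 and
a type 2-like class (nontruncating, α-domain; PPGL-dominant with PNET)
with weight 0.35 — then one variant consistent with the class: the type
from cohort-scale frequencies (missense 0.624, stop-gained 0.080,
frameshift 0.078, ... ) renormalized within the class's group, and for
codon-bearing types a codon uniform over the class's domain interval with
planted hotspot multipliers (defaults 167 ×10, 161 ×6) applied to
missense draws. Member phenotypes are conditionally independent Bernoulli
draws given the class — the simplest structure that induces co-occurrence
and clusterability; recovered co-occurrence beyond the class structure is
therefore not expected. Onset ages are per-phenotype normal draws
(location/scale defaults: PPGL 16/9, RA 16/10, CHB 36/13, RCC 44/11,
PCT 27/12, RCT 30/13, PNET 30/12 years — medians matching the early-PPGL/
RA, CHB 36, RCC 44, PCT 27 pattern), truncated at 0 and rounded to
integer years, the granularity of literature-derived data; a patient's
onset is the minimum over acquired phenotypes. Field-level missingness,
untested members (20%, exercising the familial rescue), common population
variants (1% of kindreds), de novo confirmations (3.4%), the four
resolution tags, and occasional synonymous/UTR/intronic variants (2%) are
all emulated. Not emulated: publication bias, duplicate patients across
sources, curation noise, and any dependence structure between phenotypes
beyond the latent class — so passing recovery tests demonstrates
correctness of the machinery under the stated model, not robustness to
real-data pathologies. The p. descriptions use a fixed synthetic
213-residue reference sequence (not the real protein sequence); nothing
downstream depends on the actual residues.

Planted-structure helpers define recovery experiments: K classes each
dominated by one exclusive phenotype, with background (non-class-defining)
phenotypes appearing at a configurable noise rate and optional label noise
that swaps a member's phenotype draw to another class. A deterministic
fixture also rebuilds the published patient/family/variant
phenotype × truncating/nontruncating count tables as pseudo-cohorts of
single-phenotype cases (cell counts are exactly what the χ² consumes;
the construction does not reproduce multi-phenotype patient totals), so
the contingency machinery can be exercised against published numbers
end to end.

## Problem sizes and numerical choices

Simulation studies use cohorts of 120–800 families (≈150–1000 patients),
40–100 replicates for power/coverage estimates, and 1000 replicates for
the null family-wise-error calibration at n = 1339 — sizes at which the
Monte-Carlo standard errors are small against the margins being tested.
Binomial tails are exact at all n used; eigendecompositions are dense
(`numpy.linalg.eigh`); χ² p-values come from the asymptotic χ²
distribution, standard at these cell counts. Degenerate inputs fail
loudly and specifically: empty contingency tables, zero marginals (named
row/column), empty phenotype sets reaching the affinity computation,
zero-degree graph nodes, negative BLOSUM scores, and out-of-range codons
all raise validation errors carrying record provenance where available.

## Known limitations

* The truncating assignment of start-lost variants, and the 5-residue
  in-frame-deletion cutoff, are package choices on points the grouping
  convention leaves open; both affect only a handful of variants in
  realistic cohorts but are worth a sensitivity check in applications.
* The co-occurrence ratio and the BLOSUM weighting scheme implement one
  member of a family of plausible definitions (both are pluggable or
  fully audited via emitted intermediate matrices).
* Cross-publication duplicate detection is out of scope: the package
  trusts the curated deduplication upstream.
* χ² rows are not independent for multi-phenotype units (see above);
  interpret post-hoc p-values accordingly.
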