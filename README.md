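# vhlgp

Genotype–phenotype analysis of germline *VHL* variant cohorts.

Von Hippel–Lindau (VHL) disease is an autosomal-dominant tumor-predisposition
syndrome caused by inactivating germline variants in the *VHL* tumor-suppressor
gene (protein of 213 codons, transcript NM_000551.3). Cohorts curated from the
literature arrive as heterogeneous case lists — individual patients, whole
kindreds, unique variants, or single-tumor reports — each carrying HGVS variant
descriptions and Human Phenotype Ontology (HPO) terms. `vhlgp` turns such a
datasheet into the standard battery of genotype–phenotype analyses used in
rare-disease registry studies, and ships a fully seeded synthetic-cohort
generator so every stage is testable end to end without any external data.

It is aimed at clinical geneticists and biostatisticians working with
literature-aggregated rare-disease cohorts.

## What it computes

* **Cohort assembly** — HGVS-lite parsing of c./p. descriptions into variant
  types, the truncating (stop-gained, frameshift, deletion, exon loss, splice,
  start-lost) vs nontruncating (missense, in-frame indel, delins, stop-lost)
  grouping, HPO → phenotype-group mapping, gnomAD common-variant exclusion
  (global MAF > 1%), the familial-variant rescue for untested kindred members,
  and aggregation into patient / family / variant analysis views with a
  complete exclusion ledger.
* **Summary characteristics** — demographics with pairwise deletion,
  phenotype and variant-type frequencies per level, and the
  phenotype × truncating/nontruncating count tables.
* **Phenotype co-occurrence** — conditional ratios `r[a,b] = C[a,b] / C[a,a]`,
  min–max scaled per manifestation to [0, 1] and banded
  (low ≤ 0.33 < moderate ≤ 0.66 < high).
* **Codon hotspots** — for each codon *c* with count *k* of *n* missense
  observations, the exact one-tailed binomial tail
  `p = P(X ≥ k), X ~ Bin(n, 1/213)`, Bonferroni-corrected over m = 213 tests;
  plus a BLOSUM90-adjusted variant in which each observation is weighted by
  its mean-normalized substitution radicality
  `w = (b(ref,ref) − b(ref,alt)) / W̄` and the tail extends continuously
  through the regularized incomplete gamma function (continuous Poisson tail).
* **Contingency analyses** — Pearson χ² (no continuity correction) on the
  phenotype × truncating/nontruncating table with pairwise post-hoc 2×2 tests
  at α/21, and the α-domain (codons 156–204) vs β-domain (63–143) and
  HIF-α vs Elongin B/C binding-site distribution tests.
* **Age-related penetrance** — onset-age empirical CDFs among
  isolated-phenotype patients, median-onset ages, and all-pairs two-sample
  Kolmogorov–Smirnov tests at α/m (exact p-values for n₁·n₂ ≤ 10⁴).
* **Phenotype clustering** — Jaccard similarity between patients' phenotype
  sets, eigengap estimation of the cluster count on the symmetric normalized
  Laplacian (two candidates), Ng–Jordan–Weiss spectral clustering, and
  per-cluster genotype/phenotype profiles. Exposed as the
  scikit-learn-compatible estimator `PhenotypeSpectralClustering`.

## Worked example

```python
import io
from vhlgp import (SimulationConfig, simulate_cohort, load_datasheet, build_views,
                   hotspot_analysis, group_association, summarize)

config = SimulationConfig(seed=42, n_families=800)   # type 1 / type 2 structure,
rows, truth = simulate_cohort(config)                # hotspots planted at 167, 161
views = build_views(load_datasheet(io.StringIO(rows.to_csv(sep="\t", index=False))))
print(f"admitted: {len(views.patients)} patients, {len(views.families)} families, "
      f"{len(views.variants)} unique variants")

table = hotspot_analysis(views.patients)
print(f"missense observations: {table.n_total}")
print(f"significant hotspot codons: {table.significant_codons()}")

assoc = group_association(views.patients)
print(f"truncating/nontruncating x phenotype: chi2 = {assoc.chi2:.1f}, "
      f"df = {assoc.df}, p = {assoc.p:.2e}")
ppgl = summarize(views).levels["patient"]["group_strata"]
nt = ppgl["nontruncating"]["phenotypes"]["PPGL"]["count"]
t = ppgl["truncating"]["phenotypes"]["PPGL"]["count"]
print(f"PPGL patients with nontruncating variants: {100 * nt / (nt + t):.0f}%")
```

prints

```
admitted: 688 patients, 637 families, 359 unique variants
missense observations: 237
significant hotspot codons: [161, 167, 175, 179, 180, 182]
truncating/nontruncating x phenotype: chi2 = 341.6, df = 6, p = 1.00e-70
PPGL patients with nontruncating variants: 82%
```

The two planted hotspots (167, 161) are recovered; the extra flagged codons
reflect that the default generator concentrates the nontruncating class's
missense variants in the α-domain, so the uniform-codon null is genuinely
violated there — the same mechanism that produces domain-clustered hotspots
in real VHL cohorts. The large χ² captures the planted type 1 / type 2
structure: PPGL patients carry overwhelmingly nontruncating variants while
CHB/RCC-dominated patients carry truncating ones.

The same analyses run from the shell:

```bash
vhlgp simulate --seed 42 --n-families 800 --out cohort.tsv --truth-out truth.json
vhlgp run-all --input cohort.tsv --outdir report/
vhlgp cluster --input cohort.tsv --auto --outdir report/   # eigengap, both candidates
```

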