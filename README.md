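# rarescreen

Multi-class rare-variant screening and clinical adjudication for
whole-genome sequencing (WGS) cohorts, built around the analysis design
used in clinical WGS studies of schizophrenia and related
neurodevelopmental disorders (NDDs).

Clinical genome analysis in psychiatry asks a bookkeeping-heavy
question: across *every* variant class a genome offers — small variants
(SNVs/indels), copy-number variants (CNVs), and tandem repeat
expansions (TREs) — how many individuals in a cohort carry something of
clinical significance, and does the yield differ by sex, intellectual
disability, or other phenotype strata?  `rarescreen` implements that
full accounting as a tested, reusable library plus CLI, for statistical
geneticists and clinical-genomics analysts.

## What it computes

**Variant tiering.**  A small variant is *clinically relevant* iff

- rare: max population allele frequency across panels (ExAC, 1000G,
  gnomAD, gnomAD-SV) ≤ 0.01, with max AF = 0 termed *ultra-rare*;
- damaging: a loss-of-function (LoF) consequence (stop-gain,
  frameshift, splice-site), or a missense passing an in-silico
  consensus — at least 5 of 8 predictors flag it (CADD ≥ 15,
  SIFT ≤ 0.05, PolyPhen2-HVAR ≥ 0.90, Provean < −2.5,
  MutationAssessor ≥ 1.90, MutationTaster ≥ 0.5, PhyloP-mam ≥ 2.30,
  PhyloP-vert ≥ 4.0);
- in a constrained gene: gnomAD LOEUF < 0.35;
- in a gene on an established NDD panel.

An ultra-rare LoF variant in a constrained gene *off* the panel is a
*candidate-gene* finding (potential clinical implication), promoted
into the per-individual ledger only when its gene shows
FDR-significant recurrence.

**Gene recurrence.**  For each gene, k carriers among n individuals are
tested against Binomial(n, μ_g) with an upper-tail p = P(X ≥ k); the
per-gene null carrier rate μ_g is an input (a coding-length-proportional
estimator is provided).  p-values are adjusted by Benjamini–Hochberg
step-up against the m genes screened genome-wide (m may far exceed the
number of tabulated genes).

**CNV concordance.**  Calls ≥ 10 kb from two platforms are matched
per-sample by greedy best reciprocal overlap,
RO = min(ov/|a|, ov/|b|), at RO ≥ 0.5.

**TRE screening.**  Per-sample repeat genotypes are classified against
a 45-locus disease catalog: *expanded* when the larger allele meets the
locus threshold (per-locus ≥ or >), with a near-threshold flag for
calls within 20% below it (short-read genotypers underestimate long
expansions).

**Cohort statistics.**  Distinct-carrier yields under phenotype scope
filters, Fisher's exact test on carrier contrasts, exact/asymptotic
Wilcoxon rank-sum burden comparisons, bootstrap + permutation subgroup
burden summaries, and polygenic risk score (PRS) evaluation — additive
scoring at a training p-value threshold P_T, Nagelkerke pseudo-R² from
logistic regression, and the odds ratio of case status in the top score
percentile (Woolf CI).

**Synthetic cohorts.**  `rarescreen.cohortsim` generates a full
case/control fixture bundle (VCF, BED, TSV, ExpansionHunter-style JSON)
with a ground-truth ledger of spiked findings, calibrated to published
per-genome rare exonic counts (271.7 SNVs, 20.1 indels, 2.89 SVs, 3.33
CNVs), 10% pathogenic-CNV and 4.3% clinically-relevant-SNV carrier
prevalences, repeat-expansion carriers, and case-enriched PRS.

## Worked example

The package bundles, as plain data, the findings tables of a published
259-adult schizophrenia WGS cohort (`rarescreen.datasets`).  Running
the full analysis over them:

```python
import pandas as pd
from rarescreen import datasets as ds
from rarescreen.pipeline import analyze_cohort

variants = pd.concat(
    [ds.example_clinrel_variants(), ds.example_candidate_lof_variants()],
    ignore_index=True,
).drop_duplicates(subset=["sample_id", "chrom", "pos", "ref", "alt"])
counts, pvalues, m = ds.example_recurrence_pvalues()
result = analyze_cohort(
    variants,
    ds.example_frequencies(),
    ds.example_missense_scores(),
    ds.example_gene_annotations(),
    ds.example_phenotypes(),
    cnvs_wgs=ds.example_cnvs()[0],
    cnvs_cma=ds.example_cnvs()[1],
    tre_genotypes=ds.example_tre_genotypes(validated=True),
    recurrence_pvalues=pvalues,
    recurrence_m=m,
)
print(result.summary)
print(result.recurrence)
```

prints (abridged):

```
n_clinrel_snv_carriers: 11            # 4.2% of 259 individuals
n_clinrel_snv_carriers_no_pathogenic_cnv: 9   # 3.9% of 233
n_tre_carriers: 3                     # DMPK x1, ATXN8OS x2
n_candidate_gene_carriers: 3          # ZMYM2 (the sole FDR<0.05 gene)
n_non_cnv_class_carriers: 17          # distinct individuals, all classes
n_high_impact_no_pathogenic_cnv: 14   # 6.0% of the 233 without pathogenic CNVs
fisher_rare_cnv_p: 0.761              # 5/136 vs 6/123 carrier contrast
cnv_recovery_pct: 100.0               # WGS recovered every CMA CNV at RO>=0.5

  gene_symbol  p_binomial       fdr  rank
0       ZMYM2    9.51e-06  0.028        1
1      GPRIN1    9.08e-05  0.134        2
2       BRPF1    3.67e-04  0.360        3
3      DNAJC6    7.39e-04  0.544        4
```

Eleven individuals carry a clinically relevant SNV/indel; excluding the
26 pathogenic-CNV carriers leaves nine of 233.  Adding the three
repeat-expansion carriers and the three carriers of ultra-rare LoF
variants in the recurrence-significant candidate gene *ZMYM2* gives 17
distinct carriers overall, 14 of them (6.0%) among the 233 individuals
without a pathogenic CNV.

The same stages are scriptable from a shell (`rarescreen simulate`,
`rarescreen adjudicate`, `rarescreen tre-screen`, `rarescreen
cnv-concord`, `rarescreen burden`, `rarescreen prs`, `rarescreen
pipeline run`); see `rarescreen --help`.

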