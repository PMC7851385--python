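# Methods

## Clinical tiering model

A small variant is tiered by conjunction of four predicates, evaluated
independently per (sample, variant):

1. **Rarity.**  max AF over the reference panels (ExAC, 1000 Genomes,
   gnomAD, gnomAD-SV); absent panels are ignored, an all-absent profile
   has max AF 0 and is *ultra-rare* (the convention behind "0/0"
   frequency entries in clinical tables).  Rare means 0 < max AF ≤ 0.01
   (inclusive bound).
2. **Damage.**  LoF = {stop-gain, frameshift, splice-site}; the
   splice-site label is taken from the annotation input — the pipeline
   never recomputes splice context.  Missense variants qualify through
   the 5-of-8 in-silico consensus.  All predictor inequalities are
   inclusive except Provean (strictly < −2.5, as conventionally
   printed).  A missing predictor never passes and the quorum
   denominator stays 8: requiring 5 of the canonical set, not 5 of
   whatever happened to be computed, is the conservative reading and
   means a variant with ≤ 4 scored predictors can never qualify by
   consensus.
3. **Constraint.**  LOEUF < 0.35, the conventional bound for
   LoF-intolerant genes; configurable.  A missing LOEUF yields an
   explicit *uncertain* tier on an otherwise-qualifying variant, never
   a silent fail.
4. **Gene evidence.**  NDD-panel membership is an input column; no gene
   panel is bundled beyond the fixtures, because panel content is a
   curation decision that belongs to the user.

Pathogenic and likely-pathogenic are collapsed into the single
`clinically_relevant` tier; the distinction in source material is an
output annotation, not a rule difference.  Ultra-rare LoF in a
constrained non-panel gene is `potential_implication`
(candidate-gene stratum).  Everything else is `none`, except the two
explicit `uncertain` cases (no gene annotation; no LOEUF).

No sex-specific rule is applied to X-chromosome variants beyond
recording zygosity.

### Findings ledger and yields

Findings are per-individual sets of (class, identifier, tier), classes
never merged, so one person can hold a CNV plus a missense finding and
is still counted once per scope.  Yields are distinct-individual counts
over a phenotype scope filter; an empty denominator raises rather than
returning NaN.  Candidate-gene findings enter the ledger only for
genes whose recurrence FDR clears 0.05 (below): an isolated ultra-rare
LoF in a constrained gene is not, by itself, a reportable finding.

## Gene recurrence test

P(X ≥ k) for X ~ Binomial(n, μ_g), computed with the scipy survival
function (stable far into the tail; the test suite pins it to a direct
pmf summation oracle at 1e-12).  The per-gene null rate μ_g is **input
data**: its construction (mutation-rate models, gene length, carrier
vs allele trials) varies between studies and is out of scope here.  A
helper (`lengthwise_null_rates`) distributes an observed cohort-wide
qualifying-variant total over genes proportionally to coding length.

FDR is Benjamini–Hochberg step-up, adjusted_(i) = min_{j≥i} p_(j)·m/j
capped at 1, with m ≥ number of tabulated tests (m is the size of the
genome-wide screen, e.g. all constrained genes examined).  Implemented
directly because the installed statsmodels `multipletests` cannot take
m larger than the list supplied.

## CNV concordance

Intervals are 0-based half-open (BED-native); VCF-style inputs are
converted at the boundary (`CNVCall.from_vcf_coords`).  Size filter
≥ 10 kb, bound inclusive.  Reciprocal overlap is 0 across chromosomes
or dosage types.  Matching is greedy within sample by descending RO,
each call used at most once, ties broken by input order —
deterministic, and at clinical CNV densities (a handful of calls per
genome) indistinguishable from optimal assignment.  Default RO
threshold 0.5 (community convention).  Whether published cross-platform
comparisons used RO or breakpoint proximity is typically unstated; RO
was chosen as the field's standard metric.

## Tandem-repeat screening

Threshold inclusivity is **per-locus catalog data**, not a global rule:
disease conventions differ (e.g. myotonic-dystrophy DMPK expanded at
≥ 51 CTG, spinocerebellar-ataxia-8 ATXN8OS at > 110).  Classification
uses only the larger allele.  Lower-bound genotype estimates (">200")
are stored as bound + 1 with a marker and classified at that value.
The near-threshold flag (default margin: within 20% below threshold)
exists because short-read genotypers systematically underestimate long
expansions — a genotype read as 91 can validate at > 200; the flag
marks review candidates and never promotes a call to expanded.  The
bundled 45-locus catalog has clinically exact DMPK and ATXN8OS rows;
the remaining rows follow published locus conventions but are fixture
data, replaceable via `load_catalog`.

## Subgroup and cohort statistics

- Fisher's exact test: scipy two-sided (hypergeometric); the test suite
  cross-checks against exhaustive table enumeration for small margins.
- Rank-sum test: exact enumeration of all C(n_x+n_y, n_x) rank
  assignments (midranks for ties) when n_x+n_y ≤ 12, else the normal
  approximation with tie correction.  The signed-rank variant is
  provided for genuinely paired designs, but the unpaired rank-sum is
  the default for group contrasts — published wording sometimes says
  "signed-rank" for an unpaired comparison, which is treated as a
  misnomer.
- Subgroup burden: burden = number of clinically relevant CNVs plus
  SNVs/indels per individual (TREs excluded, per the stringent
  convention for phenotype correlations).  Mean per group, percentile
  bootstrap 95% CI (≥ 1000 resamples; the interval is widened to the
  sample mean in the rare resampling corner where the percentile
  interval would exclude it), and a two-sided permutation p-value on
  the group-vs-complement mean difference, p = (extreme+1)/(B+1)
  (valid, marginally conservative).  The permutation test was chosen
  over a parametric contrast because per-individual burdens are tiny
  counts with many zeros.

## Polygenic scores

Score = Σ β_j · dosage_j over SNPs with training p ≤ P_T (default
0.05).  Weights are assumed pre-clumped; no LD handling or imputation
dosage uncertainty (WGS genotypes are treated as exact).  Missing
dosages contribute 0 and are excluded from `n_snps_used`.
Nagelkerke R² = [1 − exp(2(ll₀ − ll₁)/n)] / [1 − exp(2·ll₀/n)];
the operation consumes log-likelihoods so any maximiser of the
binomial likelihood may fit the model (statsmodels Logit is used; the
test suite pins it to an independent Newton solver at 1e-6).
Top-percentile OR: pooled scores cut at the (1 − c) quantile (default
c = 0.20; "top twentieth percentile" is ambiguous between top 5% and
top 20%, so c is a parameter), OR by cross-product with
Haldane–Anscombe 0.5 correction when a cell is zero, 95% Woolf
log-interval.  A degenerate cut (all scores equal, or a cut leaving an
empty stratum) raises.

## Synthetic cohort generator

The generator emulates *post-pipeline* data — what lands on an
analyst's desk after calling, annotation and QC — for a default
259-case / 225-control cohort.

- **Counts.**  Per-genome background counts are Poisson (simplest model
  matching only published means; no published variance to match) with
  means 271.7 SNVs, 20.1 indels, 2.89 SVs, 3.33 CNVs — these are
  *post-rarity-filter* rare exonic means, so an additional Poisson(55)
  of common (AF > 0.01) SNVs per genome is generated for the filter to
  remove.
- **Allele frequencies.**  Mixture: 60% point mass at 0 (ultra-rare)
  and 40% log-uniform on [1e-6, 0.01], populating both rarity strata;
  gnomAD carries the maximum, ExAC a sub-fraction, 1000 Genomes only
  the commoner tail.
- **Gene universe.**  1200 synthetic genes with log-normal LOEUF and
  coding lengths on a uniform synthetic exome map; 30% of constrained
  genes are panel members.  Background missense/LoF variation is kept
  out of the clinically actionable strata (no background missense or
  LoF in constrained panel genes; no background LoF in constrained
  genes at all), so ground-truth sensitivity and specificity of the
  adjudicator are exactly 1 on these fixtures.  Consequently, passing
  recovery tests demonstrates rule correctness, **not** robustness to
  annotation noise, score disagreement or frequency-database drift —
  real cohorts have all three.
- **Spikes.**  Carrier counts are deterministic roundings of
  prevalence × n (11 clinically relevant SNV carriers, 26
  pathogenic-CNV carriers — the first two holding two CNVs each, for
  28 calls — 3 repeat-expansion carriers at DMPK/ATXN8OS, and
  candidate-gene LoF recurrence of 3+2+2+2 carriers over four
  constrained non-panel genes).  Spiked variants satisfy by
  construction the tier they are labelled with;
  `score_pass_probability` (default 1.0) lets spiked missense profiles
  fail the consensus for sensitivity experiments.
- **CMA callset.**  The pathogenic CNVs are re-emitted as a
  microarray-style callset with breakpoints jittered uniformly within
  ±10% of length, for the cross-platform concordance stage.
- **Phenotypes.**  Carrier status multiplies the odds of female sex,
  broad ID and syndromic features by 3 (direction-only emulation of
  reported enrichments; published effect sizes are not printed).
  Baselines: 50% female, 39% broad ID, 20% syndromic.
- **PRS.**  300-SNP panel, β ~ N(0, 0.15²), training p ~ U(0, 1]; case
  allele frequencies are shifted by δ·β_j / (2Σβ²) over the SNPs
  passing P_T so the expected case-control score difference equals the
  configured δ (default 0.5 log-odds), recoverable within 3 SE.
- **Determinism.**  One `numpy` generator seeded from the config;
  identical config ⇒ byte-identical files.  Not emulated: linkage
  disequilibrium, realistic chromosome maps, read-level noise,
  relatedness, population stratification.

## Problem sizes

Worked-example and test computations run at the scales the analysis
itself uses: the 259-sample example cohort, full default-scale
generation (≈ 170k variants) for calibration and PRS recovery, a
30-case cohort for structural pipeline checks, 20 replicates × 28 CNVs
for concordance, 200 replicates for the permutation type-I and OR null
calibrations.

## Known limitations

- The adjudicator is not an ACMG criteria engine: no segregation,
  de-novo status, or functional-evidence codes (parental genotypes are
  typically unavailable in adult community cohorts).
- The binomial null rate and the NDD panel are inputs; results are
  only as good as those curations.
- Greedy RO matching can be suboptimal in pathological overlap
  configurations (bounded within a factor 2 of the maximum matching);
  irrelevant at clinical densities.
- The percentile-bootstrap CI is first-order; for very small subgroups
  a BCa interval would be preferable.
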