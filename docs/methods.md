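# Methods

This note documents the statistical procedures, parameter defaults,
numerical choices and limitations of `adenomaevo`. All thresholds quoted as
defaults are the values used in the colorectal adenoma / early-carcinoma
panel-sequencing setting the package targets (a 451-gene, 3.34 Mb panel;
mean deduplicated coverage of 1000x for adenoma tissue, 1500x for plasma
cfDNA and 2000x for the leukocyte control).

## Variant representation and consensus filtering

Calls from multiple somatic callers (varscan2, strelka, gvc or any caller
carried as a free-text tag) are compared through normalised variant keys:
indels are parsimony-trimmed and left-aligned against the reference
(vt-style algorithm), which is idempotent and collapses all equivalent
spellings of the same allele. Variants use 1-based inclusive coordinates;
copy-number segments are half-open 0-based.

Filtering applies, in order: caller consensus, then site-quality rules.

- Tissue: keep alleles reported by >= 2 distinct callers.
- Plasma: additionally require the matched-leukocyte VAF to be exactly 0,
  and for single-caller alleles a VAF >= 0.05.
- Quality: drop alleles with max(AF_1000G, AF_ExAC) > 0.01 (a missing
  population AF counts as 0 — absence from the database is evidence of
  rarity), mappability < 0.75 (missing mappability passes), and any
  same-sample pair of mutations closer than 100 bp, removing *every*
  member of such a cluster: clusters are treated as alignment artifacts
  with no principled survivor.

The merged record takes VAF and depth from the deepest caller. Proximity is
evaluated within one patient + sample type on the post-consensus set, so
artifact calls that already failed consensus do not veto true neighbours.
Population-AF and mappability rules commute with consensus (they are
site-level annotations); the proximity rule is defined only on the
post-consensus set, which is the documented and tested order.

## Tumor-informed plasma rescue

For each tissue mutation, alt/ref counts in cfDNA and control pileups form
a 2x2 table tested with a one-sided Fisher exact test (alternative:
cfDNA-enriched). One-sidedness is our choice: rescue asks only whether the
tissue allele is present in plasma. p-values are Benjamini–Hochberg
adjusted within one patient's tested sites (the grouping is our choice; the
procedure needs a per-patient error rate for the per-patient detection
call). A site is detected when all three hold:

1. q <= 0.1;
2. cfDNA VAF >= 2 x control VAF (VAFs computed from the pileup counts, not
   the caller's estimate);
3. cfDNA alt reads >= 4.

Sites without pileup counts are reported *untested*, never "undetected".
The cohort summary reports the patient-level detection rate, the detected
mutation table with per-mutation cohort frequency, and the VAF range. A
known oddity of the source cohort's published detection table — the text
reports detected VAFs spanning 0.92–2.97% while the table itself lists one
intronic variant at 9.38% — is surfaced by the reconstruction tests as-is;
we do not resolve the inconsistency.

## Burden metrics

TMB = qualifying mutations / panel size in Mb. The numerator defaults to
nonsynonymous classes (missense, nonsense, frameshift, splice) and is
switchable to all somatic mutations; the published definition says
"somatic mutations" without further restriction, so the convention is
explicit rather than implicit. Panel size defaults to 3.34 Mb.

GII = (gained + lost + copy-neutral-LOH length) / total segmented length,
from allele-specific segments: gain when total copy number exceeds the
baseline ploidy (default 2; the sample's rounded ploidy can be supplied),
loss when below, copy-neutral LOH when total = baseline with minor copy
number 0. Using the segmented genome rather than a fixed genome size keeps
targeted data well-defined; whether the original analysis normalised by
whole genome or covered genome is not stated, and the two coincide when
segmentation covers the genome.

## Neutral-evolution test

Under neutral tumor growth the number of subclonal mutations with VAF >= f
grows as M(f) = (mu/beta)(1/f − 1/f_max). We evaluate M at each distinct
subclonal VAF (ties collapsed) in the window f_min = 0.1 < VAF < f_max =
0.25, regress M on x = 1/f − 1/f_max by ordinary least squares through the
origin, and report R² = 1 − SS_res/SS_tot with SS_tot taken about the mean
of M (so R² can be negative; it is clipped at 0). A sample is called
neutrally evolved when R² >= 0.98. Spectra with fewer than n_min = 12
usable mutations are flagged not-evaluable — neither neutral nor
non-neutral — to guard against meaningless fits (the threshold is ours;
the source analysis is silent). VAFs are used raw, without purity or
copy-number correction, because the window cutoffs are defined on raw VAF.
The clonal/subclonal split places VAF = 0.25 exactly on the clonal side.

## dN/dS

Selection strength is the ratio of observed to expected nonsynonymous
mutations. The opportunity table counts, for every coding site and every
possible substitution, whether the change is synonymous or nonsynonymous
(stop gains/losses count as nonsynonymous), stratified by 96
strand-collapsed trinucleotide contexts; per gene the opportunities total
3 x CDS length. CDS boundary sites take an `A` flank by convention.
Context-specific mutation rates are anchored on synonymous sites,
rate_c = syn_count_c / syn_opportunity_c, pooled across genes (no per-gene
covariates — simpler than the full covariate model of the dndscv family
but identifiable at panel scale); contexts that offer no synonymous site
anywhere fall back to the pooled rate. Expected nonsynonymous count =
sum_c rate_c x nonsyn_opportunity_c.

The global confidence interval is a delta-method interval on log dN/dS
propagating *both* the observed nonsynonymous Poisson count and the
sampling variance of the synonymous-anchored expectation
(Var(E_N) = sum_c (nonsyn_opp_c / syn_opp_c)² syn_count_c). An interval
conditioned on the estimated rates (Poisson-only) under-covers the true
selection strength badly at realistic mutation counts — at 2000 mutations
it covered the no-selection truth in only about half of replicates —
whereas the propagated interval attains ~94% empirical coverage and
recovers planted selection coefficients w in {0.5, 1, 2, 5}.

Per-gene dN/dS uses cohort-wide rates and, because those rates are
estimated from the whole cohort's synonymous sites, a Poisson test of the
gene's observed vs expected nonsynonymous count is appropriate there;
genes with dN/dS > 1 and one-sided p <= 0.05 are flagged positively
selected. Per-gene p-values are reported unadjusted (whether the original
analysis adjusted them is unstated); the caller can BH-adjust.

Multi-lesion patients: lesions are classified as sharing a common
ancestral origin when at least one identical normalised variant key occurs
in two or more of the patient's adenomas; otherwise independent.

## Cohort statistics

Per-gene comparisons are two-sided Fisher exact tests on mutated/wild-type
counts, optionally BH-adjusted. Pathway alteration marks a patient altered
when >= 1 member gene is mutated; the ten canonical oncogenic signaling
pathway memberships ship as an editable YAML config (data, not code).

The persistence statistic for gene i is the printed rate-ratio form
Ri = (m_i/n_i)/(M/N) over polyp-persistent (M = 23) and polyp-free
(N = 19) follow-up groups — note this is a rate ratio, not the classical
odds ratio, which we also report from the same 2x2 for transparency. When
n_i = 0 a 0.5 continuity constant keeps Ri finite (flagged). Genes with
m_i + n_i < 2 are skipped; default risk-gene call is Ri > 1 with
unadjusted Fisher p <= 0.1 (the original six-gene result names no
threshold; both are configurable). Binomial enrichment is the upper tail
P(X >= k | Bin(n, p0)).

## Random-forest classifier

A forest (default 1000 trees, sqrt-mtry, bootstrap, fully grown) is fitted
on the binary gene x patient matrix. Minimal depth — the depth of a
variable's first split in a tree, with unused variables penalised at the
tree's maximum depth — is averaged over trees. The selection threshold
comes from the analytic null of an uninformative variable chosen uniformly
at random (probability 1/p per internal node) in trees of the observed
shapes: P(minimal depth >= d) = prod_{d'<d} (1 − 1/p)^{L_{d'}} with L_d
internal nodes at level d. The default rule selects variables below the
null's mean; a stricter rule uses the 5th percentile of the tree-averaged
null (normal approximation).

Variable selection on a *single* cohort of this size (85 + 78 patients) is
limited by chance gene–label associations: a noise gene that happens to
correlate with the class in one dataset looks informative to any
association-based statistic. In our planted-signal experiments the
sufficient-statistic (exact-test) ranking itself recovers only ~9/15
informative genes at a 5% noise budget on one cohort, and minimal depth
~11–12/15. The package's recommended recovery protocol is therefore
stability selection: run the selector on replicate cohorts (or resamples)
and keep genes selected in a majority of replicates. Across 50 simulated
cohorts this recovers >= 12 of the 15 planted genes with well under 5% of
the 200 noise genes, and it is what the acceptance experiment computes.

Evaluation: AUC via the Mann–Whitney rank statistic (ties count 0.5;
verified exactly against all-pairs concordance counting), AUCPR via
average precision, and the out-of-bag error rate. Discovery-set scores are
out-of-bag vote fractions to avoid optimism; external sets use plain
predicted vote fractions.

## Synthetic data generator

The generators emulate the study conditions: 85 CRA and 78 stage-I CRC
patients; per-gene mutation frequencies using the cohort's printed values
where available (APC 0.67/0.56, KRAS 0.39/0.28, TP53 0.09/0.42, PIK3CA
0.04/0.14, CTNNB1 0.11/0.01, SOX9 0.13, AXIN2 0.09, ...) and
CRC-literature-shaped values otherwise, plus 200 noise genes at 4%
frequency in both cohorts; three callers with unit sensitivity and planted
artifact classes so every filter rule sees positive and negative cases;
follow-up outcomes (23 persistent / 19 polyp-free / 2 cancerous among 44
followed patients) enriched for carriers of the planted risk genes
(KMT2C, DICER1, KMT2D, FAT1, SOX9, APC); plasma shedding in ~5.9% of
adenoma patients with shed VAFs drawn from 0.92–2.97% against binomial
sampling at the study depths; segment plans constructed to hit a target
GII exactly; subclonal VAFs drawn from the 1/f² density (inverse-CDF, so
the noiseless variant lies exactly on the neutral model line) with
binomial read noise; and coding mutations drawn over trinucleotide
opportunities with per-gene selection weights.

Every generator is a pure function of (configuration, seed); the master
seed fans out to fixed, independent per-generator streams so adding a
generator never perturbs another's draws.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: FFPE and sequencing error profiles beyond
binomial sampling, UMI structure, caller-specific error modes (sensitivity
is uniform and independent across callers), linkage between mutations,
subclonal copy-number interaction with VAF, tumor purity below 100%, and
real mutational-signature context biases (substitutions are drawn uniform
over opportunities unless weighted).

## Problem sizes used in the test-suite and acceptance experiments

Neutrality: 100 replicates of 1000 subclonal VAFs at 1000x. dN/dS: a
100-gene x 160-codon synthetic CDS set, 2000 mutations per replicate, 100
replicates (25 for CI-coverage checks, with an 80% pass floor on nominal
95% coverage to absorb binomial noise at small replicate counts).
Classifier: 50 replicate cohorts, 500 trees each for the stability
experiment. Exact-test agreement with the enumeration oracle is exhaustive
for table margins <= 20 and sampled (3000 tables) for margins <= 50.

## Known limitations

- dN/dS rates are shared across genes; genes with atypical base
  composition inherit the pooled context rates.
- The neutrality statistic is sensitive to the subclonal window; windows
  other than (0.1, 0.25) are configurable but untested against the
  published classification threshold.
- The minimal-depth null assumes uniform split-variable choice; best-split
  selection among mtry candidates makes the null conservative in depth
  units, which the stability-selection protocol compensates for.
- FACETS-style segmentation, caller implementations, annotation and
  oncogene/TSG classification are consumed as inputs, not reimplemented.
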