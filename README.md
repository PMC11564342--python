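# adenomaevo

Analysis pipeline for targeted panel sequencing of colorectal adenomas
(CRA) and their matched plasma cell-free DNA, built for studying the
premalignant-to-malignant transition toward colorectal cancer (CRC). It is
aimed at cancer-genomics analysts who have per-caller somatic call sets,
plasma/leukocyte pileups, allele-specific copy-number segments and binary
gene x patient mutation matrices, and who want the downstream statistics
reproducible and testable without access to restricted patient data.

## What it computes

- **Consensus filtering** of multi-caller somatic calls: population allele
  frequency <= 0.01 (1000 Genomes / ExAC), mappability >= 0.75, >= 100 bp
  between adjacent mutations, >= 2 callers for tissue; plasma additionally
  requires matched-normal VAF = 0 and VAF >= 0.05 for single-caller calls.
- **Tumor-informed plasma rescue**: for each tissue mutation, a one-sided
  Fisher exact test on the cfDNA-vs-leukocyte 2x2 read-count table; a site
  is detected when q(BH) <= 0.1, cfDNA VAF >= 2 x control VAF, and
  cfDNA alt reads >= 4.
- **Burden metrics**: TMB = qualifying mutations / panel megabases
  (3.34 Mb, 451-gene panel), and the genome instability index
  GII = fraction of the segmented genome with copy-number gain, loss, or
  copy-neutral LOH.
- **Clonal evolution**: clonal/subclonal split at VAF 0.25; the 1/f neutral
  growth test — M(f) = (mu/beta)(1/f − 1/f_max) fitted through the origin
  on the subclonal window 0.1 < VAF < 0.25, neutral when R² >= 0.98; and
  dN/dS with 96 strand-collapsed trinucleotide contexts, synonymous-anchored
  rates, global / clonal / subclonal / per-gene scopes.
- **Cohort statistics**: per-gene and per-pathway (ten canonical oncogenic
  signaling pathways) two-sided Fisher comparisons between cohorts, the
  polyp-persistence rate ratio Ri = (m_i/n_i)/(M/N), and one-sided binomial
  enrichment tests.
- **CRA-vs-CRC classification**: random forest on the binary gene matrix,
  minimal-depth variable selection against an analytic uninformative-variable
  null, reduced model, AUC / AUCPR / out-of-bag error.
- **Synthetic cohorts** with known ground truth for every stage (the raw
  study data are restricted-access), so the whole pipeline is exercisable
  and testable offline.

## Worked example

```python
import numpy as np
from adenomaevo import (SimConfig, simulate_cohort, simulate_multicaller_calls,
                        simulate_plasma_counts, simulate_segments, filter_calls,
                        rescue, cohort_detection_summary, compute_tmb, compute_gii,
                        neutrality_test)
from adenomaevo.synthetic_data import simulate_neutral_vafs

cfg = SimConfig(seed=0)                        # 85 CRA + 78 CRC-I patients
matrix, truth = simulate_cohort(cfg)
calls, _ = simulate_multicaller_calls(truth, cfg)
kept, report = filter_calls(calls, mode="tissue")
print(f"filter: kept {report.n_kept} of {report.n_input} candidate variants")

counts = simulate_plasma_counts(truth, cfg)
results = {p: rescue(muts, counts[p]) for p, muts in truth.variants.items()
           if matrix.cohort[p] == "CRA"}
summary = cohort_detection_summary(results, n_patients=85)
print(f"rescue: {summary.n_mutations} mutations in "
      f"{summary.n_patients_positive}/85 patients "
      f"({100*summary.detection_rate:.1f}%)")

res = neutrality_test(simulate_neutral_vafs(1000, rng=0))
print(f"neutrality: R^2 = {res.r_squared:.4f} -> neutral: {res.is_neutral}")
```

prints

```
filter: kept 1741 of 2882 candidate variants
rescue: 8 mutations in 5/85 patients (5.9%)
neutrality: R^2 = 0.9975 -> neutral: True
```

The filter keeps exactly the planted true somatic variants (the 1141
removed records are seeded artifacts: common SNP contaminants, poorly
mappable sites, sub-100 bp clusters and single-caller false calls). The
rescue step finds the plasma-shed mutations — about 6% of patients carry a
detectable tissue mutation in plasma at ~1-3% VAF and 1500x depth — and the
1/f statistic classifies the simulated neutrally-evolving tumor as neutral
(R² above the 0.98 threshold).

A command-line interface mirrors the library
(`adenomaevo simulate|convert|filter|rescue|burden|evolution|cohort|classify|run`);
`adenomaevo run --config run.yaml` executes every stage with provenance
logging.

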