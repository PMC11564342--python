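"""Tumor-informed plasma mutation rescue.

For every somatic mutation already identified in a patient's adenoma tissue,
alt/ref read counts are collected at the same site in the matched plasma
cfDNA and leukocyte control pileups. A one-sided Fisher's exact test asks
whether the alt allele is enriched in cfDNA over the control; per patient,
p-values are Benjamini-Hochberg adjusted, and a site counts as detected when

  q <= 0.1  AND  cfDNA VAF >= 2 x control VAF  AND  cfDNA alt reads >= 4.

This allows detection far below de novo plasma calling thresholds (the
study's positive VAFs sat around 1-3% at 1500x plasma depth).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variant_io import SomaticCall, VariantKey


@dataclasses.dataclass(frozen=True)
class SiteCounts:
    """Pileup counts at one tissue-mutation site in cfDNA and control."""

    variant: VariantKey
    cf_alt: int
    cf_ref: int
    ctrl_alt: int
    ctrl_ref: int

    def __post_init__(self) -> None:
        if min(self.cf_alt, self.cf_ref, self.ctrl_alt, self.ctrl_ref) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def cf_vaf(self) -> float:
        total = self.cf_alt + self.cf_ref
        return self.cf_alt / total if total else 0.0

    @property
    def ctrl_vaf(self) -> float:
        total = self.ctrl_alt + self.ctrl_ref
        return self.ctrl_alt / total if total else 0.0


@dataclasses.dataclass
class RescueConfig:
    max_q: float = 0.1
    min_vaf_ratio: float = 2.0
    min_alt_reads: int = 4


@dataclasses.dataclass
class RescueResult:
    variant: VariantKey
    cf_vaf: float
    ctrl_vaf: float
    p_value: float
    q_value: float
    detected: bool
    failed_rules: list[str]
    tested: bool = True
    gene: str | None = None
    variant_class: str | None = None
    protein_change: str | None = None


def fisher_site_test(site: SiteCounts) -> float:
    """One-sided (cfDNA-enriched) Fisher exact p for one site's 2x2 table."""
    table = [[site.cf_alt, site.cf_ref], [site.ctrl_alt, site.ctrl_ref]]
    if site.cf_alt + site.ctrl_alt == 0:
        if site.cf_ref + site.ctrl_ref == 0:
            warnings.warn("all-zero contingency table; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table, alternative="greater")[1])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rescue(
    tissue_variants: Sequence[SomaticCall],
    counts: Mapping[VariantKey, SiteCounts] | Sequence[SiteCounts],
    cfg: RescueConfig | None = None,
) -> list[RescueResult]:
    """Run the tumor-informed detection procedure for one patient.

    q-values are adjusted across this patient's tested sites. Tissue
    variants without pileup counts are reported untested (``tested=False``),
    not undetected.
    """
    cfg = cfg or RescueConfig()
    if not isinstance(counts, Mapping):
        counts = {c.variant: c for c in counts}

    tested: list[tuple[SomaticCall, SiteCounts, float]] = []
    untested: list[SomaticCall] = []
    for var in tissue_variants:
        site = counts.get(var.key)
        if site is None:
            untested.append(var)
        else:
            tested.append((var, site, fisher_site_test(site)))

    q_values = bh_adjust([p for _, _, p in tested]) if tested else np.array([])

    results: list[RescueResult] = []
    for (var, site, p), q in zip(tested, q_values):
        failed: list[str] = []
        if q > cfg.max_q:
            failed.append("q_value")
        if site.cf_vaf < cfg.min_vaf_ratio * site.ctrl_vaf:
            failed.append("vaf_ratio")
        if site.cf_alt < cfg.min_alt_reads:
            failed.append("min_alt_reads")
        results.append(
            RescueResult(
                variant=var.key,
                cf_vaf=site.cf_vaf,
                ctrl_vaf=site.ctrl_vaf,
                p_value=p,
                q_value=float(q),
                detected=not failed,
                failed_rules=failed,
                gene=var.gene,
                variant_class=var.variant_class,
                protein_change=var.protein_change,
            )
        )
    for var in untested:
        results.append(
            RescueResult(
                variant=var.key,
                cf_vaf=float("nan"),
                ctrl_vaf=float("nan"),
                p_value=float("nan"),
                q_value=float("nan"),
                detected=False,
                failed_rules=["untested"],
                tested=False,
                gene=var.gene,
                variant_class=var.variant_class,
                protein_change=var.protein_change,
            )
        )
    return results


@dataclasses.dataclass
class DetectionSummary:
    detection_rate: float  # fraction of patients with >= 1 detected mutation
    n_patients_positive: int
    n_patients: int
    n_mutations: int
    vaf_range: tuple[float, float] | None
    mutation_table: list[dict]


def cohort_detection_summary(
    results_per_patient: Mapping[str, Sequence[RescueResult]], n_patients: int
) -> DetectionSummary:
    """Cohort-level plasma detection statistics and the detected-mutation table.

    Each table row carries the mutation's cohort frequency: the fraction of
    the cohort in which that same (gene, protein change) mutation was
    detected in plasma.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    detected: list[tuple[str, RescueResult]] = []
    positives = set()
    for patient, results in results_per_patient.items():
        for r in results:
            if r.detected:
                detected.append((patient, r))
                positives.add(patient)

    ident_counts: dict[tuple, set] = {}
    for patient, r in detected:
        ident = (r.gene, r.protein_change)
        ident_counts.setdefault(ident, set()).add(patient)

    table = []
    for patient, r in sorted(detected, key=lambda x: (x[0], str(x[1].variant))):
        ident = (r.gene, r.protein_change)
        table.append(
            {
                "gene": r.gene,
                "variant_class": r.variant_class,
                "protein_change": r.protein_change,
                "cohort_frequency": len(ident_counts[ident]) / n_patients,
                "vaf": r.cf_vaf,
                "sample_id": patient,
            }
        )
    vafs = [r.cf_vaf for _, r in detected]
    return DetectionSummary(
        detection_rate=len(positives) / n_patients,
        n_patients_positive=len(positives),
        n_patients=n_patients,
        n_mutations=len(detected),
        vaf_range=(min(vafs), max(vafs)) if vafs else None,
        mutation_table=table,
    )
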