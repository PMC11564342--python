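"""Cohort-level comparisons of mutation frequencies.

Per-gene and per-pathway Fisher tests between patient groups (adenoma vs
stage-I carcinoma vs inherited polyposis), the persistent-polyp risk
statistic Ri, and the binomial enrichment test used for co-mutation
patterns. Ri for gene i is the rate ratio

    Ri = (mi / ni) / (M / N)

where mi and ni count mutated patients among the polyp-persistent and
polyp-free groups and M, N are those groups' sizes (the study followed 23
persistent and 19 polyp-free patients).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plasma_rescue import bh_adjust
from .variant_io import GeneMatrix


def gene_frequencies(matrix: GeneMatrix, cohort: str) -> pd.Series:
    """Fraction of the cohort's patients mutated, per gene."""
    sub = matrix.subset(cohort)
    return sub.mean(axis=0)


@dataclasses.dataclass
class FrequencyComparison:
    gene: str
    freq_a: float
    freq_b: float
    mut_a: int
    mut_b: int
    n_a: int
    n_b: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None


def fisher_2x2(mut_a: int, n_a: int, mut_b: int, n_b: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of mutated/wild-type counts; returns
    (odds ratio, p)."""
    table = [[mut_a, n_a - mut_a], [mut_b, n_b - mut_b]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def compare_frequencies(
    matrix: GeneMatrix,
    cohort_a: str,
    cohort_b: str,
    adjust: str = "none",
) -> list[FrequencyComparison]:
    """Per-gene two-sided Fisher comparison of mutation frequency between
    two cohorts, optionally BH-adjusted across genes."""
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    sub_a = matrix.subset(cohort_a)
    sub_b = matrix.subset(cohort_b)
    n_a, n_b = len(sub_a), len(sub_b)
    results = []
    for gene in matrix.genes:
        mut_a = int(sub_a[gene].sum())
        mut_b = int(sub_b[gene].sum())
        odds, p = fisher_2x2(mut_a, n_a, mut_b, n_b)
        results.append(
            FrequencyComparison(
                gene=gene,
                freq_a=mut_a / n_a,
                freq_b=mut_b / n_b,
                mut_a=mut_a,
                mut_b=mut_b,
                n_a=n_a,
                n_b=n_b,
                odds_ratio=odds,
                p_value=p,
            )
        )
    if adjust == "BH":
        qs = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


@dataclasses.dataclass
class PathwayComparison:
    pathway: str
    frac_a: float
    frac_b: float
    altered_a: int
    altered_b: int
    n_a: int
    n_b: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None


def pathway_alteration(
    matrix: GeneMatrix,
    pathways: Mapping[str, Sequence[str]],
    cohort_a: str,
    cohort_b: str,
    adjust: str = "BH",
) -> list[PathwayComparison]:
    """Per-pathway altered-patient fractions and Fisher comparison.

    A patient is altered in a pathway when at least one member gene is
    mutated. Pathways with no genes in the matrix get fraction 0 with a
    warning.
    """
    sub_a = matrix.subset(cohort_a)
    sub_b = matrix.subset(cohort_b)
    n_a, n_b = len(sub_a), len(sub_b)
    results = []
    for name, genes in pathways.items():
        if not genes:
            raise ValueError(f"pathway {name!r} has no genes")
        present = [g for g in genes if g in matrix.genes]
        if not present:
            warnings.warn(f"pathway {name!r}: no member genes in matrix", stacklevel=2)
            alt_a = alt_b = 0
        else:
            alt_a = int((sub_a[present].sum(axis=1) > 0).sum())
            alt_b = int((sub_b[present].sum(axis=1) > 0).sum())
        odds, p = fisher_2x2(alt_a, n_a, alt_b, n_b)
        results.append(
            PathwayComparison(
                pathway=name,
                frac_a=alt_a / n_a,
                frac_b=alt_b / n_b,
                altered_a=alt_a,
                altered_b=alt_b,
                n_a=n_a,
                n_b=n_b,
                odds_ratio=odds,
                p_value=p,
            )
        )
    if adjust == "BH":
        qs = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results


# --------------------------------------------------------------------------
# Persistent-polyp risk statistic

@dataclasses.dataclass(frozen=True)
class PersistenceInput:
    gene: str
    mi: int  # mutated among polyp-persistent patients
    ni: int  # mutated among polyp-free patients
    M: int  # total persistent
    N: int  # total polyp-free

    def __post_init__(self) -> None:
        if not (0 <= self.mi <= self.M and 0 <= self.ni <= self.N):
            raise ValueError(f"invalid counts for {self.gene}")


@dataclasses.dataclass
class PersistenceResult:
    gene: str
    ri: float
    odds_ratio: float
    p_value: float
    continuity_corrected: bool
    is_risk_gene: bool


def persistence_risk(
    inputs: Sequence[PersistenceInput],
    min_total: int = 2,
    ri_threshold: float = 1.0,
    max_p: float = 0.1,
) -> list[PersistenceResult]:
    """Rank genes by the persistence rate ratio Ri with a Fisher exact p.

    Ri is the printed rate-ratio form (mi/ni)/(M/N); the classical odds
    ratio from the same 2x2 table is reported alongside. A 0.5 continuity
    constant is added to both numerator counts when ni = 0 so Ri stays
    finite (flagged). Genes with mi + ni < ``min_total`` are skipped; risk
    genes are those with Ri > ``ri_threshold`` and p <= ``max_p``.
    """
    results = []
    for inp in inputs:
        if inp.M == 0 or inp.N == 0:
            raise ValueError("cohort totals M and N must be positive")
        if inp.mi + inp.ni < min_total:
            continue
        corrected = inp.ni == 0
        c = 0.5 if corrected else 0.0
        ri = ((inp.mi + c) / (inp.ni + c)) / (inp.M / inp.N)
        odds, p = fisher_2x2(inp.mi, inp.M, inp.ni, inp.N)
        results.append(
            PersistenceResult(
                gene=inp.gene,
                ri=ri,
                odds_ratio=odds,
                p_value=p,
                continuity_corrected=corrected,
                is_risk_gene=ri > ri_threshold and p <= max_p,
            )
        )
    results.sort(key=lambda r: -r.ri)
    return results


def persistence_inputs_from_matrix(matrix: GeneMatrix) -> list[PersistenceInput]:
    """Build per-gene persistence counts from the matrix's outcome labels."""
    if matrix.outcome is None:
        raise ValueError("matrix carries no outcome labels")
    persistent = matrix.values.loc[matrix.outcome == "persistent"]
    free = matrix.values.loc[matrix.outcome == "polyp-free"]
    if persistent.empty or free.empty:
        raise ValueError("need patients in both outcome groups")
    return [
        PersistenceInput(
            gene=g,
            mi=int(persistent[g].sum()),
            ni=int(free[g].sum()),
            M=len(persistent),
            N=len(free),
        )
        for g in matrix.genes
    ]


def enrichment_binomial(k: int, n: int, p0: float) -> float:
    """One-sided binomial enrichment p-value, P(X >= k | Binomial(n, p0))."""
    if not 0 < p0 < 1:
        raise ValueError("baseline fraction p0 must lie in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k - 1, n, p0))
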