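"""Clonal-evolution statistics: clonality split, 1/f neutrality test, dN/dS.

Neutral tumor growth predicts that the cumulative number of subclonal
mutations with allele frequency at least f grows linearly in 1/f:
M(f) = (mu/beta) * (1/f - 1/fmax). A sample is classified as neutrally
evolved when the R-squared of the least-squares fit (through the origin in
the transformed coordinate x = 1/f - 1/fmax) reaches 0.98 over the
subclonal window 0.1 < VAF < 0.25. Mutations at VAF >= 0.25 are treated as
clonal.

Selection strength is quantified by dN/dS: context-specific mutation rates
are anchored on synonymous sites (assumed neutral) across 96
strand-collapsed trinucleotide substitution classes; the ratio of observed
to expected nonsynonymous mutations then measures selection (> 1 positive,
< 1 negative), globally or per gene with a Poisson test.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .variant_io import VariantKey

# --------------------------------------------------------------------------
# Clonality and neutrality

CLONAL_CUTOFF = 0.25
NEUTRAL_R2 = 0.98
MIN_SUBCLONAL = 12  # fits on fewer points are not evaluable


@dataclasses.dataclass
class VAFSpectrum:
    sample_id: str
    vafs: np.ndarray

    def __post_init__(self) -> None:
        self.vafs = np.asarray(self.vafs, dtype=float)
        if self.vafs.size and not ((self.vafs > 0) & (self.vafs <= 1)).all():
            raise ValueError("VAFs must lie in (0, 1]")


@dataclasses.dataclass
class NeutralityResult:
    sample_id: str
    r_squared: float
    mu_per_beta: float
    n_subclonal: int
    is_neutral: bool
    evaluable: bool


def split_clonality(
    spectrum: VAFSpectrum, cutoff: float = CLONAL_CUTOFF
) -> tuple[np.ndarray, np.ndarray]:
    """Partition VAFs into clonal (>= cutoff) and subclonal (< cutoff)."""
    clonal = spectrum.vafs[spectrum.vafs >= cutoff]
    subclonal = spectrum.vafs[spectrum.vafs < cutoff]
    return clonal, subclonal


def neutrality_test(
    spectrum: VAFSpectrum,
    fmin: float = 0.1,
    fmax: float = CLONAL_CUTOFF,
    r2_threshold: float = NEUTRAL_R2,
    n_min: int = MIN_SUBCLONAL,
) -> NeutralityResult:
    """1/f test of neutral evolution on the subclonal VAF window.

    M(f) = #{vafs >= f} is evaluated at each distinct subclonal VAF (ties
    collapsed) and regressed through the origin on x = 1/f - 1/fmax. With
    fewer than ``n_min`` usable mutations the sample is flagged not
    evaluable (neither neutral nor non-neutral).
    """
    sub = spectrum.vafs[(spectrum.vafs > fmin) & (spectrum.vafs < fmax)]
    n = int(sub.size)
    if n < n_min:
        return NeutralityResult(spectrum.sample_id, float("nan"), float("nan"), n, False, False)

    f = np.unique(sub)  # ascending
    # M(f): number of subclonal vafs >= each distinct f
    m = n - np.searchsorted(np.sort(sub), f, side="left")
    x = 1.0 / f - 1.0 / fmax
    y = m.astype(float)

    slope = float(np.dot(x, y) / np.dot(x, x))
    residuals = y - slope * x
    ss_res = float(np.dot(residuals, residuals))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return NeutralityResult(
        sample_id=spectrum.sample_id,
        r_squared=r2,
        mu_per_beta=slope,
        n_subclonal=n,
        is_neutral=r2 >= r2_threshold,
        evaluable=True,
    )


# --------------------------------------------------------------------------
# Trinucleotide contexts and the genetic code

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    bases = "TCAG"
    amino = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    table = {}
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = amino[i]
                i += 1
    return table


_CODON_TABLE = _build_codon_table()
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def collapse_context(left: str, ref: str, right: str, alt: str) -> str:
    """Strand-collapsed trinucleotide substitution label, e.g. 'A[C>T]G'.

    Substitutions with a purine reference are reported on the opposite
    strand so every label has a pyrimidine (C/T) center; 96 classes total.
    """
    if ref in "AG":
        left, ref, right = _revcomp(right), _revcomp(ref), _revcomp(left)
        alt = _revcomp(alt)
    return f"{left}[{ref}>{alt}]{right}"


CONTEXTS_96: list[str] = [
    f"{l}[{r}>{a}]{rt}"
    for r in "CT"
    for a in "ACGT"
    if a != r
    for l in "ACGT"
    for rt in "ACGT"
]
CONTEXT_INDEX: dict[str, int] = {c: i for i, c in enumerate(CONTEXTS_96)}


@dataclasses.dataclass
class OpportunityTable:
    """Expected nonsynonymous/synonymous site counts per gene per context.

    ``nonsyn`` and ``syn`` are (n_genes x 96) arrays; their per-gene totals
    sum to 3 x CDS length (every site has three possible substitutions).
    """

    genes: list[str]
    nonsyn: np.ndarray
    syn: np.ndarray

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)


def iter_cds_substitutions(seq: str) -> Iterable[tuple[int, str, str, str, int, bool]]:
    """Yield (pos0, ref, alt, context_label, context_idx, synonymous) for
    every possible single-base substitution of a CDS.

    CDS boundary sites take an 'A' flank by convention.
    """
    seq = seq.upper()
    n = len(seq)
    for i in range(n):
        ref = seq[i]
        left = seq[i - 1] if i > 0 else "A"
        right = seq[i + 1] if i < n - 1 else "A"
        codon_start = (i // 3) * 3
        codon = seq[codon_start : codon_start + 3]
        offset = i - codon_start
        aa = _CODON_TABLE[codon]
        for alt in "ACGT":
            if alt == ref:
                continue
            new_codon = codon[:offset] + alt + codon[offset + 1 :]
            synonymous = _CODON_TABLE[new_codon] == aa
            label = collapse_context(left, ref, right, alt)
            yield i, ref, alt, label, CONTEXT_INDEX[label], synonymous


def build_opportunity_table(cds: Mapping[str, str]) -> OpportunityTable:
    """Tally per-gene nonsynonymous/synonymous opportunities per context.

    ``cds`` maps gene name to its coding sequence (already on the coding
    strand, length divisible by 3, no internal stop codons).
    """
    genes = list(cds)
    nonsyn = np.zeros((len(genes), 96))
    syn = np.zeros((len(genes), 96))
    for g, gene in enumerate(genes):
        seq = cds[gene].upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS length of {gene} not divisible by 3")
        for start in range(0, len(seq) - 3, 3):
            if _CODON_TABLE[seq[start : start + 3]] == "*":
                raise ValueError(f"internal stop codon in {gene} at codon {start // 3}")
        for _, _, _, _, ctx, is_syn in iter_cds_substitutions(seq):
            if is_syn:
                syn[g, ctx] += 1
            else:
                nonsyn[g, ctx] += 1
    return OpportunityTable(genes=genes, nonsyn=nonsyn, syn=syn)


# --------------------------------------------------------------------------
# dN/dS

@dataclasses.dataclass(frozen=True)
class CodingMutation:
    """One observed coding mutation in context."""

    gene: str
    context: str  # strand-collapsed label, e.g. 'A[C>T]G'
    synonymous: bool
    vaf: float | None = None


@dataclasses.dataclass
class DnDsResult:
    scope: str  # global / clonal / subclonal / gene
    dnds: float
    ci_low: float
    ci_high: float
    n_obs: int
    n_exp: float
    gene: str | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.dnds <= self.ci_high or np.isnan(self.dnds)):
            raise ValueError("CI must bracket the point estimate")


def _context_rates(
    mutations: Sequence[CodingMutation], opp: OpportunityTable
) -> np.ndarray:
    """Per-context mutation rates anchored on synonymous sites."""
    syn_counts = np.zeros(96)
    for mut in mutations:
        if mut.synonymous:
            syn_counts[CONTEXT_INDEX[mut.context]] += 1
    if syn_counts.sum() == 0:
        raise ValueError("rates unidentifiable: no synonymous mutations observed")
    syn_opp = opp.syn.sum(axis=0)
    rates = np.zeros(96)
    observed = syn_opp > 0
    rates[observed] = syn_counts[observed] / syn_opp[observed]
    # contexts never offering a synonymous site fall back to the pooled rate
    global_rate = syn_counts.sum() / syn_opp.sum()
    rates[~observed] = global_rate
    return rates


def _poisson_ci(k: int, alpha: float = 0.05) -> tuple[float, float]:
    low = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2
    high = stats.chi2.ppf(1 - alpha / 2, 2 * (k + 1)) / 2
    return low, high


def global_dnds(
    mutations: Sequence[CodingMutation],
    opp: OpportunityTable,
    scope: str = "global",
) -> DnDsResult:
    """Observed/expected nonsynonymous ratio pooled over all genes.

    Expected nonsynonymous counts come from the synonymous-anchored
    context rates applied to the nonsynonymous opportunities; the CI is the
    exact Poisson interval of the observed count scaled by the expectation.
    """
    known = {mut.gene for mut in mutations} - set(opp.genes)
    if known:
        raise ValueError(f"mutations in genes absent from opportunity table: {sorted(known)}")
    rates = _context_rates(mutations, opp)
    nonsyn_opp = opp.nonsyn.sum(axis=0)
    expected_n = float(rates @ nonsyn_opp)
    observed_n = sum(1 for m in mutations if not m.synonymous)
    dnds = observed_n / expected_n

    if observed_n == 0:
        low, high = _poisson_ci(0)
        return DnDsResult(
            scope=scope, dnds=0.0, ci_low=0.0, ci_high=high / expected_n,
            n_obs=0, n_exp=expected_n,
        )
    # delta-method CI on log(dnds): the expectation is itself estimated from
    # Poisson synonymous counts, so its sampling variance is propagated,
    # not just the observed count's.
    syn_counts = np.zeros(96)
    for mut in mutations:
        if mut.synonymous:
            syn_counts[CONTEXT_INDEX[mut.context]] += 1
    syn_opp = opp.syn.sum(axis=0)
    observed = syn_opp > 0
    var_exp = float(
        ((nonsyn_opp[observed] / syn_opp[observed]) ** 2 * syn_counts[observed]).sum()
    )
    if (~observed).any() and syn_opp.sum() > 0:
        var_exp += (nonsyn_opp[~observed].sum() / syn_opp.sum()) ** 2 * syn_counts.sum()
    se_log = float(np.sqrt(1.0 / observed_n + var_exp / expected_n**2))
    return DnDsResult(
        scope=scope,
        dnds=dnds,
        ci_low=dnds * np.exp(-1.959964 * se_log),
        ci_high=dnds * np.exp(1.959964 * se_log),
        n_obs=observed_n,
        n_exp=expected_n,
    )


def clonality_dnds(
    mutations: Sequence[CodingMutation],
    opp: OpportunityTable,
    cutoff: float = CLONAL_CUTOFF,
) -> dict[str, DnDsResult]:
    """Global dN/dS computed separately for clonal and subclonal mutations.

    Context rates are re-anchored within each stratum. Mutations without a
    VAF are excluded.
    """
    out = {}
    for scope, keep in (
        ("clonal", lambda v: v >= cutoff),
        ("subclonal", lambda v: v < cutoff),
    ):
        subset = [m for m in mutations if m.vaf is not None and keep(m.vaf)]
        out[scope] = global_dnds(subset, opp, scope=scope)
    return out


def gene_dnds(
    mutations: Sequence[CodingMutation],
    opp: OpportunityTable,
    alpha: float = 0.05,
) -> list[DnDsResult]:
    """Per-gene dN/dS with cohort-wide rates and a one-sided Poisson test.

    A gene is a positive-selection candidate when dN/dS > 1 and
    P(X >= observed | expected) <= alpha.
    """
    import warnings

    rates = _context_rates(mutations, opp)
    gene_to_idx = {g: i for i, g in enumerate(opp.genes)}
    obs: dict[str, int] = {g: 0 for g in opp.genes}
    for mut in mutations:
        if mut.gene not in gene_to_idx:
            warnings.warn(f"gene {mut.gene} absent from opportunity table; skipped", stacklevel=2)
            continue
        if not mut.synonymous:
            obs[mut.gene] += 1

    results = []
    for gene, g in gene_to_idx.items():
        expected_n = float(rates @ opp.nonsyn[g])
        observed_n = obs[gene]
        if expected_n == 0:
            continue
        low, high = _poisson_ci(observed_n)
        p = float(stats.poisson.sf(observed_n - 1, expected_n))
        results.append(
            DnDsResult(
                scope="gene",
                gene=gene,
                dnds=observed_n / expected_n,
                ci_low=low / expected_n,
                ci_high=high / expected_n,
                n_obs=observed_n,
                n_exp=expected_n,
                p_value=p,
            )
        )
    return results


def selected_genes(results: Sequence[DnDsResult], alpha: float = 0.05) -> list[str]:
    return [r.gene for r in results if r.dnds > 1 and r.p_value is not None and r.p_value <= alpha]


# --------------------------------------------------------------------------
# Multi-lesion origin

def shared_mutation_origin(
    lesion_variants: Mapping[str, Iterable[VariantKey]],
) -> tuple[str, set[VariantKey]]:
    """Classify multiple adenomas from one patient as independently arisen
    or sharing a common ancestral origin.

    Verdict is 'shared-ancestor' when at least one identical variant key is
    present in two or more lesions; the shared keys are returned.
    """
    if len(lesion_variants) < 2:
        raise ValueError("need >= 2 lesions to assess shared origin")
    sets = {name: set(keys) for name, keys in lesion_variants.items()}
    shared: set[VariantKey] = set()
    for a, b in combinations(sets, 2):
        shared |= sets[a] & sets[b]
    return ("shared-ancestor" if shared else "independent"), shared
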