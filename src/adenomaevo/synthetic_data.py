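"""Synthetic cohort generators with known ground truth.

The raw study data are under restricted access, so every input the pipeline
consumes is emulated here with the study's statistical structure: an
85-adenoma / 78 stage-I-carcinoma cohort with literature-shaped per-gene
mutation frequencies; three-caller call sets with planted artifact classes
(common-SNP contaminants, low-mappability sites, sub-100 bp clusters,
single-caller false calls); plasma/leukocyte pileups at 1500x/2000x with
tumor shedding in the ~1-3% VAF band; allele-specific copy-number segment
plans hitting a target genome instability index; 1/f subclonal VAF spectra
with binomial read noise; and context-dependent coding mutations with
tunable per-gene selection.

Every generator is a pure function of its configuration and seed. The
master seed fans out to fixed, independent per-generator streams, so adding
a generator never perturbs another's draws.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evolution import CodingMutation, VAFSpectrum, iter_cds_substitutions
from .plasma_rescue import SiteCounts
from .variant_io import CNSegment, GeneMatrix, SomaticCall, VariantKey

# Per-gene mutated-patient fractions (CRA, CRC-I). Values printed for the
# study cohorts are used where available (APC, KRAS, TP53, PIK3CA, CTNNB1,
# SOX9, AXIN2); the rest follow colorectal-cancer literature shapes.
DEFAULT_GENE_FREQS: dict[str, tuple[float, float]] = {
    "APC": (0.67, 0.56),
    "KRAS": (0.39, 0.28),
    "TP53": (0.09, 0.42),
    "PIK3CA": (0.04, 0.14),
    "CTNNB1": (0.11, 0.01),
    "SOX9": (0.13, 0.05),
    "LRP1B": (0.14, 0.06),
    "ARID1A": (0.12, 0.05),
    "AXIN2": (0.09, 0.03),
    "FBXW7": (0.02, 0.12),
    "NRAS": (0.01, 0.08),
    "ATM": (0.04, 0.13),
    "AMER1": (0.05, 0.14),
    "REL": (0.08, 0.01),
    "CNTNAP5": (0.02, 0.13),
    "GATA6": (0.09, 0.02),
    # extra actors for plasma / persistence analyses (not classifier signal)
    "ZNF717": (0.03, 0.02),
    "KMT2C": (0.15, 0.13),
    "KMT2D": (0.08, 0.09),
    "DICER1": (0.07, 0.07),
    "FAT1": (0.09, 0.09),
}

#: The fifteen genes carrying CRA-vs-CRC classification signal.
INFORMATIVE_GENES = [
    "TP53", "PIK3CA", "KRAS", "CNTNAP5", "APC", "GATA6", "REL", "AMER1",
    "CTNNB1", "LRP1B", "AXIN2", "FBXW7", "ARID1A", "NRAS", "ATM",
]

#: Genes promoting polyp persistence in follow-up.
RISK_GENES = ["KMT2C", "DICER1", "KMT2D", "FAT1", "SOX9", "APC"]

CALLERS = ("varscan2", "strelka", "gvc")

# hg19-like autosome lengths, Mb (rounded); the segment-plan genome.
AUTOSOME_MB = [
    249, 243, 198, 191, 181, 171, 159, 146, 141, 136,
    135, 134, 115, 107, 103, 90, 81, 78, 59, 63, 48, 51,
]


@dataclasses.dataclass
class SimConfig:
    """Study-condition parameters for all generators."""

    seed: int
    n_cra: int = 85
    n_crc: int = 78
    n_noise_genes: int = 200
    noise_gene_freq: float = 0.04
    gene_freqs: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQS)
    )
    # caller behaviour
    caller_sensitivities: dict[str, float] = dataclasses.field(
        default_factory=lambda: {c: 1.0 for c in CALLERS}
    )
    n_snp_artifacts: int = 2  # per patient: common-SNP contaminants
    n_lowmap_artifacts: int = 1
    n_cluster_artifacts: int = 1  # sub-100bp artifact pairs
    n_single_caller_false: int = 2
    # depths (mean deduplicated coverage)
    tissue_depth: int = 1000
    plasma_depth: int = 1500
    control_depth: int = 2000
    # plasma shedding
    shed_patient_fraction: float = 5 / 85
    max_shed_mutations: int = 2
    shed_vaf_range: tuple[float, float] = (0.0092, 0.0297)
    background_error: float = 1e-4
    control_error: float = 0.0
    # neutrality window
    fmin: float = 0.1
    fmax: float = 0.25
    # follow-up outcome counts (patients with long-term follow-up)
    n_followed: int = 44
    n_persistent: int = 23
    n_polyp_free: int = 19
    n_cancerous: int = 2
    risk_gene_weight: float = 2.0  # persistence-score bump per mutated risk gene

    def __post_init__(self) -> None:
        for gene, (fa, fb) in self.gene_freqs.items():
            if not (0 <= fa <= 1 and 0 <= fb <= 1):
                raise ValueError(f"invalid frequency for {gene}")
        if self.n_persistent + self.n_polyp_free + self.n_cancerous != self.n_followed:
            raise ValueError("follow-up outcome counts must sum to n_followed")


_STREAMS = {"cohort": 0, "calls": 1, "plasma": 2, "segments": 3, "vafs": 4, "coding": 5}


def stream(cfg_or_seed: SimConfig | int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one generator."""
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SimConfig) else cfg_or_seed
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


@dataclasses.dataclass
class TruthSet:
    """Ground truth emitted alongside the generated data."""

    variants: dict[str, list[SomaticCall]]  # per-patient true tissue variants
    shed: dict[str, set[VariantKey]]  # truly plasma-shed variants
    informative_genes: list[str]
    noise_genes: list[str]
    risk_genes: list[str]
    selection: dict[str, float] = dataclasses.field(default_factory=dict)


def _all_genes(cfg: SimConfig) -> tuple[list[str], list[str]]:
    noise = [f"NOISE{i:03d}" for i in range(1, cfg.n_noise_genes + 1)]
    return list(cfg.gene_freqs) + noise, noise


def gene_loci(genes: Sequence[str]) -> dict[str, tuple[str, int]]:
    """Deterministic synthetic panel layout: each gene gets a locus."""
    loci = {}
    for i, gene in enumerate(genes):
        chrom = f"chr{1 + i % 22}"
        start = 1_000_000 + (i // 22) * 200_000
        loci[gene] = (chrom, start)
    return loci


# --------------------------------------------------------------------------
# Cohort matrix and true variants


def simulate_cohort(cfg: SimConfig) -> tuple[GeneMatrix, TruthSet]:
    """Binary gene-by-patient matrix for the CRA and CRC-I cohorts, with
    per-patient true tissue variants, shed subsets and follow-up outcomes."""
    rng = stream(cfg, "cohort")
    genes, noise_genes = _all_genes(cfg)
    patients = [f"CRA{i:03d}" for i in range(1, cfg.n_cra + 1)] + [
        f"CRC{i:03d}" for i in range(1, cfg.n_crc + 1)
    ]
    cohort = pd.Series(
        ["CRA"] * cfg.n_cra + ["CRC-I"] * cfg.n_crc, index=patients, name="cohort"
    )

    values = np.zeros((len(patients), len(genes)), dtype=int)
    for j, gene in enumerate(genes):
        if gene in cfg.gene_freqs:
            f_cra, f_crc = cfg.gene_freqs[gene]
        else:
            f_cra = f_crc = cfg.noise_gene_freq
        values[: cfg.n_cra, j] = rng.random(cfg.n_cra) < f_cra
        values[cfg.n_cra :, j] = rng.random(cfg.n_crc) < f_crc
    df = pd.DataFrame(values, index=patients, columns=genes)

    outcome = _assign_outcomes(cfg, df, rng)
    matrix = GeneMatrix(values=df, cohort=cohort, outcome=outcome)

    loci = gene_loci(genes)
    variants: dict[str, list[SomaticCall]] = {}
    shed: dict[str, set[VariantKey]] = {}
    cra_patients = patients[: cfg.n_cra]
    shedders = set(
        rng.choice(
            cra_patients,
            size=round(cfg.shed_patient_fraction * cfg.n_cra),
            replace=False,
        )
    )
    for patient in patients:
        muts: list[SomaticCall] = []
        for gene in genes:
            if not df.at[patient, gene]:
                continue
            chrom, start = loci[gene]
            pos = start + int(rng.integers(0, 30)) * 250  # >= 250 bp spacing
            ref, alt = _random_snv(rng)
            # clonal/subclonal VAF mixture
            if rng.random() < 0.7:
                vaf_true = float(np.clip(rng.normal(0.35, 0.08), 0.26, 0.6))
            else:
                vaf_true = float(rng.uniform(0.05, 0.25))
            depth = int(rng.poisson(cfg.tissue_depth))
            alt_reads = int(rng.binomial(depth, vaf_true))
            muts.append(
                SomaticCall(
                    patient_id=patient,
                    sample_type="tissue",
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    caller="truth",
                    vaf=alt_reads / depth if depth else 0.0,
                    depth=depth,
                    alt_reads=alt_reads,
                    mappability=float(rng.uniform(0.85, 1.0)),
                    gene=gene,
                    variant_class=str(
                        rng.choice(
                            ["missense", "nonsense", "frameshift", "synonymous"],
                            p=[0.6, 0.12, 0.08, 0.2],
                        )
                    ),
                )
            )
        variants[patient] = muts
        if patient in shedders and muts:
            k = min(len(muts), int(rng.integers(1, cfg.max_shed_mutations + 1)))
            chosen = rng.choice(len(muts), size=k, replace=False)
            shed[patient] = {muts[i].key for i in chosen}
        else:
            shed[patient] = set()

    truth = TruthSet(
        variants=variants,
        shed=shed,
        informative_genes=list(INFORMATIVE_GENES),
        noise_genes=noise_genes,
        risk_genes=list(RISK_GENES),
    )
    return matrix, truth


def _assign_outcomes(cfg: SimConfig, df: pd.DataFrame, rng) -> pd.Series:
    """Follow-up outcomes for the first ``n_followed`` adenoma patients.

    Persistence is enriched in carriers of the planted risk genes: followed
    patients are ranked by mutated-risk-gene count plus noise, the top
    scorers (after removing the cancerous pair) become 'persistent'.
    """
    outcome = pd.Series(pd.NA, index=df.index, dtype="object")
    followed = list(df.index[: cfg.n_followed])
    cancerous = list(rng.choice(followed, size=cfg.n_cancerous, replace=False))
    rest = [p for p in followed if p not in cancerous]
    score = {
        p: cfg.risk_gene_weight * int(df.loc[p, RISK_GENES].sum()) + rng.random()
        for p in rest
    }
    rest.sort(key=lambda p: -score[p])
    for p in cancerous:
        outcome[p] = "cancerous"
    for p in rest[: cfg.n_persistent]:
        outcome[p] = "persistent"
    for p in rest[cfg.n_persistent :]:
        outcome[p] = "polyp-free"
    return outcome


def _random_snv(rng) -> tuple[str, str]:
    bases = "ACGT"
    ref = bases[rng.integers(0, 4)]
    alt = bases[rng.integers(0, 4)]
    while alt == ref:
        alt = bases[rng.integers(0, 4)]
    return ref, alt


# --------------------------------------------------------------------------
# Multi-caller call sets with planted artifacts


def simulate_multicaller_calls(
    truth: TruthSet, cfg: SimConfig, sample_type: str = "tissue"
) -> tuple[list[SomaticCall], set[tuple]]:
    """Per-caller call lists for every patient's true variants plus planted
    artifact calls.

    Returns (calls, artifact keys); artifact keys are
    (patient, sample_type, chrom, pos, ref, alt) tuples. Artifact classes:
    common-SNP contaminants (population AF > 1%), low-mappability sites,
    sub-100 bp proximity clusters and single-caller false calls. Artifact
    positions keep >= 100 bp from true variants so that the planted truth
    survives filtering intact.
    """
    rng = stream(cfg, "calls")
    calls: list[SomaticCall] = []
    artifact_keys: set[tuple] = set()

    for patient, muts in truth.variants.items():
        for mut in muts:
            for caller in CALLERS:
                if rng.random() >= cfg.caller_sensitivities[caller]:
                    continue
                depth = int(rng.poisson(cfg.tissue_depth))
                alt_reads = int(rng.binomial(depth, max(mut.vaf, 1e-6)))
                calls.append(
                    dataclasses.replace(
                        mut,
                        sample_type=sample_type,
                        caller=caller,
                        depth=depth,
                        alt_reads=alt_reads,
                        vaf=alt_reads / depth if depth else 0.0,
                    )
                )

        # artifacts live on a reserved chromosome arm, away from true loci
        arm_base = 50_000_000 + (sum(ord(ch) for ch in patient) % 1000) * 10_000
        slot = [arm_base]

        def place(offset: int = 0) -> int:
            pos = slot[0] + offset
            slot[0] += 500
            return pos

        def artifact(
            pos, ref, alt, callers, vaf, pop_af=None, mapp=0.95
        ) -> None:
            for caller in callers:
                depth = int(rng.poisson(cfg.tissue_depth))
                alt_reads = max(1, int(rng.binomial(depth, vaf)))
                calls.append(
                    SomaticCall(
                        patient_id=patient,
                        sample_type=sample_type,
                        chrom="chr22",
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        caller=caller,
                        vaf=alt_reads / depth,
                        depth=depth,
                        alt_reads=alt_reads,
                        pop_af_1kg=pop_af,
                        mappability=mapp,
                        gene=None,
                        variant_class="other",
                    )
                )
            artifact_keys.add((patient, sample_type, "chr22", pos, ref, alt))

        for _ in range(cfg.n_snp_artifacts):
            ref, alt = _random_snv(rng)
            artifact(
                place(), ref, alt, CALLERS[:2],
                vaf=float(rng.uniform(0.3, 0.6)),
                pop_af=float(rng.uniform(0.02, 0.3)),
            )
        for _ in range(cfg.n_lowmap_artifacts):
            ref, alt = _random_snv(rng)
            artifact(
                place(), ref, alt, CALLERS[:2],
                vaf=float(rng.uniform(0.1, 0.4)),
                mapp=float(rng.uniform(0.2, 0.74)),
            )
        for _ in range(cfg.n_cluster_artifacts):
            base = place()
            for offset in (0, 40):  # 40 bp apart: a proximity cluster
                ref, alt = _random_snv(rng)
                artifact(
                    base + offset, ref, alt, CALLERS,
                    vaf=float(rng.uniform(0.1, 0.4)),
                )
        for _ in range(cfg.n_single_caller_false):
            ref, alt = _random_snv(rng)
            artifact(
                place(), ref, alt, CALLERS[:1],
                vaf=float(rng.uniform(0.005, 0.045)),
            )
    return calls, artifact_keys


# --------------------------------------------------------------------------
# Plasma pileup counts


def simulate_plasma_counts(
    truth: TruthSet, cfg: SimConfig
) -> dict[str, list[SiteCounts]]:
    """Binomial cfDNA/leukocyte pileups at every tissue-mutation site.

    Shed variants draw their plasma VAF from the configured band
    (defaults to the ~0.9-3% range); unshed sites see only background
    error. Control counts use the leukocyte error rate (0 by default)."""
    rng = stream(cfg, "plasma")
    counts: dict[str, list[SiteCounts]] = {}
    lo, hi = cfg.shed_vaf_range
    for patient, muts in truth.variants.items():
        sites = []
        for mut in muts:
            if mut.key in truth.shed[patient]:
                vaf = float(rng.uniform(lo, hi))
            else:
                vaf = cfg.background_error
            cf_depth = int(rng.poisson(cfg.plasma_depth))
            cf_alt = int(rng.binomial(cf_depth, vaf))
            ctrl_depth = int(rng.poisson(cfg.control_depth))
            ctrl_alt = (
                int(rng.binomial(ctrl_depth, cfg.control_error))
                if cfg.control_error > 0
                else 0
            )
            sites.append(
                SiteCounts(
                    variant=mut.key,
                    cf_alt=cf_alt,
                    cf_ref=cf_depth - cf_alt,
                    ctrl_alt=ctrl_alt,
                    ctrl_ref=ctrl_depth - ctrl_alt,
                )
            )
        counts[patient] = sites
    return counts


# --------------------------------------------------------------------------
# Copy-number segment plans


def simulate_segments(
    target_gii: float,
    genome_mb: Sequence[int] | None = None,
    chunk_mb: int = 10,
) -> list[CNSegment]:
    """Construct a segment plan whose GII equals ``target_gii`` exactly.

    The genome (autosome plan by default) is tiled with aberrant chunks --
    cycling gain, loss, copy-neutral LOH -- until the aberrant length
    reaches the target fraction, with one partial chunk to land exactly;
    the remainder is neutral diploid."""
    if not 0 <= target_gii <= 1:
        raise ValueError("target GII must be in [0, 1]")
    genome_mb = list(genome_mb or AUTOSOME_MB)
    mb = 1_000_000
    total = sum(genome_mb) * mb
    budget = round(target_gii * total)
    states = [("gain", 3, 1), ("loss", 1, 0), ("cnloh", 2, 0)]
    segments: list[CNSegment] = []
    state_i = 0
    for c, size_mb in enumerate(genome_mb):
        chrom = f"chr{c + 1}"
        pos = 0
        end = size_mb * mb
        while pos < end:
            if budget > 0:
                length = min(chunk_mb * mb, budget, end - pos)
                _, total_cn, minor_cn = states[state_i % 3]
                state_i += 1
                budget -= length
            else:
                length = end - pos
                total_cn, minor_cn = 2, 1
            segments.append(
                CNSegment(chrom, pos, pos + length, total_cn, minor_cn)
            )
            pos += length
    return segments


# --------------------------------------------------------------------------
# VAF spectra


def _inverse_cdf_1f2(u: np.ndarray, fmin: float, fmax: float) -> np.ndarray:
    """Quantile function of the density proportional to 1/f^2 on (fmin, fmax)."""
    return 1.0 / (1.0 / fmin - u * (1.0 / fmin - 1.0 / fmax))


def simulate_neutral_vafs(
    n: int = 1000,
    fmin: float = 0.1,
    fmax: float = 0.25,
    depth: int | None = 1000,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "neutral",
) -> VAFSpectrum:
    """Subclonal VAFs from a neutrally evolving tumor.

    Frequencies follow the 1/f^2 density on (fmin, fmax), so the cumulative
    count M(f) grows linearly in 1/f - 1/fmax. ``depth`` adds binomial read
    sampling noise; ``depth=None`` places points noiselessly at the exact
    inverse-CDF quantiles (M(f) exactly on the model line)."""
    rng = _as_rng(rng)
    if depth is None:
        u = np.arange(n) / n  # u=0 at fmin so M(f) passes through the origin
        vafs = _inverse_cdf_1f2(u, fmin, fmax)
    else:
        f = _inverse_cdf_1f2(rng.random(n), fmin, fmax)
        reads = rng.binomial(depth, f)
        vafs = reads[reads > 0] / depth
    return VAFSpectrum(sample_id=sample_id, vafs=vafs)


def simulate_selected_vafs(
    n_cluster: int = 300,
    cluster_vaf: float = 0.18,
    cluster_sd: float = 0.004,
    n_tail: int = 60,
    fmin: float = 0.1,
    fmax: float = 0.25,
    depth: int | None = 1000,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "selected",
) -> VAFSpectrum:
    """Non-neutral spectrum: a dominant subclonal cluster plus a sparse
    neutral tail, violating the 1/f shape."""
    rng = _as_rng(rng)
    cluster = rng.normal(cluster_vaf, cluster_sd, size=n_cluster)
    tail = _inverse_cdf_1f2(rng.random(n_tail), fmin, fmax)
    f = np.clip(np.concatenate([cluster, tail]), 1e-4, 1.0)
    if depth is not None:
        reads = rng.binomial(depth, f)
        f = reads[reads > 0] / depth
    return VAFSpectrum(sample_id=sample_id, vafs=f)


# --------------------------------------------------------------------------
# Coding mutations over trinucleotide opportunities


def make_synthetic_cds(
    n_genes: int = 100,
    n_codons: int = 160,
    rng: np.random.Generator | int | None = None,
    names: Sequence[str] | None = None,
) -> dict[str, str]:
    """Random stop-free coding sequences (a synthetic panel CDS set)."""
    rng = _as_rng(rng)
    codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    names = list(names) if names is not None else [f"G{i:03d}" for i in range(1, n_genes + 1)]
    cds = {}
    for name in names:
        idx = rng.integers(0, len(codons), size=n_codons)
        cds[name] = "".join(codons[i] for i in idx)
    return cds


@dataclasses.dataclass
class SubstitutionSpace:
    """Pre-enumerated substitution universe of a CDS set (reusable across
    replicate draws)."""

    genes: list[str]
    contexts: list[str]
    synonymous: np.ndarray  # bool per substitution

    @classmethod
    def from_cds(cls, cds: Mapping[str, str]) -> "SubstitutionSpace":
        genes: list[str] = []
        contexts: list[str] = []
        synonymous: list[bool] = []
        for gene, seq in cds.items():
            for _, _, _, label, _, is_syn in iter_cds_substitutions(seq):
                genes.append(gene)
                contexts.append(label)
                synonymous.append(is_syn)
        return cls(genes=genes, contexts=contexts, synonymous=np.asarray(synonymous))


def simulate_coding_mutations(
    cds: Mapping[str, str],
    w: Mapping[str, float] | float = 1.0,
    n: int = 2000,
    rng: np.random.Generator | int | None = None,
    clonal_fraction: float = 0.6,
    space: SubstitutionSpace | None = None,
) -> list[CodingMutation]:
    """Draw coding mutations over trinucleotide opportunities.

    Each possible substitution is weighted 1 if synonymous and by the
    gene's selection coefficient ``w`` if nonsynonymous (w > 1 positive
    selection, w < 1 negative, w = 1 neutral). VAFs are attached from a
    clonal/subclonal mixture so clonality-stratified dN/dS is exercisable.
    Pass a precomputed ``space`` when drawing many replicates."""
    rng = _as_rng(rng)
    if not isinstance(w, Mapping):
        w = {gene: float(w) for gene in cds}
    if space is None:
        space = SubstitutionSpace.from_cds(cds)
    genes, contexts, synonymous = space.genes, space.contexts, space.synonymous

    wg = np.array([w.get(g, 1.0) for g in genes])
    probs = np.where(synonymous, 1.0, wg)
    probs = probs / probs.sum()
    picks = rng.choice(len(probs), size=n, replace=True, p=probs)

    mutations = []
    for i in picks:
        if rng.random() < clonal_fraction:
            vaf = float(np.clip(rng.normal(0.35, 0.08), 0.26, 0.6))
        else:
            vaf = float(rng.uniform(0.05, 0.25))
        mutations.append(
            CodingMutation(
                gene=genes[i], context=contexts[i], synonymous=synonymous[i], vaf=vaf
            )
        )
    return mutations


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
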