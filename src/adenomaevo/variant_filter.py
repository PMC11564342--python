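"""Consensus and quality filtering of multi-caller somatic call sets.

Tissue calls are retained when at least two independent callers agree on the
same normalised allele. Plasma calls additionally require a clean matched
leukocyte (normal VAF = 0) and, when only a single caller saw the variant, a
VAF of at least 5%. Quality filters then drop common polymorphisms
(population AF > 1%), poorly mappable sites (< 0.75) and clustered calls
(< 100 bp apart within one sample, all members of a cluster removed as
presumptive alignment artifacts).
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

from .variant_io import SomaticCall, VariantKey


@dataclasses.dataclass
class FilterConfig:
    """Thresholds for consensus and quality filtering (study defaults)."""

    max_pop_af: float = 0.01
    min_mappability: float = 0.75
    min_pair_distance: int = 100
    min_callers_tissue: int = 2
    plasma_single_caller_min_vaf: float = 0.05
    require_normal_vaf_zero_plasma: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_pop_af <= 1:
            raise ValueError("max_pop_af must be in [0,1]")
        if not 0 <= self.min_mappability <= 1:
            raise ValueError("min_mappability must be in [0,1]")
        if self.min_pair_distance < 0:
            raise ValueError("min_pair_distance must be >= 0")
        if self.min_callers_tissue < 1:
            raise ValueError("min_callers_tissue must be >= 1")
        if not 0 <= self.plasma_single_caller_min_vaf <= 1:
            raise ValueError("plasma_single_caller_min_vaf must be in [0,1]")


@dataclasses.dataclass
class FilterReport:
    """Decision trail: which rule(s) removed which variant."""

    removed: dict[tuple, list[str]] = dataclasses.field(default_factory=dict)
    n_input: int = 0
    n_kept: int = 0

    def mark(self, key, rule: str) -> None:
        self.removed.setdefault(key, []).append(rule)

    @property
    def counts_per_rule(self) -> Counter:
        counter: Counter = Counter()
        for rules in self.removed.values():
            counter.update(rules)
        return counter

    def check_totals(self) -> None:
        if self.n_kept + len(self.removed) != self.n_input:
            raise AssertionError("kept + removed != input")


def _group_key(call: SomaticCall) -> tuple:
    """Identity for cross-caller matching: sample plus normalised allele."""
    return (call.patient_id, call.sample_type, call.chrom, call.pos, call.ref, call.alt)


def consensus_merge(
    calls: Sequence[SomaticCall],
    mode: str,
    cfg: FilterConfig | None = None,
    normal_vafs: Mapping[VariantKey, float] | None = None,
) -> tuple[list[SomaticCall], FilterReport]:
    """Merge per-caller calls into consensus variants.

    Tissue mode keeps alleles supported by >= ``min_callers_tissue`` distinct
    callers. Plasma mode keeps alleles whose matched-normal VAF is 0 and that
    either reach the caller quorum or exceed the single-caller VAF floor.
    The merged record takes VAF/depth from the deepest caller.

    ``normal_vafs`` maps each plasma variant's :class:`VariantKey` to its
    VAF in the matched leukocyte sample; required in plasma mode.
    """
    cfg = cfg or FilterConfig()
    if mode not in ("tissue", "plasma"):
        raise ValueError(f"mode must be 'tissue' or 'plasma', got {mode!r}")
    if mode == "plasma" and cfg.require_normal_vaf_zero_plasma and normal_vafs is None:
        raise ValueError("plasma mode requires matched-normal VAFs per variant")

    groups: dict[tuple, list[SomaticCall]] = defaultdict(list)
    for call in calls:
        groups[_group_key(call)].append(call)

    report = FilterReport(n_input=len(groups))
    kept: list[SomaticCall] = []
    for key, members in groups.items():
        n_callers = len({m.caller for m in members})
        best = max(members, key=lambda m: m.depth)
        rules: list[str] = []
        if mode == "tissue":
            if n_callers < cfg.min_callers_tissue:
                rules.append("caller_consensus")
        else:
            if cfg.require_normal_vaf_zero_plasma:
                nv = normal_vafs.get(best.key)
                if nv is None:
                    raise ValueError(f"missing matched-normal VAF for {best.key}")
                if nv > 0:
                    rules.append("normal_vaf_nonzero")
            if n_callers < 2 and best.vaf < cfg.plasma_single_caller_min_vaf:
                rules.append("single_caller_low_vaf")
        if rules:
            for rule in rules:
                report.mark(key, rule)
        else:
            kept.append(best)
    report.n_kept = len(kept)
    report.check_totals()
    return kept, report


def quality_filters(
    variants: Sequence[SomaticCall], cfg: FilterConfig | None = None
) -> tuple[list[SomaticCall], FilterReport]:
    """Population-AF, mappability and proximity filters.

    A variant is removed when max(pop_af_1kg, pop_af_exac) exceeds
    ``max_pop_af`` (missing values treated as 0), when its mappability is
    below ``min_mappability`` (missing mappability passes), or when another
    variant of the same patient+sample lies closer than
    ``min_pair_distance`` bp on the same chromosome -- in which case the
    whole cluster is removed.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=len(variants))

    rules_by_idx: dict[int, list[str]] = defaultdict(list)
    for i, v in enumerate(variants):
        if v.max_pop_af() > cfg.max_pop_af:
            rules_by_idx[i].append("population_af")
        if v.mappability is not None and v.mappability < cfg.min_mappability:
            rules_by_idx[i].append("mappability")

    # Proximity: within patient+sample_type+chromosome, any pair < D bp apart
    # marks both members.
    by_sample: dict[tuple, list[int]] = defaultdict(list)
    for i, v in enumerate(variants):
        by_sample[(v.patient_id, v.sample_type, v.chrom)].append(i)
    for idxs in by_sample.values():
        idxs = sorted(idxs, key=lambda i: variants[i].pos)
        for a, b in zip(idxs, idxs[1:]):
            if abs(variants[b].pos - variants[a].pos) < cfg.min_pair_distance:
                for i in (a, b):
                    if "proximity" not in rules_by_idx[i]:
                        rules_by_idx[i].append("proximity")

    kept: list[SomaticCall] = []
    for i, v in enumerate(variants):
        if rules_by_idx.get(i):
            # per-record key: the same allele may appear once per caller
            for rule in rules_by_idx[i]:
                report.mark((*_group_key(v), v.caller, i), rule)
        else:
            kept.append(v)
    report.n_kept = len(kept)
    report.check_totals()
    return kept, report


def filter_calls(
    calls: Sequence[SomaticCall],
    mode: str,
    cfg: FilterConfig | None = None,
    normal_vafs: Mapping[VariantKey, float] | None = None,
) -> tuple[list[SomaticCall], FilterReport]:
    """Full filter: caller consensus followed by quality filters.

    Proximity is evaluated on the post-consensus variant set (clustered
    artifact calls that already failed consensus do not veto their
    neighbours).
    """
    merged, rep1 = consensus_merge(calls, mode=mode, cfg=cfg, normal_vafs=normal_vafs)
    kept, rep2 = quality_filters(merged, cfg=cfg)
    combined = FilterReport(n_input=rep1.n_input, n_kept=rep2.n_kept)
    combined.removed = {**rep1.removed}
    for key, rules in rep2.removed.items():
        combined.removed.setdefault(key, []).extend(rules)
    combined.check_totals()
    return kept, combined


def report_to_rows(report: FilterReport) -> list[dict]:
    """Flatten a FilterReport for TSV output."""
    rows = []
    for key, rules in sorted(report.removed.items()):
        patient, stype, chrom, pos, ref, alt = key[:6]
        rows.append(
            {
                "patient_id": patient,
                "sample_type": stype,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "removed_by": ",".join(rules),
            }
        )
    return rows
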