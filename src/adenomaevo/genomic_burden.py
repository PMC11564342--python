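"""Per-sample genomic burden: TMB and the genome instability index (GII).

TMB is the number of qualifying somatic mutations per megabase of sequenced
territory (default: nonsynonymous mutations over the 3.34 Mb 451-gene
panel). GII is the fraction of the segmented genome affected by copy-number
gain, loss, or copy-neutral loss of heterozygosity, computed from
allele-specific copy-number segments (FACETS-style output).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .variant_io import CNSegment, SomaticCall, check_non_overlapping

PANEL_SIZE_MB = 3.34

NONSYNONYMOUS_CLASSES = {"missense", "nonsense", "frameshift", "splice"}

SEGMENT_STATES = ("gain", "loss", "cnloh", "neutral")


@dataclasses.dataclass
class BurdenResult:
    tmb: float
    gii: float
    fractions: dict[str, float]  # per segment state, sums to 1

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions sum to {total}, not 1")


def compute_tmb(
    variants: Sequence[SomaticCall],
    panel_size_mb: float = PANEL_SIZE_MB,
    numerator: str = "nonsynonymous",
) -> float:
    """Somatic mutations per megabase of panel territory."""
    if panel_size_mb <= 0:
        raise ValueError("panel size must be positive")
    if numerator == "all":
        count = len(variants)
    elif numerator == "nonsynonymous":
        count = sum(1 for v in variants if v.variant_class in NONSYNONYMOUS_CLASSES)
    else:
        raise ValueError(f"numerator must be 'all' or 'nonsynonymous', got {numerator!r}")
    return count / panel_size_mb


def classify_segment(seg: CNSegment, baseline_ploidy: int = 2) -> str:
    """gain / loss / cnloh / neutral relative to the baseline ploidy."""
    if seg.total_cn > baseline_ploidy:
        return "gain"
    if seg.total_cn < baseline_ploidy:
        return "loss"
    if seg.minor_cn == 0:
        return "cnloh"
    return "neutral"


def segment_state_fractions(
    segments: Sequence[CNSegment], baseline_ploidy: int = 2
) -> dict[str, float]:
    check_non_overlapping(segments)
    lengths = {state: 0 for state in SEGMENT_STATES}
    for seg in segments:
        lengths[classify_segment(seg, baseline_ploidy)] += seg.length
    total = sum(lengths.values())
    if total == 0:
        raise ValueError("zero total segmented length")
    return {state: lengths[state] / total for state in SEGMENT_STATES}


def compute_gii(segments: Sequence[CNSegment], baseline_ploidy: int = 2) -> float:
    """Fraction of segmented genome that is gained, lost, or copy-neutral LOH."""
    fractions = segment_state_fractions(segments, baseline_ploidy)
    return fractions["gain"] + fractions["loss"] + fractions["cnloh"]


def burden(
    variants: Sequence[SomaticCall],
    segments: Sequence[CNSegment],
    panel_size_mb: float = PANEL_SIZE_MB,
    numerator: str = "nonsynonymous",
    baseline_ploidy: int = 2,
) -> BurdenResult:
    fractions = segment_state_fractions(segments, baseline_ploidy)
    return BurdenResult(
        tmb=compute_tmb(variants, panel_size_mb, numerator),
        gii=fractions["gain"] + fractions["loss"] + fractions["cnloh"],
        fractions=fractions,
    )
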