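"""Reading, writing and normalising somatic variant records.

Calls from different callers (varscan2, strelka, gvc, ...) arrive in VCF or
MAF-like tabular form; downstream consensus logic compares them through
normalised :class:`VariantKey` objects so that equivalent indel spellings
collapse to one allele.

Coordinate conventions: variants are 1-based inclusive (VCF/MAF dialect);
copy-number segments are half-open 0-based internally and written out as
plain SEG-style TSV.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam


class SampleType(str, enum.Enum):
    TISSUE = "tissue"
    PLASMA = "plasma"


VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice",
    "synonymous",
    "intron",
    "other",
)

#: Column order of the MAF-like TSV interchange format.
MAF_COLUMNS = [
    "patient_id",
    "sample_type",
    "chrom",
    "pos",
    "ref",
    "alt",
    "caller",
    "vaf",
    "depth",
    "alt_reads",
    "pop_af_1kg",
    "pop_af_exac",
    "mappability",
    "gene",
    "variant_class",
    "protein_change",
]


@dataclasses.dataclass(frozen=True, order=True)
class VariantKey:
    """Normalised (left-aligned, parsimony-trimmed) allele identity."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclasses.dataclass
class SomaticCall:
    """One caller's record of one candidate somatic mutation."""

    patient_id: str
    sample_type: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    caller: str
    vaf: float
    depth: int
    alt_reads: int
    pop_af_1kg: float | None = None
    pop_af_exac: float | None = None
    mappability: float | None = None
    gene: str | None = None
    variant_class: str = "other"
    protein_change: str | None = None

    def __post_init__(self) -> None:
        self.sample_type = SampleType(self.sample_type).value
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        self.validate()

    def validate(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) > depth ({self.depth}) "
                f"at {self.chrom}:{self.pos}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF out of [0,1]: {self.vaf}")
        if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 1.0 / self.depth + 1e-9:
            raise ValueError(
                f"VAF {self.vaf} inconsistent with {self.alt_reads}/{self.depth} "
                f"at {self.chrom}:{self.pos}"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")

    @property
    def key(self) -> VariantKey:
        """Raw (unnormalised) allele key."""
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    def max_pop_af(self) -> float:
        """Largest population allele frequency across databases.

        Missing annotations count as 0: absence from 1000 Genomes / ExAC is
        treated as evidence of rarity.
        """
        return max(self.pop_af_1kg or 0.0, self.pop_af_exac or 0.0)


@dataclasses.dataclass(frozen=True)
class CNSegment:
    """Allele-specific copy-number interval, half-open 0-based."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds major allele for total {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class GeneMatrix:
    """Binary gene-by-patient mutation indicator matrix with cohort labels.

    ``values`` is patients (rows) x genes (columns) with {0,1} entries;
    ``cohort`` maps each patient to its group (CRA, CRC-I, ...); ``outcome``
    optionally records follow-up status (polyp-free / persistent / cancerous).
    """

    values: pd.DataFrame
    cohort: pd.Series
    outcome: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("gene matrix entries must be 0/1")
        if not self.cohort.index.equals(self.values.index):
            self.cohort = self.cohort.reindex(self.values.index)
            if self.cohort.isna().any():
                raise ValueError("cohort labels do not cover all patients")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    def subset(self, cohort: str) -> pd.DataFrame:
        mask = self.cohort == cohort
        if not mask.any():
            raise ValueError(f"no patients in cohort {cohort!r}")
        return self.values.loc[mask]


# ---------------------------------------------------------------------------
# Normalisation


def normalize(call: SomaticCall | VariantKey, reference) -> VariantKey:
    """Left-align and parsimony-trim a variant against the reference.

    ``reference`` is any accessor with ``fetch(chrom, start0, end0)``
    semantics (a :class:`pysam.FastaFile`, a :class:`pyfaidx.Fasta` wrapped
    below, or a dict of chromosome strings). The result is the unique
    minimal, leftmost representation, so two spellings of the same indel
    compare equal. Idempotent.
    """
    chrom = call.chrom
    pos = call.pos
    ref = call.ref.upper()
    alt = call.alt.upper()

    fetch = _fetcher(reference)
    observed = fetch(chrom, pos - 1, pos - 1 + len(ref)).upper()
    if observed != ref:
        raise ValueError(
            f"ref allele {ref!r} at {chrom}:{pos} disagrees with reference {observed!r}"
        )

    # vt-style normalisation: trim shared suffix (extending left when an
    # allele would empty), then trim shared prefix.
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
            elif pos > 1:
                base = fetch(chrom, pos - 2, pos - 1).upper()
                ref, alt = base + ref[:-1], base + alt[:-1]
                pos -= 1
            else:
                break
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


def _fetcher(reference):
    if hasattr(reference, "fetch"):
        return lambda c, s, e: reference.fetch(c, s, e)
    if isinstance(reference, Mapping):
        return lambda c, s, e: str(reference[c][s:e])
    # pyfaidx.Fasta supports chrom[start:end] slicing
    return lambda c, s, e: str(reference[c][s:e])


# ---------------------------------------------------------------------------
# MAF-like TSV


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value in ("", ".", "NA", "nan"):
            return None
    return float(value)


def read_calls(path: str | Path, format: str = "maf") -> list[SomaticCall]:
    """Read somatic calls from ``maf`` (tab-separated) or ``vcf`` files.

    Malformed rows raise :class:`ValueError` naming the offending line.
    Missing annotations stay missing (``None``), never zero-filled.
    """
    if format == "maf":
        return _read_maf(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}; expected 'maf' or 'vcf'")


def _read_maf(path: str | Path) -> list[SomaticCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    calls: list[SomaticCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        d = dict(zip(df.columns, row))
        try:
            calls.append(
                SomaticCall(
                    patient_id=d["patient_id"],
                    sample_type=d["sample_type"],
                    chrom=d["chrom"],
                    pos=int(d["pos"]),
                    ref=d["ref"],
                    alt=d["alt"],
                    caller=d["caller"],
                    vaf=float(d["vaf"]),
                    depth=int(d["depth"]),
                    alt_reads=int(d["alt_reads"]),
                    pop_af_1kg=_parse_optional_float(d["pop_af_1kg"]),
                    pop_af_exac=_parse_optional_float(d["pop_af_exac"]),
                    mappability=_parse_optional_float(d["mappability"]),
                    gene=d["gene"] if pd.notna(d["gene"]) else None,
                    variant_class=d["variant_class"],
                    protein_change=(
                        d["protein_change"] if pd.notna(d["protein_change"]) else None
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return calls


def write_maf(calls: Iterable[SomaticCall], path: str | Path) -> None:
    rows = [
        {col: getattr(c, col) for col in MAF_COLUMNS}
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=MAF_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="")


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient identifier">
##INFO=<ID=STYPE,Number=1,Type=String,Description="Sample type (tissue/plasma)">
##INFO=<ID=CALLER,Number=1,Type=String,Description="Calling tool">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting reads">
##INFO=<ID=AF1KG,Number=1,Type=Float,Description="1000 Genomes AF">
##INFO=<ID=AFEXAC,Number=1,Type=Float,Description="ExAC AF">
##INFO=<ID=MAP,Number=1,Type=Float,Description="Mappability">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">
##INFO=<ID=PC,Number=1,Type=String,Description="Protein change">
"""


def write_vcf(calls: Sequence[SomaticCall], path: str | Path) -> None:
    """Write calls as a single-sample-style VCF 4.2 with annotations in INFO."""
    chroms = sorted({c.chrom for c in calls})
    lines = [_VCF_HEADER.rstrip("\n")]
    for chrom in chroms:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt, c.caller)):
        info = [
            f"PATIENT={c.patient_id}",
            f"STYPE={c.sample_type}",
            f"CALLER={c.caller}",
            f"VAF={c.vaf:.6g}",
            f"DP={c.depth}",
            f"AD={c.alt_reads}",
        ]
        if c.pop_af_1kg is not None:
            info.append(f"AF1KG={c.pop_af_1kg:.6g}")
        if c.pop_af_exac is not None:
            info.append(f"AFEXAC={c.pop_af_exac:.6g}")
        if c.mappability is not None:
            info.append(f"MAP={c.mappability:.6g}")
        if c.gene:
            info.append(f"GENE={c.gene}")
        info.append(f"VC={c.variant_class}")
        if c.protein_change:
            info.append(f"PC={c.protein_change}")
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vcf(path: str | Path) -> list[SomaticCall]:
    calls: list[SomaticCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            for alt in rec.alts or ():
                calls.append(
                    SomaticCall(
                        patient_id=str(info.get("PATIENT", "unknown")),
                        sample_type=str(info.get("STYPE", "tissue")),
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        caller=str(info.get("CALLER", "unknown")),
                        vaf=float(info.get("VAF", 0.0)),
                        depth=int(info.get("DP", 0)),
                        alt_reads=int(info.get("AD", 0)),
                        pop_af_1kg=_maybe(info, "AF1KG"),
                        pop_af_exac=_maybe(info, "AFEXAC"),
                        mappability=_maybe(info, "MAP"),
                        gene=info.get("GENE"),
                        variant_class=str(info.get("VC", "other")),
                        protein_change=info.get("PC"),
                    )
                )
    return calls


def _maybe(info, key) -> float | None:
    value = info.get(key)
    return None if value is None else float(value)


# ---------------------------------------------------------------------------
# Segments and gene matrix


def read_segments(path: str | Path) -> list[CNSegment]:
    """Read SEG-style TSV (chrom, start, end, total_cn, minor_cn).

    Segments must not overlap within a chromosome.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "total_cn", "minor_cn"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    segments = [
        CNSegment(str(r.chrom), int(r.start), int(r.end), int(r.total_cn), int(r.minor_cn))
        for r in df.itertuples(index=False)
    ]
    check_non_overlapping(segments)
    return segments


def check_non_overlapping(segments: Sequence[CNSegment]) -> None:
    by_chrom: dict[str, list[CNSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def write_segments(segments: Iterable[CNSegment], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "total_cn": s.total_cn,
                "minor_cn": s.minor_cn,
            }
            for s in segments
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_matrix(
    path: str | Path, labels_path: str | Path | None = None
) -> GeneMatrix:
    """Read a genes(rows) x patients(columns) TSV, plus optional labels TSV.

    The labels file has columns ``patient``, ``cohort`` and optionally
    ``outcome``. Without it every patient is labelled ``unknown``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.T.astype(int)  # patients x genes internally
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", index_col="patient")
        cohort = lab["cohort"].reindex(values.index)
        if cohort.isna().any():
            missing = list(values.index[cohort.isna()])
            raise ValueError(f"labels missing for patients {missing}")
        outcome = lab["outcome"].reindex(values.index) if "outcome" in lab else None
    else:
        cohort = pd.Series("unknown", index=values.index)
        outcome = None
    return GeneMatrix(values=values, cohort=cohort, outcome=outcome)


def write_gene_matrix(
    matrix: GeneMatrix, path: str | Path, labels_path: str | Path | None = None
) -> None:
    matrix.values.T.to_csv(path, sep="\t")
    if labels_path is not None:
        lab = pd.DataFrame({"patient": matrix.patients, "cohort": matrix.cohort.values})
        if matrix.outcome is not None:
            lab["outcome"] = matrix.outcome.values
        lab.to_csv(labels_path, sep="\t", index=False)
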