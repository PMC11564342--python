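"""End-to-end orchestration: simulate/load -> filter -> rescue -> burden ->
evolution -> cohort comparisons -> classifier.

Each stage writes its report into the output directory even when a
downstream stage fails; a failed stage is recorded in the run log and its
dependents are skipped. Runs are deterministic given the same inputs and
seed, and the fully-resolved configuration is serialised alongside the
outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
import traceback
from pathlib import Path

import pandas as pd
import yaml

from . import (
    classifier,
    cohort_stats,
    evolution,
    genomic_burden,
    plasma_rescue,
    synthetic_data,
    variant_filter,
    variant_io,
)


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate is False)
    calls_maf: str | None = None
    counts_tsv: str | None = None
    segments_seg: str | None = None
    matrix_tsv: str | None = None
    labels_tsv: str | None = None
    pathways_yaml: str | None = None
    # analysis parameters (study defaults)
    panel_size_mb: float = genomic_burden.PANEL_SIZE_MB
    tmb_numerator: str = "nonsynonymous"
    cohort_a: str = "CRA"
    cohort_b: str = "CRC-I"
    n_trees: int = 1000
    target_gii: float = 0.146
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def load_pathways(path: str | Path | None = None) -> dict[str, list[str]]:
    """Pathway gene sets; the packaged ten-pathway config by default."""
    if path is None:
        ref = importlib.resources.files("adenomaevo.data") / "pathways.yaml"
        with ref.open() as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Execute all stages; returns per-stage status ('ok', 'skipped', 'failed')."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger = logging.getLogger("adenomaevo.pipeline")
    logger.setLevel(cfg.log_level)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh)

    status: dict[str, str] = {}
    state: dict[str, object] = {}

    stages = [
        ("simulate", _stage_simulate, []),
        ("filter", _stage_filter, ["calls"]),
        ("rescue", _stage_rescue, ["kept", "counts"]),
        ("burden", _stage_burden, ["kept", "segments"]),
        ("evolution", _stage_evolution, ["kept"]),
        ("cohort", _stage_cohort, ["matrix"]),
        ("classify", _stage_classify, ["matrix"]),
    ]
    for name, fn, needs in stages:
        if name == "simulate" and not cfg.simulate:
            try:
                _load_inputs(cfg, state)
                status["simulate"] = "loaded"
            except Exception as exc:
                logger.error("loading inputs failed: %s", exc)
                status["simulate"] = "failed"
            continue
        if any(key not in state for key in needs):
            missing = [key for key in needs if key not in state]
            logger.warning("stage %s skipped; missing %s", name, missing)
            status[name] = "skipped"
            continue
        try:
            fn(cfg, state, out, logger)
            status[name] = "ok"
            logger.info("stage %s ok", name)
        except Exception:
            logger.error("stage %s failed:\n%s", name, traceback.format_exc())
            status[name] = "failed"

    with open(out / "status.json", "w") as fh:
        json.dump(status, fh, indent=2)
    logger.removeHandler(handler)
    handler.close()
    return status


def _load_inputs(cfg: RunConfig, state: dict) -> None:
    if cfg.calls_maf:
        state["calls"] = variant_io.read_calls(cfg.calls_maf, format="maf")
    if cfg.counts_tsv:
        state["counts"] = read_counts_tsv(cfg.counts_tsv)
    if cfg.segments_seg:
        state["segments"] = variant_io.read_segments(cfg.segments_seg)
    if cfg.matrix_tsv:
        state["matrix"] = variant_io.read_gene_matrix(cfg.matrix_tsv, cfg.labels_tsv)


def _stage_simulate(cfg: RunConfig, state: dict, out: Path, logger) -> None:
    sim = synthetic_data.SimConfig(seed=cfg.seed)
    matrix, truth = synthetic_data.simulate_cohort(sim)
    calls, artifacts = synthetic_data.simulate_multicaller_calls(truth, sim)
    counts = synthetic_data.simulate_plasma_counts(truth, sim)
    segments = synthetic_data.simulate_segments(cfg.target_gii)

    variant_io.write_maf(calls, out / "calls.maf")
    variant_io.write_segments(segments, out / "segments.seg")
    variant_io.write_gene_matrix(matrix, out / "matrix.tsv", out / "labels.tsv")
    write_counts_tsv(counts, out / "counts.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "informative_genes": truth.informative_genes,
                "risk_genes": truth.risk_genes,
                "n_artifacts": len(artifacts),
                "shed": {p: [str(k) for k in keys] for p, keys in truth.shed.items() if keys},
            },
            fh,
            indent=2,
        )
    state.update(
        calls=calls, counts=counts, segments=segments, matrix=matrix, truth=truth
    )
    logger.info(
        "simulated %d patients, %d calls, %d segments",
        len(matrix.patients), len(calls), len(segments),
    )


def _stage_filter(cfg: RunConfig, state: dict, out: Path, logger) -> None:
    kept, report = variant_filter.filter_calls(state["calls"], mode="tissue")
    variant_io.write_maf(kept, out / "kept.maf")
    pd.DataFrame(variant_filter.report_to_rows(report)).to_csv(
        out / "filter_report.tsv", sep="\t", index=False
    )
    state["kept"] = kept
    logger.info(
        "filter: %d -> %d variants; removals per rule %s",
        report.n_input, report.n_kept, dict(report.counts_per_rule),
    )


def _stage_rescue(cfg: RunConfig, state: dict, out: Path, logger) -> None:
    kept = state["kept"]
    counts = state["counts"]
    by_patient: dict[str, list] = {}
    for call in kept:
        by_patient.setdefault(call.patient_id, []).append(call)
    results = {}
    for patient, variants in sorted(by_patient.items()):
        patient_counts = counts.get(patient, [])
        results[patient] = plasma_rescue.rescue(variants, patient_counts)
    summary = plasma_rescue.cohort_detection_summary(results, n_patients=len(by_patient))
    rows = []
    for patient, res in results.items():
        for r in res:
            rows.append(
                {
                    "patient_id": patient,
                    "variant": str(r.variant),
                    "gene": r.gene,
                    "cf_vaf": r.cf_vaf,
                    "ctrl_vaf": r.ctrl_vaf,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "detected": r.detected,
                    "failed_rules": ",".join(r.failed_rules),
                }
            )
    pd.DataFrame(rows).to_csv(out / "rescue.tsv", sep="\t", index=False)
    with open(out / "rescue_summary.json", "w") as fh:
        json.dump(
            {
                "detection_rate": summary.detection_rate,
                "n_patients_positive": summary.n_patients_positive,
                "n_mutations": summary.n_mutations,
                "vaf_range": summary.vaf_range,
            },
            fh,
            indent=2,
        )
    logger.info(
        "rescue: %d/%d patients positive (%.1f%%), %d mutations",
        summary.n_patients_positive, summary.n_patients,
        100 * summary.detection_rate, summary.n_mutations,
    )


def _stage_burden(cfg: RunConfig, state: dict, out: Path, logger) -> None:
    kept = state["kept"]
    by_patient: dict[str, list] = {}
    for call in kept:
        by_patient.setdefault(call.patient_id, []).append(call)
    gii = genomic_burden.compute_gii(state["segments"])
    rows = [
        {
            "patient_id": patient,
            "tmb": genomic_burden.compute_tmb(
                variants, cfg.panel_size_mb, cfg.tmb_numerator
            ),
            "gii": gii,
        }
        for patient, variants in sorted(by_patient.items())
    ]
    pd.DataFrame(rows).to_csv(out / "burden.tsv", sep="\t", index=False)
    logger.info("burden: median TMB %.2f, GII %.3f",
                pd.DataFrame(rows)["tmb"].median(), gii)


def _stage_evolution(cfg: RunConfig, state: dict, out: Path, logger) -> None:
    kept = state["kept"]
    by_patient: dict[str, list] = {}
    for call in kept:
        by_patient.setdefault(call.patient_id, []).append(call)
    rows = []
    for patient, variants in sorted(by_patient.items()):
        spectrum = evolution.VAFSpectrum(
            sample_id=patient, vafs=[v.vaf for v in variants if v.vaf > 0]
        )
        clonal, subclonal = evolution.split_clonality(spectrum)
        res = evolution.neutrality_test(spectrum)
        rows.append(
            {
                "patient_id": patient,
                "n_clonal": clonal.size,
                "n_subclonal": subclonal.size,
                "r_squared": res.r_squared,
                "mu_per_beta": res.mu_per_beta,
                "evaluable": res.evaluable,
                "is_neutral": res.is_neutral,
            }
        )
    pd.DataFrame(rows).to_csv(out / "evo.tsv", sep="\t", index=False)
    logger.info("evolution: %d samples, %d evaluable",
                len(rows), sum(r["evaluable"] for r in rows))


def _stage_cohort(cfg: RunConfig, state: dict, out: Path, logger) -> None:
    matrix = state["matrix"]
    comps = cohort_stats.compare_frequencies(
        matrix, cfg.cohort_a, cfg.cohort_b, adjust="BH"
    )
    pd.DataFrame([dataclasses.asdict(c) for c in comps]).to_csv(
        out / "cohort_genes.tsv", sep="\t", index=False
    )
    pathways = load_pathways(cfg.pathways_yaml)
    path_comps = cohort_stats.pathway_alteration(
        matrix, pathways, cfg.cohort_a, cfg.cohort_b
    )
    pd.DataFrame([dataclasses.asdict(c) for c in path_comps]).to_csv(
        out / "cohort_pathways.tsv", sep="\t", index=False
    )
    if matrix.outcome is not None and matrix.outcome.notna().any():
        inputs = cohort_stats.persistence_inputs_from_matrix(matrix)
        persistence = cohort_stats.persistence_risk(inputs)
        pd.DataFrame([dataclasses.asdict(p) for p in persistence]).to_csv(
            out / "cohort_persistence.tsv", sep="\t", index=False
        )
    logger.info("cohort: %d genes compared", len(comps))


def _stage_classify(cfg: RunConfig, state: dict, out: Path, logger) -> None:
    matrix = state["matrix"]
    labels = matrix.cohort.map(lambda c: "CRA" if c == "CRA" else "CRC")
    model = classifier.fit_forest(matrix, labels, seed=cfg.seed, n_trees=cfg.n_trees)
    selected = classifier.minimal_depth_select(model)
    if selected:
        reduced = classifier.reduced_model(
            matrix, labels, selected, seed=cfg.seed, n_trees=cfg.n_trees
        )
        report = classifier.evaluate(reduced, matrix, labels)
    else:
        report = classifier.evaluate(model, matrix, labels)
    with open(out / "classify.json", "w") as fh:
        json.dump(
            {
                "selected_genes": selected,
                "auc": report.auc,
                "aucpr": report.aucpr,
                "oob_error": report.oob_error,
                "n_trees": cfg.n_trees,
                "seed": cfg.seed,
            },
            fh,
            indent=2,
        )
    logger.info(
        "classify: %d genes selected, AUC %.3f, OOB error %.3f",
        len(selected), report.auc, report.oob_error,
    )


# --------------------------------------------------------------------------
# Pileup-count TSV helpers (variant key + 4 counts)


def write_counts_tsv(counts: dict[str, list], path: str | Path) -> None:
    rows = []
    for patient, sites in sorted(counts.items()):
        for s in sites:
            rows.append(
                {
                    "patient_id": patient,
                    "chrom": s.variant.chrom,
                    "pos": s.variant.pos,
                    "ref": s.variant.ref,
                    "alt": s.variant.alt,
                    "cf_alt": s.cf_alt,
                    "cf_ref": s.cf_ref,
                    "ctrl_alt": s.ctrl_alt,
                    "ctrl_ref": s.ctrl_ref,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> dict[str, list]:
    from .variant_io import VariantKey

    df = pd.read_csv(path, sep="\t")
    counts: dict[str, list] = {}
    for r in df.itertuples(index=False):
        counts.setdefault(str(r.patient_id), []).append(
            plasma_rescue.SiteCounts(
                variant=VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt)),
                cf_alt=int(r.cf_alt),
                cf_ref=int(r.cf_ref),
                ctrl_alt=int(r.ctrl_alt),
                ctrl_ref=int(r.ctrl_ref),
            )
        )
    return counts
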