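"""Consensus and quality filtering against rule-forcing cases and
independent brute-force oracles."""

import numpy as np
import pytest

from adenomaevo import variant_filter
from adenomaevo.variant_filter import FilterConfig, consensus_merge, quality_filters
from adenomaevo.synthetic_data import SimConfig, simulate_cohort, simulate_multicaller_calls

from conftest import make_call


class TestConsensusTissue:
    def test_two_callers_kept_one_removed(self):
        calls = [
            make_call(pos=100, caller="varscan2"),
            make_call(pos=100, caller="strelka"),
            make_call(pos=300, caller="strelka"),
        ]
        kept, report = consensus_merge(calls, mode="tissue")
        assert {c.pos for c in kept} == {100}
        assert report.counts_per_rule["caller_consensus"] == 1

    def test_merged_record_uses_deepest_caller(self):
        calls = [
            make_call(pos=100, caller="varscan2", depth=800, alt_reads=240),
            make_call(pos=100, caller="strelka", depth=1200, alt_reads=400),
        ]
        kept, _ = consensus_merge(calls, mode="tissue")
        assert kept[0].depth == 1200


class TestConsensusPlasma:
    def test_single_caller_vaf_boundary(self):
        high = make_call(pos=100, caller="gvc", sample_type="plasma", vaf=0.06)
        low = make_call(pos=300, caller="gvc", sample_type="plasma", vaf=0.04)
        normals = {high.key: 0.0, low.key: 0.0}
        kept, report = consensus_merge([high, low], mode="plasma", normal_vafs=normals)
        assert {c.pos for c in kept} == {100}
        assert report.counts_per_rule["single_caller_low_vaf"] == 1

    def test_nonzero_normal_vaf_removed(self):
        call = make_call(pos=100, caller="varscan2", sample_type="plasma", vaf=0.2)
        other = make_call(pos=100, caller="strelka", sample_type="plasma", vaf=0.2)
        kept, report = consensus_merge(
            [call, other], mode="plasma", normal_vafs={call.key: 0.01}
        )
        assert not kept
        assert report.counts_per_rule["normal_vaf_nonzero"] == 1

    def test_missing_normal_vafs_error(self):
        call = make_call(sample_type="plasma")
        with pytest.raises(ValueError, match="matched-normal"):
            consensus_merge([call], mode="plasma")


class TestQualityFilters:
    def test_population_af_rule(self):
        call = make_call(pos=100, pop_af_1kg=0.02)
        kept, report = quality_filters([call])
        assert not kept
        assert "population_af" in next(iter(report.removed.values()))

    def test_proximity_boundary(self):
        # 99 bp apart: both removed; exactly 100 bp: both kept
        near = [make_call(pos=1000), make_call(pos=1099, ref="G", alt="C")]
        kept, _ = quality_filters(near)
        assert not kept
        far = [make_call(pos=1000), make_call(pos=1100, ref="G", alt="C")]
        kept, _ = quality_filters(far)
        assert len(kept) == 2

    def test_proximity_cluster_fully_removed(self):
        cluster = [make_call(pos=p, ref="G", alt="C") for p in (1000, 1050, 1099)]
        kept, report = quality_filters(cluster)
        assert not kept
        assert report.counts_per_rule["proximity"] == 3

    def test_missing_mappability_passes(self):
        kept, _ = quality_filters([make_call(mappability=None)])
        assert len(kept) == 1

    def test_random_fixture_matches_pairwise_oracle(self, rng):
        calls = []
        for i in range(120):
            calls.append(
                make_call(
                    patient=f"P{rng.integers(3)}",
                    chrom=f"chr{rng.integers(1, 4)}",
                    pos=int(rng.integers(1, 5000)),
                    ref="A",
                    alt="T",
                    pop_af_1kg=float(rng.choice([0.0, 0.005, 0.05])),
                    mappability=float(rng.choice([0.5, 0.8, 1.0])),
                )
            )
        # dedupe identical keys (grouping identity)
        seen = {}
        for c in calls:
            seen[(c.patient_id, c.sample_type, c.chrom, c.pos)] = c
        calls = list(seen.values())
        kept, _ = quality_filters(calls)

        def oracle(calls):
            out = []
            for c in calls:
                if max(c.pop_af_1kg or 0, c.pop_af_exac or 0) > 0.01:
                    continue
                if c.mappability is not None and c.mappability < 0.75:
                    continue
                clustered = any(
                    o is not c
                    and o.patient_id == c.patient_id
                    and o.sample_type == c.sample_type
                    and o.chrom == c.chrom
                    and abs(o.pos - c.pos) < 100
                    for o in calls
                )
                if not clustered:
                    out.append(c)
            return out

        assert {c.key for c in kept} == {c.key for c in oracle(calls)}


class TestConsensusOracle:
    def test_200_call_fixture_matches_brute_force(self, rng):
        cfg = FilterConfig()
        calls = []
        for i in range(200):
            calls.append(
                make_call(
                    patient=f"P{rng.integers(4)}",
                    pos=int(rng.integers(1, 40)) * 1000,
                    caller=str(rng.choice(["varscan2", "strelka", "gvc"])),
                    vaf=float(rng.uniform(0.01, 0.5)),
                )
            )
        kept, _ = consensus_merge(calls, mode="tissue", cfg=cfg)

        groups = {}
        for c in calls:
            groups.setdefault(
                (c.patient_id, c.sample_type, c.chrom, c.pos, c.ref, c.alt), set()
            ).add(c.caller)
        expected = {k for k, callers in groups.items() if len(callers) >= 2}
        got = {
            (c.patient_id, c.sample_type, c.chrom, c.pos, c.ref, c.alt) for c in kept
        }
        assert got == expected


class TestProperties:
    def test_annotation_filters_commute_with_consensus(self, rng):
        # population AF / mappability are site-level annotations, so they are
        # drawn per site (consistent across callers), not per record
        calls = []
        for i in range(150):
            pos = int(rng.integers(1, 50)) * 1000
            calls.append(
                make_call(
                    patient=f"P{rng.integers(3)}",
                    pos=pos,
                    caller=str(rng.choice(["varscan2", "strelka", "gvc"])),
                    pop_af_1kg=0.05 if pos % 7000 == 0 else 0.0,
                    mappability=0.5 if pos % 5000 == 0 else 0.9,
                )
            )
        cfg = FilterConfig(min_pair_distance=0)  # isolate annotation rules
        after, _ = quality_filters(consensus_merge(calls, "tissue", cfg)[0], cfg)
        pre, _ = quality_filters(calls, cfg)
        before, _ = consensus_merge(pre, "tissue", cfg)
        assert {c.key for c in after} == {c.key for c in before}

    def test_relaxing_thresholds_never_shrinks_kept_set(self, rng):
        calls = []
        for i in range(150):
            calls.append(
                make_call(
                    patient=f"P{rng.integers(3)}",
                    pos=int(rng.integers(1, 3000)),
                    ref="A",
                    alt="T",
                    caller=str(rng.choice(["varscan2", "strelka", "gvc"])),
                    pop_af_1kg=float(rng.choice([0.0, 0.005, 0.05])),
                    mappability=float(rng.uniform(0.4, 1.0)),
                )
            )
        seen = {}
        for c in calls:
            seen[(c.patient_id, c.chrom, c.pos, c.caller)] = c
        calls = list(seen.values())
        strict = FilterConfig()
        relaxed = FilterConfig(
            max_pop_af=0.1, min_mappability=0.3, min_pair_distance=10,
            min_callers_tissue=1,
        )
        kept_strict, _ = variant_filter.filter_calls(calls, "tissue", strict)
        kept_relaxed, _ = variant_filter.filter_calls(calls, "tissue", relaxed)
        assert {c.key for c in kept_strict} <= {c.key for c in kept_relaxed}


class TestMulticallerFixture:
    def test_filter_recovers_planted_truth_exactly(self):
        sim = SimConfig(seed=11)
        _, truth = simulate_cohort(sim)
        calls, artifact_keys = simulate_multicaller_calls(truth, sim)
        kept, _ = variant_filter.filter_calls(calls, mode="tissue")
        kept_keys = {
            (c.patient_id, c.sample_type, c.chrom, c.pos, c.ref, c.alt) for c in kept
        }
        truth_keys = {
            (c.patient_id, c.sample_type, c.chrom, c.pos, c.ref, c.alt)
            for muts in truth.variants.values()
            for c in muts
        }
        assert kept_keys == truth_keys
        assert not kept_keys & artifact_keys

    def test_planted_snp_contaminant_removed_by_population_rule(self):
        sim = SimConfig(seed=12)
        _, truth = simulate_cohort(sim)
        calls, artifact_keys = simulate_multicaller_calls(truth, sim)
        _, report = variant_filter.filter_calls(calls, mode="tissue")
        removed_by_pop = {
            key[:6] for key, rules in report.removed.items() if "population_af" in rules
        }
        assert removed_by_pop
        assert removed_by_pop <= artifact_keys
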