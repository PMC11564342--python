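"""Tumor-informed rescue: exact-test oracle, BH adjustment, detection rules
and cohort summary."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adenomaevo import plasma_rescue as pr
from adenomaevo.plasma_rescue import RescueConfig, SiteCounts
from adenomaevo.synthetic_data import SimConfig, simulate_cohort, simulate_plasma_counts
from adenomaevo.variant_io import VariantKey

from conftest import make_call


def hypergeom_tail_oracle(a, b, c, d):
    """One-sided enrichment p by direct enumeration of the hypergeometric
    support with fixed margins, summing tables at least as alt-rich in cfDNA."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for x in range(a, hi + 1):
        total += (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )
    return min(1.0, total)


class TestFisherSiteTest:
    def test_matches_enumeration_oracle_small_margins(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if a + b == 0 or (a + c == 0):
                            continue
                        site = SiteCounts(
                            VariantKey("chr1", 1, "A", "T"), a, b, c, d
                        )
                        assert pr.fisher_site_test(site) == pytest.approx(
                            hypergeom_tail_oracle(a, b, c, d), rel=1e-9
                        )

    def test_typical_rescue_table(self):
        site = SiteCounts(VariantKey("chr1", 1, "A", "T"), 5, 995, 0, 2000)
        assert pr.fisher_site_test(site) == pytest.approx(
            hypergeom_tail_oracle(5, 995, 0, 2000), rel=1e-9
        )

    def test_no_enrichment_gives_p_one(self):
        site = SiteCounts(VariantKey("chr1", 1, "A", "T"), 0, 1000, 0, 2000)
        assert pr.fisher_site_test(site) == 1.0

    def test_all_zero_table_warns_p_one(self):
        site = SiteCounts(VariantKey("chr1", 1, "A", "T"), 0, 0, 0, 0)
        with pytest.warns(UserWarning):
            assert pr.fisher_site_test(site) == 1.0


class TestBHAdjust:
    def test_single_test_unchanged(self):
        assert pr.bh_adjust([0.01]) == pytest.approx([0.01])

    def test_step_up_hand_computed(self):
        # p*(n/rank) = [.04, .04, .04, .04] after the step-up minimum scan
        assert pr.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_empty(self):
        assert len(pr.bh_adjust([])) == 0

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance_and_dominance(self, ps, rnd):
        qs = pr.bh_adjust(ps)
        assert (qs >= np.asarray(ps) - 1e-12).all()
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        qs_perm = pr.bh_adjust([ps[i] for i in perm])
        for orig_idx, new_pos in enumerate(perm):
            assert qs_perm[orig_idx] == pytest.approx(qs[new_pos])


class TestRescueRules:
    def _run(self, cf_alt, cf_ref, ctrl_alt=0, ctrl_ref=2000):
        var = make_call(pos=100)
        site = SiteCounts(var.key, cf_alt, cf_ref, ctrl_alt, ctrl_ref)
        return pr.rescue([var], [site])[0]

    def test_min_alt_reads_rule(self):
        res = self._run(3, 997)
        assert not res.detected
        assert res.failed_rules == ["min_alt_reads"]

    def test_vaf_ratio_rule(self):
        # cf VAF 0.015 < 2 x ctrl VAF 0.009 regardless of p
        res = self._run(15, 985, ctrl_alt=18, ctrl_ref=1982)
        assert not res.detected
        assert "vaf_ratio" in res.failed_rules

    def test_clean_site_detected(self):
        res = self._run(20, 1480)
        assert res.detected and not res.failed_rules

    def test_untested_variant_reported_not_undetected(self):
        var = make_call(pos=100)
        results = pr.rescue([var], [])
        assert not results[0].tested
        assert results[0].failed_rules == ["untested"]

    def test_detection_monotone_in_alt_reads(self):
        detected = [self._run(k, 1500 - k).detected for k in range(0, 30)]
        # once detected, more alt reads never undoes it
        assert detected == sorted(detected)

    def test_zero_control_alt_reduces_to_q_rule(self):
        # with ctrl_alt = 0 and cf_alt >= 4 the 2x rule cannot fail
        for k in (4, 6, 10):
            res = self._run(k, 1500 - k)
            assert "vaf_ratio" not in res.failed_rules


class TestCohortSummary:
    def test_reconstructed_detection_table(self):
        # seven detected mutations across five of 85 patients; the KRAS
        # p.G12V hotspot appears in two patients
        detections = {
            "P5": [("APC", "frameshift", "p.G1394fs", 0.0094),
                   ("KRAS", "missense", "p.G12V", 0.0157)],
            "P6": [("KIF1B", "intron", None, 0.0297),
                   ("BAP1", "intron", None, 0.0241)],
            "P7": [("CCDC170", "intron", None, 0.0938)],
            "P8": [("KRAS", "missense", "p.G12V", 0.0092)],
            "P9": [("NOVA1", "intron", None, 0.0287)],
        }
        results = {}
        for patient, muts in detections.items():
            rs = []
            for i, (gene, vc, pc, vaf) in enumerate(muts):
                var = make_call(pos=100 + 200 * i, patient=patient, gene=gene,
                                variant_class="other" if vc == "intron" else vc)
                depth = 1500
                alt = round(vaf * depth)
                site = SiteCounts(var.key, alt, depth - alt, 0, 2000)
                res = pr.rescue([var], [site])
                res[0].protein_change = pc
                res[0].variant_class = vc
                rs.extend(res)
            results[patient] = rs
        summary = pr.cohort_detection_summary(results, n_patients=85)
        assert summary.n_mutations == 7
        assert summary.n_patients_positive == 5
        assert round(100 * summary.detection_rate, 1) == 5.9
        kras = [r for r in summary.mutation_table if r["protein_change"] == "p.G12V"]
        assert len(kras) == 2
        assert round(100 * kras[0]["cohort_frequency"], 1) == 2.4

    def test_no_detections_rate_zero(self):
        assert pr.cohort_detection_summary({"P1": []}, 10).detection_rate == 0

    def test_all_patients_positive_rate_one(self):
        var = make_call()
        site = SiteCounts(var.key, 30, 1470, 0, 2000)
        results = {f"P{i}": pr.rescue([var], [site]) for i in range(4)}
        assert pr.cohort_detection_summary(results, 4).detection_rate == 1.0

    def test_zero_patients_error(self):
        with pytest.raises(ValueError):
            pr.cohort_detection_summary({}, 0)


class TestSimulationPower:
    def test_shed_variants_detected_with_high_sensitivity(self, rng):
        """10 shed (VAF in 1-3%) + 10 unshed variants at 1500x/2000x:
        >= 95% of shed sites detected across 200 replicates."""
        hits = trials = 0
        fps = 0
        for _ in range(200):
            variants, sites, shed = [], [], set()
            for i in range(20):
                var = make_call(pos=1000 * (i + 1))
                variants.append(var)
                if i < 10:
                    vaf = rng.uniform(0.01, 0.03)
                    shed.add(var.key)
                else:
                    vaf = 1e-4
                depth = int(rng.poisson(1500))
                alt = int(rng.binomial(depth, vaf))
                sites.append(SiteCounts(var.key, alt, depth - alt, 0, 2000))
            for res in pr.rescue(variants, sites):
                if res.variant in shed:
                    trials += 1
                    hits += res.detected
                else:
                    fps += res.detected
        assert hits / trials >= 0.95
        assert fps / (200 * 10) <= 0.01

    def test_no_shedding_high_specificity(self):
        """Specificity >= 0.99 over 100 simulated patients with zero shedding."""
        sim = SimConfig(seed=3, shed_patient_fraction=0.0)
        _, truth = simulate_cohort(sim)
        counts = simulate_plasma_counts(truth, sim)
        n_sites = n_detected = 0
        for patient, muts in truth.variants.items():
            for res in pr.rescue(muts, counts[patient]):
                n_sites += 1
                n_detected += res.detected
        assert n_sites > 500
        assert 1 - n_detected / n_sites >= 0.99
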