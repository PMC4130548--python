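"""aCGH genotyping: summarization, validation, QC metrics, integer and
continuous copy-number fitting, read-depth method gating."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from foundercnv import cgh, simulate as S


def probes_frame(log2s, sample="s1", locus="L1", test=None, ref=None):
    n = len(log2s)
    return pd.DataFrame(
        {
            "sample": [sample] * n,
            "locus_id": [locus] * n,
            "chrom": ["chr1"] * n,
            "probe_start": np.arange(n) * 100,
            "log2_ratio": log2s,
            "test_intensity": test if test is not None else [1000.0] * n,
            "ref_intensity": ref if ref is not None else [1000.0] * n,
        }
    )


def mk_summary(sample, log2, test=1000.0, ref=1000.0, locus="L1"):
    return cgh.LocusSummary(sample, locus, log2, test, ref)


def summaries_for_cn(cn_by_sample, reference_cn=2, locus="L1", scale=1000.0):
    """Noise-free summaries consistent across both channels."""
    out = []
    for sid, cn in cn_by_sample.items():
        cn_eff = max(cn, S.CN_ZERO_FLOOR)
        out.append(
            mk_summary(
                sid,
                math.log2(cn_eff / reference_cn),
                test=scale * cn_eff / 2,
                ref=scale * reference_cn / 2,
                locus=locus,
            )
        )
    return out


class TestSummarizeLocus:
    def test_odd_count_median(self):
        s = cgh.summarize_locus(probes_frame([-0.9, -1.1, -1.0]))
        assert s.median_log2 == -1.0

    def test_even_count_median_is_mean_of_central_pair(self):
        s = cgh.summarize_locus(probes_frame([0.2, 0.4]))
        assert s.median_log2 == pytest.approx(0.3)

    def test_noise_free_deletion_is_exact(self):
        truth = S.SimulatedCnvTruth(
            pd.DataFrame([{"locus_id": "L1", "chrom": "chr1", "start": 0,
                           "end": 1000, "allele_type": "deletion", "founder_freq": 0}]),
            pd.DataFrame({"L1": [1]}, index=["s1"]),
        )
        probes = S.simulate_acgh_probes(truth, 10, 0.0, seed=0)
        assert cgh.summarize_locus(probes).median_log2 == -1.0

    def test_empty_probe_set_is_an_error(self):
        with pytest.raises(ValueError):
            cgh.summarize_locus(probes_frame([]))


class TestCallValidation:
    @pytest.mark.parametrize(
        "median,expected",
        [(-1.0, True), (0.0, False), (0.5, False), (0.500001, True), (-0.6, True)],
    )
    def test_strict_threshold(self, median, expected):
        assert cgh.call_validation(mk_summary("s", median)) is expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, 3), st.floats(0, 1))
    def test_monotone_in_absolute_median(self, a, b):
        lo, hi = sorted([a, a + b])
        s_lo, s_hi = mk_summary("s", lo), mk_summary("s", hi)
        if cgh.call_validation(s_lo):
            assert cgh.call_validation(s_hi)


class TestComputeDlr:
    def test_constant_sequence_is_zero(self):
        assert cgh.compute_dlr([0.3] * 10) == 0.0

    def test_hand_computed_alternating_sequence(self):
        a = 0.2
        seq = [a, -a, a, -a, a, -a]
        diffs = [seq[i + 1] - seq[i] for i in range(5)]
        expected = statistics.stdev(diffs) / math.sqrt(2)
        assert cgh.compute_dlr(seq) == pytest.approx(expected)

    def test_estimates_white_noise_sd(self):
        rng = np.random.default_rng(0)
        sigma = 0.21
        x = rng.normal(0, sigma, 10_000)
        assert cgh.compute_dlr(x) == pytest.approx(sigma, rel=0.05)

    def test_needs_two_probes(self):
        with pytest.raises(ValueError):
            cgh.compute_dlr([0.1])


class TestSexConcordance:
    def test_male_vs_female_reference(self):
        inferred, ok = cgh.check_sex_concordance(
            [mk_summary("s", -1.0, locus="X1")], "male", "female"
        )
        assert inferred == "male" and ok is True

    def test_female_vs_female_reference(self):
        inferred, ok = cgh.check_sex_concordance(
            [mk_summary("s", 0.0, locus="X1")], "female", "female"
        )
        assert inferred == "female" and ok is True

    def test_no_x_loci_is_indeterminate(self):
        inferred, ok = cgh.check_sex_concordance([], "male", "female")
        assert inferred == "unknown" and ok is None

    def test_swapped_labels_are_flagged_exactly(self):
        # cohort with 5% sex-swapped reported labels: only those flag
        rng = np.random.default_rng(3)
        flagged, expected = [], []
        for k in range(100):
            true_sex = "male" if k % 2 == 0 else "female"
            swapped = k % 20 == 0
            reported = {"male": "female", "female": "male"}[true_sex] if swapped else true_sex
            log2 = math.log2((1 if true_sex == "male" else 2) / 2)
            sums = [
                mk_summary(f"s{k}", log2 + rng.normal(0, 0.05), locus=f"X{j}")
                for j in range(3)
            ]
            _, ok = cgh.check_sex_concordance(sums, reported, "female")
            if not ok:
                flagged.append(k)
            if swapped:
                expected.append(k)
        assert flagged == expected


class TestComputeRcv:
    def test_invariant_test_channel_not_flagged(self):
        sums = [mk_summary(f"s{i}", 0.0, test=500.0, ref=400.0 + 10 * i) for i in range(5)]
        res = cgh.compute_rcv(sums)
        assert res.rcv == 0.0 and not res.variant_and_well_performing

    def test_zero_reference_cv_is_review_sentinel(self):
        sums = [mk_summary(f"s{i}", 0.0, test=100.0 * (i + 1), ref=300.0) for i in range(4)]
        res = cgh.compute_rcv(sums)
        assert math.isinf(res.rcv) and res.needs_review
        assert not res.variant_and_well_performing

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        sums = [
            mk_summary(f"s{i}", 0.0, test=rng.uniform(200, 900), ref=rng.uniform(380, 420))
            for i in range(20)
        ]
        scaled = [
            mk_summary(s.sample_id, s.median_log2, s.median_test * 37.0, s.median_ref * 37.0)
            for s in sums
        ]
        assert cgh.compute_rcv(scaled).rcv == pytest.approx(cgh.compute_rcv(sums).rcv)

    def test_polymorphic_locus_has_larger_rcv(self):
        ped = S.simulate_pedigree(80, 1, seed=0)
        truth = S.simulate_cnv_truth(ped, 1, "deletion", 0.3, seed=2)
        invariant = S.SimulatedCnvTruth(truth.loci.copy(), truth.copy_number * 0 + 2)
        rcvs = []
        for t in (truth, invariant):
            probes = S.simulate_acgh_probes(t, 10, 0.15, seed=5)
            rcvs.append(cgh.compute_rcv(cgh.summarize_probe_table(probes)).rcv)
        assert rcvs[0] > rcvs[1]

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            cgh.compute_rcv([mk_summary("a", 0.0), mk_summary("b", 0.0)])


class TestFitIntegerCn:
    def test_clean_clusters_map_to_theoretical_states(self):
        sums = summaries_for_cn({"a": 1, "b": 2, "c": 3})
        for method in ("joint_fit", "log2_only"):
            calls = cgh.fit_integer_cn(sums, method)
            assert [c.cn for c in calls] == [1, 2, 3]

    def test_all_diploid(self):
        sums = summaries_for_cn({f"s{i}": 2 for i in range(6)})
        calls = cgh.fit_integer_cn(sums, "log2_only")
        assert all(c.cn == 2 for c in calls)

    def test_noise_free_recovery_across_full_state_range(self):
        sums = summaries_for_cn({f"s{c}": c for c in range(0, 9)})
        for method in ("joint_fit", "log2_only"):
            calls = cgh.fit_integer_cn(sums, method, max_cn=8)
            assert [c.cn for c in calls] == list(range(0, 9))

    def test_noisy_biallelic_deletion_recovery(self):
        ped = S.simulate_pedigree(200, 1, seed=1)
        truth = S.simulate_cnv_truth(ped, 1, "deletion", 0.3, seed=1)
        probes = S.simulate_acgh_probes(truth, 10, 0.1, seed=1)
        calls = cgh.fit_integer_cn(cgh.summarize_probe_table(probes), "joint_fit")
        truth_cn = truth.copy_number.iloc[:, 0]
        acc = np.mean([c.cn == truth_cn[c.sample_id] for c in calls])
        assert acc >= 0.99

    def test_compressed_response_is_unfittable(self):
        # dynamic-range compression scales the log2 response so cluster
        # spacings no longer match any integer-state grid: the locus is
        # reported unfittable (None), not forced onto wrong states
        gamma = 0.6
        values = [gamma * math.log2(c / 2) for c in (1, 2, 3, 4, 5) for _ in range(4)]
        sums = [mk_summary(f"s{i}", v, test=1000.0, ref=1000.0)
                for i, v in enumerate(values)]
        assert cgh.fit_integer_cn(sums, "log2_only") is None


class TestSelectCnMethod:
    def _calls(self, cns, method):
        return [cgh.CopyNumberCall(f"s{i}", "L1", float(c), method) for i, c in enumerate(cns)]

    def test_higher_correlation_wins(self):
        rd = {f"s{i}": float(v) for i, v in enumerate([1, 2, 2, 3, 2])}
        a = self._calls([1, 2, 2, 3, 2], "joint_fit")      # r = 1
        b = self._calls([2, 2, 1, 2, 3], "log2_only")      # poorly correlated
        sel = cgh.select_cn_method(a, b, rd)
        assert sel.chosen_method == "joint_fit" and not sel.rejected
        assert all(c.r == pytest.approx(1.0) for c in sel.calls)

    def test_low_best_correlation_rejects_locus(self):
        rd = {f"s{i}": v for i, v in enumerate([2.0, 1.8, 2.2, 2.4, 1.2, 3.0])}
        a = self._calls([2, 3, 1, 2, 3, 2], "joint_fit")
        b = self._calls([3, 2, 2, 1, 3, 2], "log2_only")
        sel = cgh.select_cn_method(a, b, rd)
        assert sel.rejected and "below" in sel.reason

    def test_zero_variance_is_rejected_with_reason(self):
        rd = {f"s{i}": 2.0 for i in range(5)}
        a = self._calls([1, 2, 2, 3, 2], "joint_fit")
        sel = cgh.select_cn_method(a, a, rd)
        assert sel.rejected and sel.reason == "correlation undefined"

    def test_tie_prefers_joint_fit(self):
        rd = {f"s{i}": float(v) for i, v in enumerate([1, 2, 3])}
        a = self._calls([1, 2, 3], "log2_only")
        b = self._calls([1, 2, 3], "joint_fit")
        assert cgh.select_cn_method(a, b, rd).chosen_method == "joint_fit"

    def test_log2_bias_misanchors_log2_only_and_joint_wins(self):
        # a constant hybridization offset of half a state spacing shifts
        # log2-only calls by +1; the intensity channel keeps joint_fit honest
        ped = S.simulate_pedigree(120, 1, seed=2)
        truth = S.simulate_cnv_truth(ped, 1, "duplication", 0.3, seed=2)
        probes = S.simulate_acgh_probes(truth, 10, 0.05, seed=2, log2_bias=0.5)
        sums = cgh.summarize_probe_table(probes)
        joint = cgh.fit_integer_cn(sums, "joint_fit")
        log2only = cgh.fit_integer_cn(sums, "log2_only", max_rms_residual=1.0)
        truth_cn = truth.copy_number.iloc[:, 0]
        joint_acc = np.mean([c.cn == truth_cn[c.sample_id] for c in joint])
        bias = np.mean([c.cn - truth_cn[c.sample_id] for c in log2only])
        assert joint_acc > 0.95
        assert bias > 0.5  # log2-only systematically mis-anchored upward
        sel = cgh.select_cn_method(joint, log2only, truth_cn.astype(float))
        assert sel.chosen_method == "joint_fit"


class TestEstimateContinuousCn:
    def test_reference_calibration(self):
        s = mk_summary("s", 0.0, test=800.0, ref=800.0)
        (call,) = cgh.estimate_continuous_cn([s], single_copy_intensity=400.0)
        assert call.cn == pytest.approx(2.0)
        assert call.method == "intensity_calibrated"

    def test_deletion_log2(self):
        s = mk_summary("s", -1.0, test=400.0, ref=800.0)
        (call,) = cgh.estimate_continuous_cn([s], single_copy_intensity=400.0)
        assert call.cn == pytest.approx(1.0)

    def test_multiallelic_recovery_within_half_copy(self):
        ped = S.simulate_pedigree(150, 1, seed=4)
        truth = S.simulate_cnv_truth(ped, 1, "multiallelic", seed=4)
        probes = S.simulate_acgh_probes(truth, 10, 0.05, seed=4, intensity_scale=1000.0)
        sums = cgh.summarize_probe_table(probes)
        calls = cgh.estimate_continuous_cn(sums, single_copy_intensity=500.0)
        truth_cn = truth.copy_number.iloc[:, 0]
        frac = np.mean([abs(c.cn - truth_cn[c.sample_id]) <= 0.5 for c in calls])
        assert frac >= 0.95
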