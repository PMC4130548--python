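"""Association statistics: allelic OR, kinship-corrected chi-square,
rank-sum copy-number test, CMH combination, frequency comparison, and the
covariate-adjusted set test."""

import math

import numpy as np
import pytest
from scipy import stats

from foundercnv import association as A
from foundercnv import simulate as S


class TestAllelicOr:
    def test_equal_frequencies_give_unity(self):
        for f in (0.015, 0.2, 0.9):
            assert A.allelic_or(f, f).odds_ratio == pytest.approx(1.0)

    def test_published_frequency_pair(self):
        assert A.allelic_or(0.019, 0.015).odds_ratio == pytest.approx(1.27, abs=0.005)

    def test_zero_control_frequency_is_infinite_sentinel(self):
        assert math.isinf(A.allelic_or(0.014, 0.0).odds_ratio)

    def test_counts_give_binomial_se(self):
        res = A.allelicor = A.allelic_or((11, 740), (11, 728))
        f = 11 / 740
        assert res.se_case == pytest.approx(math.sqrt(f * (1 - f) / 740))
        assert res.odds_ratio == pytest.approx(0.98, abs=0.005)

    def test_haldane_correction_is_finite(self):
        res = A.allelic_or((5, 354), (0, 438), haldane=True)
        assert math.isfinite(res.odds_ratio) and res.odds_ratio > 1

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            A.allelic_or(1.2, 0.5)


class TestCorrectedChisq:
    def test_reduces_to_classical_for_unrelateds(self):
        rng = np.random.default_rng(5)
        x = rng.binomial(2, 0.3, 150)
        y = rng.random(150) < 0.4
        res = A.corrected_chisq_test(x, y, kinship=0.5 * np.eye(150))
        a, c = x[y].sum(), x[~y].sum()
        table = np.array([[a, 2 * y.sum() - a], [c, 2 * (~y).sum() - c]])
        classical = stats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(classical.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(classical.pvalue, abs=1e-10)

    def test_equal_frequencies_give_zero_statistic(self):
        x = np.array([1, 1, 0, 2, 1, 1, 0, 2])
        y = np.array([True] * 4 + [False] * 4)
        res = A.corrected_chisq_test(x, y, kinship=0.5 * np.eye(8))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_inverts_odds_ratio(self):
        rng = np.random.default_rng(6)
        ped = S.simulate_pedigree(12, 3, 1.5, seed=6)
        kin = S.compute_kinship(ped)
        x = S.drop_biallelic_genotypes(ped, 0.3, seed=6).to_numpy()
        y = rng.random(len(ped)) < 0.4
        res = A.corrected_chisq_test(x, y, kin)
        swapped = A.corrected_chisq_test(x, ~y, kin)
        assert res.statistic == pytest.approx(swapped.statistic)
        assert res.odds_ratio == pytest.approx(1.0 / swapped.odds_ratio)

    def test_monomorphic_is_flagged(self):
        res = A.corrected_chisq_test(
            np.zeros(10, dtype=int), np.array([True] * 5 + [False] * 5),
            kinship=0.5 * np.eye(10),
        )
        assert res.extra["monomorphic"] and res.p_value == 1.0 and res.odds_ratio == 1.0

    def test_accepts_phenotype_labels(self):
        x = np.array([2, 1, 0, 0, 1, 0])
        labels = np.array(["asthma", "asthma", "control", "control", "unknown", "control"])
        res = A.corrected_chisq_test(x, labels, kinship=0.5 * np.eye(6))
        assert res.extra["n_case"] == 2 and res.extra["n_control"] == 3


class TestWilcoxonCnTest:
    def test_identical_multisets(self):
        assert A.wilcoxon_cn_test([2, 2, 3], [2, 2, 3]).p_value == 1.0

    def test_enumerated_worked_example(self):
        res = A.wilcoxon_cn_test([3, 3, 3], [2, 2, 2])
        assert res.p_value == pytest.approx(2 / 20)
        assert res.extra["method"] == "exact_enumeration"

    def test_large_shift_matches_permutation_oracle(self):
        rng = np.random.default_rng(2)
        case = 3.0 + rng.normal(0, 0.5, 40)
        ctrl = 2.0 + rng.normal(0, 0.5, 40)
        res = A.wilcoxon_cn_test(case, ctrl)
        assert res.p_value < 0.01

        def rank_sum(a, b):
            ranks = stats.rankdata(np.concatenate([a, b]))
            return ranks[: len(a)].sum()

        oracle = stats.permutation_test(
            (case, ctrl), rank_sum, permutation_type="independent",
            alternative="two-sided", n_resamples=100_000,
            rng=np.random.default_rng(0),
        )
        assert res.p_value == pytest.approx(float(oracle.pvalue), abs=2e-3)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            A.wilcoxon_cn_test([], [1.0])


class TestCmhCombined:
    def test_single_stratum_reduces_to_plain_chi2(self):
        t = np.array([[7, 371], [5, 339]], dtype=float)
        res = A.cmh_combined([t])
        plain = stats.chi2_contingency(t, correction=False)
        assert res.statistic == pytest.approx(plain.statistic)
        assert res.p_value == pytest.approx(plain.pvalue)
        assert res.odds_ratio == pytest.approx((7 * 339) / (371 * 5))

    def test_two_identical_strata_same_or_smaller_p(self):
        t = np.array([[20, 180], [10, 190]], dtype=float)
        one = A.cmh_combined([t])
        two = A.cmh_combined([t, t])
        assert two.odds_ratio == pytest.approx(one.odds_ratio)
        assert two.p_value < one.p_value

    def test_agrees_with_statsmodels_up_to_variance_convention(self):
        # statsmodels uses the N-1 hypergeometric variance; ours uses N so
        # a single stratum reduces exactly to Pearson.  The known factor
        # reconciles them.
        from statsmodels.stats.contingency_tables import StratifiedTable

        strata = S.simulate_strata(
            [(200, 180, 0.08, 0.05), (300, 250, 0.06, 0.05), (150, 150, 0.09, 0.04)],
            seed=3,
        )
        res = A.cmh_combined(strata)
        st = StratifiedTable([t.table.astype(int) for t in strata])
        assert res.odds_ratio == pytest.approx(st.oddsratio_pooled)
        ratio = res.statistic / float(st.test_null_odds(correction=False).statistic)
        assert 1.0 < ratio < 1.01

    def test_degenerate_strata_are_dropped_then_error(self):
        empty = np.array([[0, 0], [0, 0]], dtype=float)
        good = np.array([[5, 95], [2, 98]], dtype=float)
        res = A.cmh_combined([empty, good])
        assert res.extra["n_strata"] == 1
        with pytest.raises(A.DegenerateDataError):
            A.cmh_combined([empty])

    def test_one_sided_direction(self):
        t = np.array([[30, 170], [10, 190]], dtype=float)  # cases enriched
        two = A.cmh_combined([t], tail="two_sided")
        one = A.cmh_combined([t], tail="one_sided")
        assert one.p_value == pytest.approx(two.p_value / 2)

    def test_recovers_known_common_odds_ratio(self):
        # five cohorts at replication-study sizes sharing a true OR of 1.6
        sizes = [(177, 219), (370, 364), (189, 172), (755, 742), (1052, 747)]
        f_ctrl = 0.05
        odds_case = 1.6 * f_ctrl / (1 - f_ctrl)
        f_case = odds_case / (1 + odds_case)
        estimates = []
        for b in range(2000):
            strata = S.simulate_strata(
                [(n1, n2, f_case, f_ctrl) for n1, n2 in sizes], seed=b
            )
            estimates.append(A.cmh_combined(strata).odds_ratio)
        assert abs(np.median(estimates) - 1.6) < 0.16


class TestComparePopulationFrequencies:
    def test_identical_vectors(self):
        res = A.compare_population_frequencies([0.1, 0.4, 0.8], [0.1, 0.4, 0.8])
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["n_exceeding"] == 0

    def test_exceed_count_arithmetic(self):
        res = A.compare_population_frequencies(
            [0.1, 0.5, 0.3], [0.6, 0.0, 0.3], diff_threshold=0.4
        )
        assert res["n_exceeding"] == 2

    def test_zero_variance_is_an_error(self):
        with pytest.raises(A.DegenerateDataError):
            A.compare_population_frequencies([0.2, 0.2, 0.2], [0.1, 0.2, 0.3])

    def test_shared_true_frequencies_correlate(self):
        rng = np.random.default_rng(4)
        true = rng.uniform(0.05, 0.95, 200)
        fa = rng.binomial(1000, true) / 1000
        fb = rng.binomial(1000, true) / 1000
        res = A.compare_population_frequencies(fa, fb)
        assert res["r_squared"] > 0.9


class TestSetScoreTest:
    def test_no_qualifying_variants_is_untestable(self):
        res = A.set_score_test(np.empty((50, 0)), np.zeros(50))
        assert not res.extra["testable"]
        assert math.isnan(res.p_value)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(7)
        G = rng.binomial(2, 0.05, (300, 5)).astype(float)
        y = rng.binomial(1, 0.4, 300).astype(float)
        cov = rng.random((300, 2))
        a = A.set_score_test(G, y, covariates=cov, seed=1)
        b = A.set_score_test(G[:, ::-1], y, covariates=cov, seed=1)
        assert a.p_value == pytest.approx(b.p_value)
        for rho in a.extra["p_by_rho"]:
            assert a.extra["p_by_rho"][rho] == pytest.approx(b.extra["p_by_rho"][rho])

    def test_constant_covariate_column_is_harmless(self):
        rng = np.random.default_rng(8)
        G = rng.binomial(2, 0.05, (300, 4)).astype(float)
        y = rng.binomial(1, 0.4, 300).astype(float)
        cov = rng.random((300, 1))
        a = A.set_score_test(G, y, covariates=cov, seed=2)
        b = A.set_score_test(G, y, covariates=np.column_stack([cov, np.ones(300)]), seed=2)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-6)

    def test_missing_genotypes_are_imputed(self):
        rng = np.random.default_rng(9)
        G = rng.binomial(2, 0.1, (200, 3)).astype(float)
        G[rng.random(G.shape) < 0.05] = np.nan
        y = rng.binomial(1, 0.3, 200).astype(float)
        res = A.set_score_test(G, y, seed=3)
        assert 0.0 <= res.p_value <= 1.0

    def test_separation_is_an_error_state(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        cov = y[:, None].copy()  # covariate perfectly separates the outcome
        G = np.random.default_rng(0).binomial(2, 0.2, (40, 2)).astype(float)
        with pytest.raises(A.DegenerateDataError):
            A.set_score_test(G, y, covariates=cov)

    def test_bonferroni(self):
        assert A.bonferroni(0.004, 29, 2) == pytest.approx(0.232)
        assert A.bonferroni(0.5, 29, 2) == 1.0
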