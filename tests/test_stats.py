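"""Nonparametric tests, ERP contrasts, weight summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from cbci.stats import (
    grand_average,
    kruskal_wallis,
    pointwise_erp_tests,
    weight_density,
    weight_summaries,
    wilcoxon_signed_rank,
)


def kw_h_by_hand(groups):
    """Independent H computation straight from the textbook formula."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    return h / (1 - np.sum(counts**3 - counts) / (n**3 - n))


class TestKruskalWallis:
    def test_identical_samples_are_null(self):
        res = kruskal_wallis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_all_values_equal_gives_h0_p1(self):
        res = kruskal_wallis([2.0, 2.0], [2.0, 2.0, 2.0])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_separated_samples_match_permutation_enumeration(self):
        """Statistic and exact p equal a full rank-permutation oracle."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = kruskal_wallis(a, b, method="exact")
        assert res.statistic == pytest.approx(kw_h_by_hand([a, b]), abs=1e-9)
        # oracle: every C(6,3) split of the pooled sample
        pooled = np.array(a + b)
        h_obs = kw_h_by_hand([a, b])
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(combo)] = True
            h = kw_h_by_hand([pooled[mask], pooled[~mask]])
            total += 1
            hits += h >= h_obs - 1e-12
        assert res.p_value == pytest.approx(hits / total)
        # chi-square mode returns the usual asymptotic p
        assert 0 < kruskal_wallis(a, b).p_value < 0.06

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            g = rng.standard_normal((3, 8))
            rejections += kruskal_wallis(*g).p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_two_group_verdict_agrees_with_rank_sum(self):
        rng = np.random.default_rng(8)
        for shift in (0.0, 2.0):
            a = rng.standard_normal(12)
            b = rng.standard_normal(12) + shift
            kw_sig = kruskal_wallis(a, b).p_value < 0.05
            rs_sig = mannwhitneyu(a, b, alternative="two-sided").pvalue < 0.05
            assert kw_sig == rs_sig

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 0.5
        h1 = kruskal_wallis(a, b).statistic
        h2 = kruskal_wallis(np.exp(a), np.exp(b)).statistic
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0], [])


def enumerate_wilcoxon(diffs, alternative):
    """Brute-force 2^n oracle over all sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ge = le = total = 0
    for signs in itertools.product([1, -1], repeat=n):
        w = ranks[np.array(signs) > 0].sum()
        total += 1
        ge += w >= w_obs - 1e-12
        le += w <= w_obs + 1e-12
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge / total, le / total))


class TestWilcoxonExact:
    def test_three_positive_differences_one_tailed(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], tails="one", alternative="greater")
        assert res.p_value == pytest.approx(1 / 8)

    def test_symmetric_pair_two_tailed(self):
        res = wilcoxon_signed_rank([-1.0, 1.0], tails="two")
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_matches_full_enumeration_with_ties_and_zeros(self, alternative):
        rng = np.random.default_rng(20)
        for _ in range(5):
            diffs = rng.integers(-3, 4, size=10).astype(float)  # many ties, some zeros
            if np.all(diffs == 0):
                continue
            res = wilcoxon_signed_rank(diffs, tails="one", alternative=alternative)
            assert res.p_value == pytest.approx(enumerate_wilcoxon(diffs, alternative))

    def test_two_tailed_matches_enumeration_at_n12(self):
        rng = np.random.default_rng(21)
        diffs = rng.integers(-5, 6, size=12).astype(float)
        res = wilcoxon_signed_rank(diffs, tails="two")
        assert res.p_value == pytest.approx(enumerate_wilcoxon(diffs, "two"))

    def test_invariance_under_monotone_transform_of_magnitudes(self):
        rng = np.random.default_rng(22)
        d = rng.standard_normal(9)
        f = lambda x: np.sign(x) * np.expm1(np.abs(x))  # odd, strictly monotone
        p1 = wilcoxon_signed_rank(d, tails="two").p_value
        p2 = wilcoxon_signed_rank(f(d), tails="two").p_value
        assert p1 == pytest.approx(p2)


class TestGrandAverage:
    def test_identical_epochs_reproduce_the_epoch(self):
        epoch = np.arange(24.0).reshape(1, 24) * np.ones((4, 1))
        epochs = np.stack([epoch] * 6)
        ga = grand_average(epochs, ["a", "a", "a", "b", "b", "b"], np.ones(6, bool))
        assert np.allclose(ga, epoch)

    def test_participants_weighted_equally_not_pooled(self):
        # participant a: 10 epochs of 0s; participant b: 1 epoch of 2s
        epochs = np.concatenate([np.zeros((10, 2, 3)), np.full((1, 2, 3), 2.0)])
        who = ["a"] * 10 + ["b"]
        ga = grand_average(epochs, who, np.ones(11, bool))
        assert np.allclose(ga, 1.0)  # pooled mean would be 2/11

    def test_overall_average_between_condition_averages(self):
        rng = np.random.default_rng(30)
        epochs = rng.standard_normal((20, 2, 3))
        who = np.repeat(["a", "b"], 10)
        correct = np.tile([True] * 5 + [False] * 5, 2)  # equal counts per condition
        ga_c = grand_average(epochs, who, correct)
        ga_i = grand_average(epochs, who, ~correct)
        ga_all = grand_average(epochs, who, np.ones(20, bool))
        assert np.all(ga_all >= np.minimum(ga_c, ga_i) - 1e-12)
        assert np.all(ga_all <= np.maximum(ga_c, ga_i) + 1e-12)


class TestPointwiseErpTests:
    def make_epochs(self, rng, shift=False, n_per=20, participants=6):
        """participants x n_per epochs per condition, 4 channels x 24 samples."""
        epochs, who, correct = [], [], []
        t = np.arange(24)
        bump_c = np.sin(np.pi * np.clip((t - 10) / 6, 0, 1))
        bump_i = np.sin(np.pi * np.clip((t - 7) / 6, 0, 1))
        for p in range(participants):
            for cond in (True, False):
                x = rng.standard_normal((n_per, 4, 24))
                if shift:
                    x[:, 2, :] += 3 * (bump_c if cond else bump_i)
                epochs.append(x)
                who += [f"p{p}"] * n_per
                correct += [cond] * n_per
        return np.concatenate(epochs), np.array(who), np.array(correct)

    def test_identical_conditions_give_p_one(self):
        x = np.random.default_rng(1).standard_normal((4, 2, 24))
        epochs = np.concatenate([x, x])  # the two conditions share the same epochs
        who = np.array(["a", "a", "b", "b"] * 2)
        correct = np.array([True] * 4 + [False] * 4)
        p_pooled, p_paired = pointwise_erp_tests(epochs, correct, who)
        assert np.all(p_paired == 1.0)
        assert np.all(p_pooled > 0.9)

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(2)
        epochs, who, correct = self.make_epochs(rng, shift=False)
        p_pooled, _ = pointwise_erp_tests(epochs, correct, who)
        frac = (p_pooled < 0.05).mean()
        assert 0.0 <= frac <= 0.12  # 96 cells, Monte-Carlo tolerance

    def test_latency_shift_detected_in_the_loaded_channel(self):
        rng = np.random.default_rng(3)
        epochs, who, correct = self.make_epochs(rng, shift=True)
        p_pooled, p_paired = pointwise_erp_tests(epochs, correct, who)
        sig = p_pooled[2] < 0.05
        # a contiguous run of significant samples where the bumps differ
        assert sig[8:13].all()
        assert (p_pooled[[0, 1, 3]] < 0.05).mean() < 0.15  # clean channels stay null
        assert (p_paired[2][7:12] < 0.05).any()

    def test_bonferroni_option_scales_p(self):
        rng = np.random.default_rng(4)
        epochs, who, correct = self.make_epochs(rng, shift=False, n_per=5, participants=4)
        raw, _ = pointwise_erp_tests(epochs, correct, who)
        adj, _ = pointwise_erp_tests(epochs, correct, who, bonferroni=True)
        assert np.allclose(adj, np.minimum(1.0, raw * raw.size))


class TestWeightSummaries:
    def toy_votes(self):
        return pd.DataFrame(
            {
                "participant": ["a"] * 6,
                "trial": range(6),
                "correct": [True, True, True, True, False, False],
                "dom": [0, 0, 6, 6, 6, 6],
                "w_RT": [30.0, 28.0, 24.0, 22.0, 20.0, 18.0],
                "w_nf": [29.0, 27.0, 25.0, 23.0, 19.0, 17.0],
                "w_RTnf": [29.5, 27.5, 24.5, 22.5, 19.5, 17.5],
            }
        )

    def test_medians_match_hand_sorting(self):
        tables = weight_summaries(self.toy_votes())
        by_corr = tables["by_correctness"]
        assert by_corr.loc["correct", "RT"] == pytest.approx((28 + 24) / 2)
        assert by_corr.loc["incorrect", "RT"] == pytest.approx(19.0)
        by_dom = tables["by_dom"]
        assert by_dom.loc[0, "nf"] == pytest.approx(28.0)
        assert by_dom.loc[6, "RTnf"] == pytest.approx((22.5 + 19.5) / 2)

    def test_empty_cells_reported_missing(self):
        tables = weight_summaries(self.toy_votes())
        assert np.isnan(tables["by_dom"].loc[3, "RT"])

    def test_single_vote_class_median_is_that_weight(self):
        votes = self.toy_votes().iloc[:1]
        tables = weight_summaries(votes)
        assert tables["by_correctness"].loc["correct", "RT"] == 30.0


def test_weight_density_integrates_to_one():
    rng = np.random.default_rng(5)
    grid, pdf = weight_density(rng.gamma(5.0, 4.0, size=500))
    assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=1e-3)
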