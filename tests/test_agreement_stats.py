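import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mjtkinect.agreement_stats import (bias_t_test, bland_altman_repeated,
                                       levene_equal_variance,
                                       wilcoxon_exact_p, wilcoxon_retest)
from mjtkinect.recording_io import TimesTable
from mjtkinect.synthetic_scene import simulate_times_panel
from oracles import wilcoxon_two_sided_enumeration


def _table(diffs_by_subject, base=8.0):
    """TimesTable where kinect - ground_truth equals the given differences."""
    rows = []
    for s, (sid, ds) in enumerate(diffs_by_subject.items()):
        for j, d in enumerate(ds):
            rep, hand = 1 + j % 2, ("most", "least")[j // 2 % 2]
            for method, total in (("ground_truth", base), ("kinect", base + d)):
                rows.append({"subject_id": sid, "repetition": rep, "hand": hand,
                             "subtest": "card", "method": method, "start_s": 1.0,
                             "end_s": 1.0 + total, "total_s": total})
    return TimesTable(pd.DataFrame(rows))


class TestBlandAltmanRepeated:
    def test_identical_methods_have_zero_bias_and_loa(self):
        tbl = _table({"A": [0, 0], "B": [0, 0]})
        res = bland_altman_repeated(tbl, ("kinect", "ground_truth"), "total")
        assert res.bias_s == res.sd_diff_s == 0.0
        assert res.loa_low_s == res.loa_high_s == 0.0

    def test_two_subject_anova_components(self):
        """d = {1,1},{3,3}: MS_within = 0; MS_between = 4 on 1 df; the
        between-subject component is (4-0)/2 = 2, so sd = sqrt(2).

        Oracle: explicit one-way ANOVA sums computed here from scratch.
        """
        d = {"A": [1.0, 1.0], "B": [3.0, 3.0]}
        flat = np.array([1.0, 1.0, 3.0, 3.0])
        means = np.array([1.0, 3.0])
        grand = flat.mean()
        ss_w = sum((x - m) ** 2 for xs, m in zip(d.values(), means) for x in xs)
        ms_w = ss_w / (4 - 2)
        ms_b = (2 * (means - grand) ** 2).sum() / (2 - 1)
        m0 = (4 ** 2 - (2 ** 2 + 2 ** 2)) / ((2 - 1) * 4)
        sd_expected = np.sqrt(ms_w + (ms_b - ms_w) / m0)

        res = bland_altman_repeated(_table(d), ("kinect", "ground_truth"), "total")
        assert res.bias_s == pytest.approx(2.0)
        assert res.sd_diff_s == pytest.approx(sd_expected) == pytest.approx(np.sqrt(2))
        assert res.loa_low_s == pytest.approx(2 - 1.96 * np.sqrt(2))
        assert res.loa_high_s == pytest.approx(2 + 1.96 * np.sqrt(2))

    def test_single_observation_per_subject_reduces_to_classic(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.3, 0.5, 12)
        tbl = _table({f"S{i}": [d[i]] for i in range(12)})
        res = bland_altman_repeated(tbl, ("kinect", "ground_truth"), "total")
        assert res.bias_s == pytest.approx(d.mean())
        assert res.sd_diff_s == pytest.approx(np.std(d, ddof=1))

    def test_loa_width_identity(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            d = {f"S{i}": rng.normal(0, 1, rng.integers(1, 4)).tolist()
                 for i in range(6)}
            res = bland_altman_repeated(_table(d), ("kinect", "ground_truth"), "total")
            assert res.loa_width_s == pytest.approx(2 * 1.96 * res.sd_diff_s)

    def test_missing_observation_named(self):
        tbl = _table({"A": [1.0, 1.0]})
        df = tbl.df.drop(index=[1]).reset_index(drop=True)   # drop one kinect row
        broken = TimesTable(df)
        with pytest.raises(ValueError, match="missing"):
            bland_altman_repeated(broken, ("kinect", "ground_truth"), "total")

    def test_variance_components_recovered_on_large_panel(self):
        tbl = simulate_times_panel(200, bias_s=0.2, sd_within_s=0.3,
                                   sd_between_s=0.1, seed=7)
        res = bland_altman_repeated(tbl, ("kinect", "ground_truth"), "total")
        assert abs(res.bias_s - 0.2) < 0.05
        truth = np.hypot(0.3, 0.1)
        assert abs(res.sd_diff_s - truth) / truth < 0.10


class TestBiasTTest:
    def test_zero_means(self):
        tbl = _table({"A": [0.0], "B": [0.0], "C": [0.0]})
        res = bias_t_test(bland_altman_repeated(tbl, ("kinect", "ground_truth"),
                                                "total"))
        assert res.t_stat == 0.0 and res.p_bias == 1.0

    def test_constant_nonzero_means_degenerate(self):
        tbl = _table({"A": [1.0], "B": [1.0], "C": [1.0]})
        res = bias_t_test(bland_altman_repeated(tbl, ("kinect", "ground_truth"),
                                                "total"))
        assert res.degenerate and res.p_bias == 0.0

    def test_textbook_one_sample_t(self):
        means = np.array([0.1, 0.2, 0.3, 0.2])
        tbl = _table({f"S{i}": [m] for i, m in enumerate(means)})
        res = bias_t_test(bland_altman_repeated(tbl, ("kinect", "ground_truth"),
                                                "total"), m_comparisons=3)
        t_expected = means.mean() / (means.std(ddof=1) / np.sqrt(4))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=3)
        assert res.t_stat == pytest.approx(t_expected)
        assert res.p_bias == pytest.approx(p_expected)
        assert res.p_bias_adj == pytest.approx(min(1.0, 3 * p_expected))


class TestLevene:
    def test_identical_sets(self):
        a = [1.0, 2.0, 3.0, 4.0]
        (res,) = levene_equal_variance([a, list(a)])
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_adj"] == 1.0

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 50), rng.normal(0, 10, 50)
        (res,) = levene_equal_variance([a, b])
        assert res["p_adj"] < 0.05

    def test_three_sets_give_three_bonferroni_pairs(self):
        rng = np.random.default_rng(3)
        sets = [rng.normal(0, 1, 20) for _ in range(3)]
        out = levene_equal_variance(sets)
        assert [r["pair"] for r in out] == [(0, 1), (0, 2), (1, 2)]
        for r in out:
            assert r["p_adj"] == pytest.approx(min(1.0, 3 * r["p"]))

    def test_small_set_rejected(self):
        with pytest.raises(ValueError):
            levene_equal_variance([[1.0, 2.0], [1.0, 2.0, 3.0]])

    def test_matches_scipy_mean_centred(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 2, 30)
        (res,) = levene_equal_variance([a, b], m_comparisons=1)
        w, p = stats.levene(a, b, center="mean")
        assert res["statistic"] == pytest.approx(w)
        assert res["p_adj"] == pytest.approx(p)


class TestWilcoxonRetest:
    def test_equal_repetitions(self):
        x = [5.0, 6.0, 7.0, 8.0, 9.0]
        res = wilcoxon_retest(x, x)
        assert res.median_diff_s == 0.0 and res.p_wilcoxon == 1.0

    def test_six_positive_untied_differences(self):
        rep2 = np.array([5.0, 6, 7, 8, 9, 10])
        rep1 = rep2 + np.array([1.0, 2, 3, 4, 5, 6])
        res = wilcoxon_retest(rep1, rep2)
        assert res.p_wilcoxon == pytest.approx(2 / 64)
        assert res.median_diff_s == pytest.approx(3.5)

    def test_median_and_iqr_reported(self):
        rep1 = np.array([10.0, 9, 8, 12, 11])
        rep2 = np.array([8.0, 8, 7, 9, 9])
        res = wilcoxon_retest(rep1, rep2)
        d = rep1 - rep2
        assert res.median_diff_s == np.median(d)
        assert res.iqr_s == pytest.approx(np.percentile(d, 75) - np.percentile(d, 25))

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_matches_full_enumeration(self, seed):
        """Exact signed-rank p equals brute force over all 2^n sign patterns,
        including midranked ties, for n <= 12."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d = np.round(rng.normal(0, 2, n), 1)       # rounding makes ties likely
        assert wilcoxon_exact_p(d) == pytest.approx(wilcoxon_two_sided_enumeration(d))

    def test_exact_p_matches_scipy_when_tie_free(self):
        d = np.array([0.8, -1.3, 2.1, 3.7, -0.2, 1.9, -2.8])
        assert wilcoxon_exact_p(d) == pytest.approx(
            stats.wilcoxon(d, method="exact").pvalue)

    def test_practice_effect_panel(self):
        tbl = simulate_times_panel(10, bias_s=0.0, sd_within_s=0.0,
                                   sd_between_s=0.0, practice_effect_s=2.0, seed=1)
        df = tbl.df
        gt = df[df["method"] == "ground_truth"]
        wide = gt.pivot_table(index=["subject_id", "hand"], columns="repetition",
                              values="total_s")
        res = wilcoxon_retest(wide[1].to_numpy(), wide[2].to_numpy())
        assert res.median_diff_s == pytest.approx(2.0)
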