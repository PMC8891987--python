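"""Normality testing, the comparison decision tree, Dunn's post hoc, ROUT."""

import numpy as np
import pytest
from scipy import stats as sps

from cellmech.errors import DegenerateDataError
from cellmech.stats import (
    GroupedSample,
    compare_groups,
    dagostino_pearson,
    dunn_test,
    kruskal_wallis,
    rout_outliers,
)

THREE_GROUPS = {
    "a": np.array([1.0, 2, 3, 4, 5]),
    "b": np.array([2.0, 3, 4, 5, 6]),
    "c": np.array([10.0, 11, 12, 13, 14]),
}


def brute_force_kw_h(groups):
    """Independent oracle: explicit pooled ranking + H with tie correction."""
    pooled = np.concatenate(list(groups.values()))
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank of the tie block
        i = j
    n_tot = len(pooled)
    h = 0.0
    start = 0
    for v in groups.values():
        r = ranks[start : start + len(v)]
        h += r.sum() ** 2 / len(v)
        start += len(v)
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3 * (n_tot + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n_tot**3 - n_tot)
    return h / correction


class TestDagostinoPearson:
    def test_null_acceptance_rate_under_normality(self):
        rng = np.random.default_rng(0)
        accepted = sum(
            dagostino_pearson(rng.normal(size=5000))[1] > 0.05 for _ in range(100)
        )
        assert accepted >= 90

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(1)
        _, p = dagostino_pearson(rng.exponential(size=500))
        assert p < 0.05

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            dagostino_pearson([1.0, 2, 3, 4, 5])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            dagostino_pearson(np.ones(20))


class TestKruskalWallisAndDunn:
    def test_h_matches_brute_force_rank_oracle(self):
        h, _ = kruskal_wallis(THREE_GROUPS)
        assert h == pytest.approx(brute_force_kw_h(THREE_GROUPS), rel=1e-12)
        assert h == pytest.approx(9.8504, abs=1e-4)  # frozen from the oracle

    def test_identical_groups_no_separation(self):
        rng = np.random.default_rng(2)
        vals = rng.exponential(size=20)  # non-normal so the rank branch fires
        sample = GroupedSample({"g1": vals, "g2": vals.copy(), "g3": vals.copy()})
        report = compare_groups(sample)
        assert report.test_used == "kruskal-wallis+dunn"
        assert report.statistic == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(report.pairwise["p_adj"], 1.0)

    def test_constant_data_has_h_zero(self):
        h, p = kruskal_wallis({"a": np.ones(5), "b": np.ones(5)})
        assert (h, p) == (0.0, 1.0)

    def test_dunn_adjustment_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            groups = {k: rng.normal(loc, 1, 15) for k, loc in zip("abcd", rng.normal(0, 1, 4))}
            res = dunn_test(groups)
            assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()
            assert (res["p_adj"] <= 1.0).all()

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = {k: rng.normal(size=30) for k in "abc"}
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestCompareGroupsBranching:
    def test_normal_data_takes_anova_branch(self):
        rng = np.random.default_rng(5)
        sample = GroupedSample({k: rng.normal(i, 1, 40) for i, k in enumerate("abc")})
        report = compare_groups(sample)
        assert report.test_used == "one-way-anova+tukey"
        assert report.p_value < 0.05

    def test_partially_normal_rule_is_permissive_by_default(self):
        rng = np.random.default_rng(6)
        groups = {
            "norm": rng.normal(0, 1, 60),
            "expo": rng.exponential(1, 60),
            "expo2": rng.exponential(1, 60),
        }
        permissive = compare_groups(GroupedSample(groups))
        orthodox = compare_groups(GroupedSample(groups), normality_rule="all")
        assert permissive.test_used == "one-way-anova+tukey"
        assert orthodox.test_used == "kruskal-wallis+dunn"

    def test_two_way_design_reports_primary_factor(self):
        rng = np.random.default_rng(7)
        groups, factor2 = {}, {}
        for k, mu in [("a", 0.0), ("b", 2.0)]:
            groups[k] = np.concatenate([rng.normal(mu, 1, 20), rng.normal(mu + 1, 1, 20)])
            factor2[k] = np.array(["soft"] * 20 + ["stiff"] * 20)
        report = compare_groups(
            GroupedSample(groups, factor2=factor2), design="two-way"
        )
        assert report.test_used == "two-way-anova+tukey"
        assert report.p_value < 0.05

    def test_permutation_invariance_to_group_order(self):
        rng = np.random.default_rng(8)
        groups = {k: rng.exponential(1 + i, 25) for i, k in enumerate("abc")}
        r1 = compare_groups(GroupedSample(groups))
        r2 = compare_groups(GroupedSample(dict(reversed(list(groups.items())))))
        assert r1.p_value == pytest.approx(r2.p_value)
        pairs1 = {frozenset((a, b)): p for a, b, p in
                  r1.pairwise[["group1", "group2", "p_adj"]].itertuples(index=False)}
        pairs2 = {frozenset((a, b)): p for a, b, p in
                  r2.pairwise[["group1", "group2", "p_adj"]].itertuples(index=False)}
        for key in pairs1:
            assert pairs1[key] == pytest.approx(pairs2[key])

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            GroupedSample({"only": np.arange(5.0)})

    def test_summary_renders(self):
        rng = np.random.default_rng(9)
        report = compare_groups(GroupedSample({k: rng.normal(size=30) for k in "ab"}))
        text = report.summary()
        assert "Normality" in text and "Pairwise" in text


class TestRoutOutliers:
    def test_false_positive_rate_on_clean_data(self):
        rng = np.random.default_rng(10)
        ok = sum(
            rout_outliers(rng.normal(size=100)).n_outliers <= 2 for _ in range(100)
        )
        assert ok >= 95

    def test_injected_10sd_point_flagged(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=100)
        scale = 1.4826 * np.median(np.abs(x - np.median(x)))
        x[0] = np.median(x) + 10 * scale
        res = rout_outliers(x)
        assert res.flags[0]

    def test_constant_sample_with_one_deviant(self):
        x = np.full(20, 5.0)
        x[7] = 9.0
        with pytest.warns(UserWarning):
            res = rout_outliers(x)
        assert res.flags[7] and res.n_outliers == 1

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rout_outliers(np.arange(5.0))

    def test_flags_never_mutate_data(self):
        x = np.arange(20.0)
        x_copy = x.copy()
        rout_outliers(x)
        assert np.array_equal(x, x_copy)
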