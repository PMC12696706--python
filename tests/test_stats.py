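import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from docbci.stats import (
    build_contrast_tables,
    contrast_pvalues,
    pearson_chi2,
    quartiles,
    spearman_rho,
    welch_t,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

# --- independent enumeration oracles --------------------------------


def oracle_rank_sum_p(x, y):
    """Enumerate every assignment of the pooled values into two groups
    of the observed sizes and compute the two-sided rank-sum p."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:nx].sum()
    sums = np.array([ranks[list(c)].sum()
                     for c in itertools.combinations(range(n), nx)])
    eps = 1e-9
    return min(1.0, 2 * min((sums <= w_obs + eps).mean(),
                            (sums >= w_obs - eps).mean()))


def oracle_signed_rank_p(pre, post):
    """Enumerate all 2^n sign patterns of the nonzero differences."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    s = ranks.sum()
    d_obs = ranks[d > 0].sum() - ranks[d < 0].sum()
    count = 0
    for bits in itertools.product([1, -1], repeat=n):
        w_plus = ranks[np.array(bits) > 0].sum()
        if abs(2 * w_plus - s) >= abs(d_obs) - 1e-9:
            count += 1
    return min(1.0, count / 2**n)


def oracle_spearman_p(a, b):
    """Enumerate all n! permutations of one ranking."""
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    rho_obs = np.corrcoef(ra, rb)[0, 1]
    count, total = 0, 0
    for perm in itertools.permutations(rb):
        r = np.corrcoef(ra, perm)[0, 1]
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


class TestRankSum:
    def test_separated_triples_give_point_one(self):
        gc = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert gc.p == pytest.approx(0.1, abs=1e-12)
        assert gc.method == "exact"

    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning):
            gc = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert gc.p == 1.0

    @pytest.mark.parametrize("x,y", [
        ([1, 2, 3], [4, 5, 6]),
        ([1.5, 2.5, 7.0, 3.0], [2.5, 2.5, 8.0]),       # ties
        ([0, 0, 1, 1], [0, 1, 1, 2]),                  # heavy ties
        ([10, 12, 9, 15, 11], [13, 14, 16]),
    ])
    def test_exact_mode_matches_enumeration_oracle(self, x, y):
        gc = wilcoxon_rank_sum(x, y)
        assert gc.p == pytest.approx(oracle_rank_sum_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            gc = wilcoxon_rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact")
            assert gc.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = rng.normal(loc=0.8, size=15)
        ab = wilcoxon_rank_sum(x, y)
        ba = wilcoxon_rank_sum(y, x)
        assert ab.p == pytest.approx(ba.p, abs=1e-12)
        assert ab.z == pytest.approx(-ba.z, abs=1e-9)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1, 2], [3, 4, 5])

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=19)
        y = rng.normal(loc=1.0, size=12)
        gc = wilcoxon_rank_sum(x, y)
        assert gc.method == "normal_tie_corrected"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert gc.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSignedRank:
    def test_all_increases_give_floor_statistic(self):
        pre = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        post = [2.0, 3.5, 4.0, 5.5, 6.0, 7.5]
        gc = wilcoxon_signed_rank(pre, post)
        assert gc.statistic == 0.0  # sum of negative ranks at its floor
        assert gc.extra["w_plus"] == 21.0

    def test_symmetric_differences_are_null(self):
        pre = np.arange(6, dtype=float)
        post = pre + np.array([0.1, -0.1, 0.1, -0.1, 0.1, -0.1])
        gc = wilcoxon_signed_rank(pre, post)
        assert gc.p > 0.5

    @pytest.mark.parametrize("pre,post", [
        ([1, 2, 3, 4, 5, 6], [2, 1.5, 5, 4.5, 8, 5.5]),
        ([0, 0, 1, 2, 3, 4], [1, 1, 0, 4, 5, 3]),        # tied |d|
        ([1, 2, 3, 4, 5, 6, 7, 8], [3, 1, 5, 6, 4, 8, 9, 7]),
    ])
    def test_exact_mode_matches_two_power_n_oracle(self, pre, post):
        gc = wilcoxon_signed_rank(pre, post)
        assert gc.method == "exact"
        assert gc.p == pytest.approx(oracle_signed_rank_p(pre, post),
                                     abs=1e-12)

    def test_exact_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(size=10)
        post = pre + rng.normal(0.5, 1.0, size=10)
        gc = wilcoxon_signed_rank(pre, post)
        ref = sps.wilcoxon(post, pre, method="exact")
        assert gc.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            gc = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert gc.p == 1.0

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        pre = rng.normal(size=19)
        post = pre + rng.normal(0.6, 1.0, size=19)
        gc = wilcoxon_signed_rank(pre, post)
        assert gc.method == "normal_tie_corrected"
        assert 0 < gc.p <= 1


class TestWelchT:
    def test_published_mi_trials_contrast(self):
        gc = welch_t((5.75, 1.55, 12), (8.21, 2.15, 19))
        assert gc.statistic == pytest.approx(-3.701, abs=0.02)
        assert gc.p < 0.001

    def test_equal_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        gc = welch_t(x, x.copy())
        assert gc.statistic == pytest.approx(0.0, abs=1e-12)

    def test_summaries_equal_raw(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=14)
        y = rng.normal(0.5, 2.0, size=11)
        raw = welch_t(x, y)
        summ = welch_t((x.mean(), x.std(ddof=1), len(x)),
                       (y.mean(), y.std(ddof=1), len(y)))
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-12)

    def test_pooled_flag_matches_students_t(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=8)
        y = rng.normal(size=12)
        gc = welch_t(x, y, pooled=True)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert gc.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_zero_variance_in_both_groups_undefined(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0, 1.0], [2.0, 2.0])


class TestChi2:
    def test_published_sex_table(self):
        gc = pearson_chi2([[8, 4], [16, 3]])
        assert gc.statistic == pytest.approx(1.295, abs=5e-4)
        assert 0 < gc.p <= 1
        assert "fisher_p" in gc.extra

    def test_independence_gives_zero(self):
        gc = pearson_chi2([[5, 5], [5, 5]])
        assert gc.statistic == 0.0

    def test_matches_expected_count_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = rng.integers(1, 20, size=(2, 2)).astype(float)
            obs = pearson_chi2(t).statistic
            total = t.sum()
            expected = np.outer(t.sum(1), t.sum(0)) / total
            oracle = float(np.sum((t - expected) ** 2 / expected))
            assert obs == pytest.approx(oracle, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 3]])


class TestSpearman:
    def test_perfect_monotone(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_rho(a, a**2).rho == pytest.approx(1.0)
        assert spearman_rho(a, -a).rho == pytest.approx(-1.0)

    def test_exact_permutation_matches_enumeration_oracle(self):
        a = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3]
        b = [2.0, 7.0, 1.0, 8.0, 2.8, 1.8, 2.8]  # includes a tie
        res = spearman_rho(a, b)
        assert res.method == "exact_permutation"
        assert res.p == pytest.approx(oracle_spearman_p(a, b), abs=1e-12)

    def test_t_approximation_matches_scipy_for_larger_n(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=25)
        b = a + rng.normal(0, 1.5, size=25)
        res = spearman_rho(a, b)
        ref = sps.spearmanr(a, b)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=20)
        b = a + rng.normal(0, 1.0, size=20)
        r1 = spearman_rho(a, b, seed=3)
        r2 = spearman_rho(a, b, seed=3)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.rho <= r1.ci_high

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestQuartiles:
    def test_linear_interpolation_convention(self):
        med, q1, q3 = quartiles([1.0, 2.0, 3.0, 4.0])
        assert (med, q1, q3) == (2.5, 1.75, 3.25)


def _toy_rpt(n_uws=6, n_mcs=7, effect=0.0, seed=0):
    """Tidy relative-power table with an optional task-theta shift."""
    rng = np.random.default_rng(seed)
    rows = []
    bands = ("delta", "theta", "alpha", "beta", "gamma")
    base = np.array([0.4, 0.2, 0.2, 0.15, 0.05])
    sid = 0
    for group, n in (("UWS", n_uws), ("MCS", n_mcs)):
        for _ in range(n):
            sid += 1
            for condition in ("rest", "task"):
                for region in ("frontal", "parietal"):
                    w = base + rng.normal(0, 0.01, 5)
                    if condition == "task" and group == "MCS":
                        w[1] += effect
                    w = np.clip(w, 1e-3, None)
                    w = w / w.sum()
                    for band, v in zip(bands, w):
                        rows.append({"subject_id": f"T{sid:02d}",
                                     "group": group,
                                     "condition": condition,
                                     "region": region, "band": band,
                                     "rel_power": v})
    return pd.DataFrame(rows)


class TestContrastTables:
    def test_table_shape_ten_blocks_two_groups(self):
        tables = build_contrast_tables(_toy_rpt())
        within = tables["table2_within"]
        assert len(within) == 20  # 2 regions x 5 bands x 2 groups
        assert len(tables["table2_between"]) == 30
        ps = contrast_pvalues(tables)
        assert ps.size == 50
        assert np.all((ps > 0) & (ps <= 1))

    def test_injected_effect_detected(self):
        tables = build_contrast_tables(_toy_rpt(effect=0.15, seed=1))
        w = tables["table2_within"].set_index(["region", "band", "group"])
        row = w.loc[("parietal", "theta", "MCS")]
        # n=7 pairs -> the exact two-sided floor is 2/2^7 = 0.0156
        assert row.p == pytest.approx(2 / 2**7, abs=1e-12)
        assert row.delta_median > 0

    def test_missing_subject_cell_skips_with_reason(self):
        rpt = _toy_rpt(n_uws=3, n_mcs=7)  # UWS too small for pairs
        tables = build_contrast_tables(rpt)
        assert len(tables["table2_within"]) == 0
        assert len(tables["skipped"]) == 10
        assert (tables["skipped"].reason.str.contains("complete")).all()
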