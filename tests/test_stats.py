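"""Group statistics: splits, mixed ANOVA with independent oracles, classic tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rmfaces.stats import (
    SYNTHETIC_SPQ_KEY,
    chi_square_2x2,
    cronbach_alpha,
    ks_normality,
    median_split,
    mixed_anova_2x2,
    one_sample_t,
    rm_ancova_2level,
    score_spq,
    spearman_rho,
    tertile_split,
    tukey_posthoc,
)


class TestScoreSpq:
    def test_all_yes_gives_74(self):
        assert score_spq(np.ones(74))["total"] == 74

    def test_all_no_gives_0(self):
        assert score_spq(np.zeros(74))["total"] == 0

    def test_factor_sums_bounded_by_total(self, rng):
        for _ in range(20):
            items = rng.integers(0, 2, 74)
            scores = score_spq(items)
            for factor in SYNTHETIC_SPQ_KEY["factors"]:
                assert 0 <= scores[factor]
            # dimensions partition the items, so they sum to the total
            dim_sum = sum(
                scores[d] for d in SYNTHETIC_SPQ_KEY["dimensions"]
            )
            assert dim_sum == scores["total"]

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ValueError):
            score_spq(np.ones(73))


class TestSplits:
    def test_median_split_even_case(self):
        labels = median_split([1, 2, 3, 4])
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_median_ties_go_low_by_default(self):
        labels = median_split([1, 2, 2, 3])
        assert labels.tolist() == ["low", "low", "low", "high"]

    def test_median_tie_rule_configurable(self):
        labels = median_split([1, 2, 2, 3], ties="high")
        assert labels.tolist() == ["low", "high", "high", "high"]

    def test_split_invariant_to_order(self, rng):
        scores = rng.integers(0, 40, 21)
        perm = rng.permutation(21)
        direct = median_split(scores)[perm]
        permuted = median_split(scores[perm])
        assert direct.tolist() == permuted.tolist()

    def test_all_equal_scores_rejected(self):
        with pytest.raises(ValueError):
            median_split([3, 3, 3])

    def test_tertile_split_exact_thirds(self):
        labels = tertile_split([10, 20, 30, 40, 50, 60, 70, 80, 90])
        assert labels.tolist() == ["low"] * 3 + ["middle"] * 3 + ["high"] * 3

    def test_tertile_order_property(self, rng):
        scores = rng.normal(size=30)
        labels = tertile_split(scores)
        assert scores[labels == "low"].max() < scores[labels == "high"].min()

    def test_tertile_boundary_ties_fall_into_middle(self):
        # rank-based oracle: values equal to either boundary quantile are
        # neither strictly below q1 nor strictly above q2
        scores = np.array([1.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 3.0, 4.0])
        q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
        labels = tertile_split(scores)
        for x, lab in zip(scores, labels):
            expected = "low" if x < q1 else ("high" if x > q2 else "middle")
            assert lab == expected


def regression_oracle_mixed(y, group):
    """Independent cell-means/model-comparison oracle for the 2x2 mixed ANOVA."""
    y = np.asarray(y, float)
    group = np.asarray(group)
    glabels = np.unique(group)
    z = np.where(group == glabels[1], 0.5, -0.5)
    N = len(y)
    df_den = N - 2

    # group effect: model comparison on subject means, scaled by k=2
    m = y.mean(axis=1)
    X_full = np.column_stack([np.ones(N), z])
    beta, *_ = np.linalg.lstsq(X_full, m, rcond=None)
    ssr_full = float(np.sum((m - X_full @ beta) ** 2))
    ssr_red = float(np.sum((m - m.mean()) ** 2))
    F_group = (ssr_red - ssr_full) / (ssr_full / df_den)

    # within/interaction: OLS of difference scores with covariance-based t
    d = y[:, 1] - y[:, 0]
    XtX_inv = np.linalg.inv(X_full.T @ X_full)
    b = XtX_inv @ X_full.T @ d
    resid = d - X_full @ b
    s2 = float(resid @ resid) / df_den
    t0 = b[0] / np.sqrt(s2 * XtX_inv[0, 0])
    t1 = b[1] / np.sqrt(s2 * XtX_inv[1, 1])
    return F_group, float(t0**2), float(t1**2)


class TestMixedAnova:
    def test_constant_data_gives_zero_f(self):
        y = np.full((10, 2), 3.0)
        g = np.repeat(["a", "b"], 5)
        table = mixed_anova_2x2(y, g)
        for row in table.rows:
            assert row.F == 0.0
            assert row.partial_eta_sq == 0.0

    @pytest.mark.parametrize("seed,n1,n2", [(0, 4, 4), (1, 8, 8), (2, 6, 9), (3, 5, 12)])
    def test_equals_regression_oracle(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(n1 + n2, 2))
        g = np.array(["a"] * n1 + ["b"] * n2)
        table = mixed_anova_2x2(y, g)
        F_g, F_w, F_i = regression_oracle_mixed(y, g)
        assert table["Group"].F == pytest.approx(F_g, abs=1e-10)
        assert table["Within"].F == pytest.approx(F_w, abs=1e-10)
        assert table["Interaction"].F == pytest.approx(F_i, abs=1e-10)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_pingouin_on_balanced_data(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        n = 12
        y = rng.normal(size=(2 * n, 2))
        g = np.repeat(["a", "b"], n)
        table = mixed_anova_2x2(y, g)
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(2 * n), 2),
                "group": np.repeat(g, 2),
                "within": np.tile(["w1", "w2"], 2 * n),
                "y": y.ravel(),
            }
        )
        pt = pg.mixed_anova(df, dv="y", within="within", subject="subj",
                            between="group").set_index("Source")
        assert table["Group"].F == pytest.approx(pt.loc["group", "F"], rel=1e-9)
        assert table["Within"].F == pytest.approx(pt.loc["within", "F"], rel=1e-9)
        assert table["Interaction"].F == pytest.approx(
            pt.loc["Interaction", "F"], rel=1e-9
        )
        assert table["Group"].partial_eta_sq == pytest.approx(
            pt.loc["group", "np2"], rel=1e-9
        )

    def test_interaction_p_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(2024)
        n = 40
        y = rng.normal(size=(2 * n, 2))
        y[n:, 1] += 0.35
        g = np.repeat(["a", "b"], n)
        p_param = mixed_anova_2x2(y, g)["Interaction"].p
        F_obs = mixed_anova_2x2(y, g)["Interaction"].F
        B = 10**4
        count = sum(
            mixed_anova_2x2(y, g[rng.permutation(2 * n)])["Interaction"].F >= F_obs
            for _ in range(B)
        )
        p_perm = count / B
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / B)
        assert abs(p_param - p_perm) < 3 * se

    def test_p_values_and_eta_in_unit_interval(self, rng):
        for _ in range(10):
            n1, n2 = rng.integers(3, 12, 2)
            y = rng.normal(size=(n1 + n2, 2))
            g = np.array(["a"] * n1 + ["b"] * n2)
            for row in mixed_anova_2x2(y, g).rows:
                assert 0.0 <= row.p <= 1.0
                assert 0.0 <= row.partial_eta_sq <= 1.0

    def test_missing_cells_rejected(self):
        y = np.ones((6, 2))
        y[0, 1] = np.nan
        with pytest.raises(ValueError):
            mixed_anova_2x2(y, np.repeat(["a", "b"], 3))


def difference_score_oracle(y, x):
    """Hand-computed regression of the difference score on the centred covariate."""
    d = y[:, 1] - y[:, 0]
    xc = x - x.mean()
    n = len(d)
    b1 = float(np.sum(xc * d) / np.sum(xc**2))
    b0 = d.mean()
    resid = d - b0 - b1 * xc
    s2 = float(resid @ resid) / (n - 2)
    F_slope = b1**2 / (s2 / np.sum(xc**2))
    F_icept = b0**2 / (s2 / n)
    return F_icept, F_slope


class TestAncova:
    def test_orthogonal_covariate_gives_zero_interaction(self):
        d = np.array([1.0, -1.0, 1.0, -1.0])
        x = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to d by construction
        y = np.column_stack([np.zeros(4), d])
        table = rm_ancova_2level(y, x)
        assert table["Within*Covariate"].F == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_difference_score_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        y = rng.normal(size=(n, 2))
        x = rng.normal(size=n)
        table = rm_ancova_2level(y, x)
        F_icept, F_slope = difference_score_oracle(y, x)
        assert table["Within"].F == pytest.approx(F_icept, abs=1e-10)
        assert table["Within*Covariate"].F == pytest.approx(F_slope, abs=1e-10)

    def test_centring_leaves_interaction_unchanged(self, rng):
        y = rng.normal(size=(12, 2))
        x = rng.normal(size=12)
        assert rm_ancova_2level(y, x)["Within*Covariate"].F == pytest.approx(
            rm_ancova_2level(y, x + 100.0)["Within*Covariate"].F
        )

    def test_zero_variance_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            rm_ancova_2level(rng.normal(size=(8, 2)), np.ones(8))


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        res = one_sample_t([9, 10, 12, 13], 11.0)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["d"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_formula(self):
        # mean 12, sd sqrt(2.5), n 5 vs mu0 11
        res = one_sample_t([10, 11, 12, 13, 14], 11.0)
        assert res["t"] == pytest.approx(1.0 / (np.sqrt(2.5) / np.sqrt(5)))
        assert res["d"] == pytest.approx(1.0 / np.sqrt(2.5))
        assert res["df"] == 4

    def test_one_tailed_p_halves_two_tailed_for_positive_t(self, rng):
        x = rng.normal(loc=1.0, size=10)
        if one_sample_t(x, 0.0)["t"] > 0:
            assert one_sample_t(x, 0.0, tail="greater")["p"] == pytest.approx(
                one_sample_t(x, 0.0)["p"] / 2
            )

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([5, 5, 5], 4.0)


class TestTukey:
    CELLS = {"hh": 1.0, "ha": 1.0, "lh": 1.0, "la": 1.0}

    def test_identical_means_give_p_one(self):
        out = tukey_posthoc(self.CELLS, ms_error=2.0, n=10, df_error=36)
        assert (out["p_tukey"] >= 1.0 - 1e-9).all()

    def test_adjusted_p_at_least_pairwise_t_p(self, rng):
        cells = {k: float(v) for k, v in zip(self.CELLS, rng.normal(size=4))}
        df_error = 36
        out = tukey_posthoc(cells, ms_error=1.5, n=10, df_error=df_error)
        for _, row in out.iterrows():
            t = row["q"] / np.sqrt(2)
            p_unadj = 2 * sps.t.sf(t, df_error)
            assert row["p_tukey"] >= p_unadj - 1e-12

    def test_matches_studentized_range_table(self):
        # critical value q(.05; k=4, df=20) = 3.958 from standard tables
        se = 1.0
        cells = {"a": 3.958 * se, "b": 0.0, "c": 1.0, "d": 2.0}
        out = tukey_posthoc(cells, ms_error=1.0, n=1, df_error=20)
        row = out.loc[(out["a"] == "a") & (out["b"] == "b")].iloc[0]
        assert row["p_tukey"] == pytest.approx(0.05, abs=1e-3)


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert spearman_rho(x, np.exp(x))["rho"] == pytest.approx(1.0)
        assert spearman_rho(x, -(x**3))["rho"] == pytest.approx(-1.0)

    def test_ties_equal_pearson_of_average_ranks(self, rng):
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        rx = sps.rankdata(x)  # average ranks: brute-force oracle
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y)["rho"] == pytest.approx(expected, abs=1e-12)


class TestChiSquare:
    def test_proportional_table_gives_zero(self):
        assert chi_square_2x2(10, 20, 30, 60)["chi2"] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "table,expected",
        [((9, 37, 7, 42), 0.47), ((2, 44, 3, 46), 0.15)],
    )
    def test_reported_contingency_tables(self, table, expected):
        assert round(chi_square_2x2(*table)["chi2"], 2) == expected

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(-1, 2, 3, 4)


class TestKsNormality:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_gaussian_sample_not_rejected(self, seed):
        x = np.random.default_rng(seed).normal(size=500)
        assert ks_normality(x)["p"] > 0.05

    def test_two_point_data_has_large_d(self):
        res = ks_normality([0.0] * 10 + [1.0] * 10)
        assert res["D"] > 0.25

    def test_d_in_unit_interval(self, rng):
        for _ in range(5):
            res = ks_normality(rng.exponential(size=50))
            assert 0.0 <= res["D"] <= 1.0


class TestCronbach:
    def test_perfectly_correlated_items(self, rng):
        base = rng.normal(size=50)
        X = np.column_stack([base, base, base])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_three_item_toy_against_hand_formula(self, rng):
        X = rng.normal(size=(40, 3))
        k = 3
        expected = k / (k - 1) * (
            1 - X.var(axis=0, ddof=1).sum() / X.sum(axis=1).var(ddof=1)
        )
        assert cronbach_alpha(X) == pytest.approx(expected, rel=1e-12)

    def test_uncorrelated_items_near_zero(self):
        X = np.random.default_rng(5).normal(size=(2000, 10))
        assert abs(cronbach_alpha(X)) < 0.1

    def test_invariant_to_item_location_shift(self, rng):
        X = rng.normal(size=(30, 4))
        Y = X.copy()
        Y[:, 2] += 7.5
        assert cronbach_alpha(X) == pytest.approx(cronbach_alpha(Y))
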