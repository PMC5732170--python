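"""Cohort statistics against independent oracles and closed forms."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from lungquant.stats import (
    chi_square_test,
    cox_lrt,
    cox_partial_loglik,
    fisher_exact,
    fit_logistic,
    km_estimator,
    pearson_correlation,
    recursive_partition_split,
    rescale_odds_ratio,
    roc_curve,
    stepwise_select,
    table_percentages,
    threshold_at_sensitivity,
    wilcoxon_rank_sum,
)
from lungquant.tables import load_printed_tables


class TestFisher:
    def test_2x2_diagonal(self):
        assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("table", [
        [[3, 1], [1, 3]], [[8, 2], [1, 5]], [[10, 0], [0, 10]], [[5, 5], [5, 5]],
    ])
    def test_2x2_matches_scipy(self, table):
        assert fisher_exact(table) == pytest.approx(
            sps.fisher_exact(table)[1], rel=1e-9)

    def test_proportional_rows_give_p_one(self):
        assert fisher_exact([[2, 4], [3, 6]]) == pytest.approx(1.0)

    def test_rxc_matches_permutation_oracle(self):
        table = np.array([[4, 1], [2, 5], [1, 6]])
        p = fisher_exact(table)
        # Monte-Carlo oracle: permute individual labels, recompute table prob
        rng = np.random.default_rng(0)
        rows = np.repeat(np.arange(3), table.sum(axis=1))
        cols = np.repeat(np.arange(2), table.sum(axis=0))
        from scipy.special import gammaln

        def logp(t):
            return (gammaln(t.sum(1) + 1).sum() + gammaln(t.sum(0) + 1).sum()
                    - gammaln(t.sum() + 1) - gammaln(t + 1).sum())

        obs = logp(table)
        hits = 0
        n_mc = 20000
        for _ in range(n_mc):
            perm = rng.permutation(cols)
            t = np.zeros((3, 2), int)
            np.add.at(t, (rows, perm), 1)
            if logp(t) <= obs + 1e-7:
                hits += 1
        assert abs(p - hits / n_mc) < 0.02

    def test_smoking_fixture_is_highly_significant(self):
        t = load_printed_tables()["egfr_smoking"]
        assert fisher_exact(t) < 1e-3

    def test_budget_exceeded_directs_to_chi_square(self):
        big = np.full((6, 6), 40)
        with pytest.raises(ValueError, match="chi_square"):
            fisher_exact(big, enumeration_budget=1000)


class TestChiSquare:
    def test_hand_computed_statistic(self):
        stat, _ = chi_square_test([[10, 20], [20, 10]])
        assert stat == pytest.approx(100 / 15)

    def test_table_equal_to_expected_gives_zero(self):
        stat, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        t = np.array([[5, 9, 2], [7, 3, 8]])
        s1, _ = chi_square_test(t)
        s2, _ = chi_square_test(t[:, ::-1])
        s3, _ = chi_square_test(t[::-1])
        assert s1 == pytest.approx(s2) == pytest.approx(s3)


class TestWilcoxon:
    def test_identical_multisets_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_small_sample(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_asymptotic_close_to_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.5, 1, 6)
            exact = wilcoxon_rank_sum(x, y)
            approx = wilcoxon_rank_sum(x, y, exact_limit=0)
            assert abs(exact - approx) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestLogistic:
    def test_slope_equals_table_log_odds_ratio(self):
        # 2x2 table [[10,20],[20,10]]: log OR = log((10*10)/(20*20)) = log(0.25)
        # exposed group (x=1) has 10 cases / 20 controls, unexposed 20 / 10
        x = np.repeat([0, 0, 1, 1], [20, 10, 10, 20]).astype(float)
        y = np.repeat([1, 0, 1, 0], [20, 10, 10, 20]).astype(float)
        fit = fit_logistic(x[:, None], y, names=["x"])
        assert fit.params["x"] == pytest.approx(np.log(0.25), abs=1e-8)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.random.default_rng(0).normal(size=(20, 1)),
                         np.ones(20))

    def test_separation_flagged(self):
        x = np.linspace(-1, 1, 30)
        y = (x > 0).astype(float)
        fit = fit_logistic(x[:, None], y, names=["x"])
        assert fit.separation

    def test_parameter_recovery_coverage(self):
        rng_master = np.random.default_rng(42)
        true_beta = 0.8
        covered = 0
        for _ in range(20):
            rng = np.random.default_rng(rng_master.integers(2**31))
            x = rng.normal(size=2000)
            y = rng.random(2000) < 1 / (1 + np.exp(-(0.3 + true_beta * x)))
            fit = fit_logistic(x[:, None], y.astype(float), names=["x"])
            lo, hi = fit.conf_int("x")
            covered += lo <= true_beta <= hi
        assert covered >= 18


class TestStepwise:
    def _noise_data(self, seed=0, n=300, k=4):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, k)),
                         columns=[f"n{i}" for i in range(k)])
        y = rng.random(n) < 0.3
        return X, y.astype(float)

    def test_null_candidates_give_intercept_only(self):
        X, y = self._noise_data()
        fit = stepwise_select(X, y, entry_p=0.001)
        assert fit.variables == []

    def test_liberal_alphas_include_everything(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = (rng.random(200) < 0.4).astype(float)
        fit = stepwise_select(X, y, entry_p=1.0, stay_p=1.0)
        assert set(fit.variables) == {"a", "b", "c"}

    def test_duplicate_column_enters_once(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-2 * x))).astype(float)
        X = pd.DataFrame({"x1": x, "x2": x})
        fit = stepwise_select(X, y)
        assert len(fit.variables) == 1

    def test_strong_predictor_found_noise_rejected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = rng.normal(size=1000)
            noise = rng.normal(size=(1000, 5))
            y = (rng.random(1000) < 1 / (1 + np.exp(-(-0.5 + np.log(3) * x)))
                 ).astype(float)
            X = pd.DataFrame(np.column_stack([x, noise]),
                             columns=["strong"] + [f"n{i}" for i in range(5)])
            fit = stepwise_select(X, y)
            hits += ("strong" in fit.variables
                     and len(fit.variables) <= 2)
        assert hits >= 8


class TestOddsRescaling:
    def test_null_effect(self):
        assert rescale_odds_ratio(0.0, -10.0) == 1.0

    def test_closed_form(self):
        assert rescale_odds_ratio(0.05, -10) == pytest.approx(np.exp(-0.5))

    def test_inverse_identity(self):
        b = 0.123
        assert rescale_odds_ratio(b, -10) * rescale_odds_ratio(b, 10) == \
            pytest.approx(1.0)


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)
        thr, sens, spec = threshold_at_sensitivity(roc, 0.8)
        assert sens == 1.0 and spec == 1.0

    def test_all_ties_gives_half(self):
        roc = roc_curve([5, 5, 5, 5], [1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_pairwise_concordance_oracle(self):
        roc = roc_curve([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_auc_equals_concordance_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            scores = rng.integers(0, 6, 40).astype(float)  # ties likely
            labels = rng.random(40) < 0.4
            if labels.all() or not labels.any():
                continue
            roc = roc_curve(scores, labels)
            pos = scores[labels]
            neg = scores[~labels]
            conc = np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                            for p in pos for q in neg])
            assert roc.auc == pytest.approx(conc, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores))

    def test_lower_direction(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0],
                        direction="lower")
        assert roc.auc == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], [1, 1])


class TestThresholdAtSensitivity:
    def test_bruteforce_scan_oracle(self):
        pos = np.array([3, 2, 1, 0.5, 0.4])
        neg = np.array([2.5, 1.5, 0.6, 0.3])
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(5), np.zeros(4)])
        roc = roc_curve(scores, labels)
        thr, sens, spec = threshold_at_sensitivity(roc, 0.8)
        assert (pos >= thr).sum() >= 4
        # exhaustive scan: max specificity subject to sens >= 0.8,
        # then max sensitivity, then least strict cut
        best = max(
            ((t, (pos >= t).mean(), (neg < t).mean()) for t in np.unique(scores)),
            key=lambda r: (r[2] if r[1] >= 0.8 else -1, r[1], -r[0]),
        )
        assert (thr, sens, spec) == pytest.approx(best)

    def test_target_zero_returns_max_specificity(self):
        roc = roc_curve([1, 2, 3, 4], [0, 1, 0, 1])
        thr, sens, spec = threshold_at_sensitivity(roc, 0.0)
        assert spec == 1.0


class TestPearson:
    def test_affine(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_constant_bcg_forces_perfect_anticorrelation(self):
        # partition identity: VIRO + YP = 100 - BCG, so with BCG constant the
        # cohort correlation of VIRO and YP is exactly -1
        rng = np.random.default_rng(0)
        viro = rng.uniform(10, 80, 50)
        bcg = np.full(50, 12.0)
        yp = 100.0 - bcg - viro
        assert pearson_correlation(viro, yp) == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(5), np.arange(5.0))


class TestRecursivePartition:
    def test_perfect_split_found(self):
        X = pd.DataFrame({"a": [1, 2, 3, 10, 11, 12], "b": [0, 1, 0, 1, 0, 1]})
        y = [0, 0, 0, 1, 1, 1]
        name, cut, imp = recursive_partition_split(X, y)
        assert name == "a" and 3 < cut < 10 and imp == 0.0

    def test_constant_feature_never_beats_informative(self):
        X = pd.DataFrame({"const": np.ones(8), "x": np.arange(8.0)})
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        name, _, _ = recursive_partition_split(X, y)
        assert name == "x"

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        y = (rng.random(10) < 0.5).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        got = recursive_partition_split(X, y)

        def gini(v):
            if len(v) == 0:
                return 0.0
            p = np.mean(v)
            return 2 * p * (1 - p)

        best = (None, None, np.inf)
        for colname in X.columns:
            xv = X[colname].to_numpy()
            vals = np.unique(xv)
            for cut in (vals[:-1] + vals[1:]) / 2:
                l, r = y[xv <= cut], y[xv > cut]
                imp = (len(l) * gini(l) + len(r) * gini(r)) / len(y)
                if imp < best[2] - 1e-12:
                    best = (colname, cut, imp)
        assert got[0] == best[0]
        assert got[1] == pytest.approx(best[1])
        assert got[2] == pytest.approx(best[2])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            recursive_partition_split(pd.DataFrame({"a": [1.0, 2.0]}), [1, 1])


class TestSurvival:
    def test_no_events_flat_curve(self):
        km = km_estimator([1, 2, 3], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        km = km_estimator([1, 2, 3], [0, 1, 1])
        surv = dict(zip(km["time"], km["survival"]))
        assert surv[2.0] == pytest.approx(0.5)
        assert surv[3.0] == pytest.approx(0.0)

    def test_curve_non_increasing(self):
        rng = np.random.default_rng(0)
        km = km_estimator(rng.exponential(5, 50), rng.random(50) < 0.7)
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_cox_beta_matches_partial_likelihood_grid(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 1], bool)
        x = np.array([0.0, 1.0, 0.0, 1.0])
        res = cox_lrt(times, events, x)
        grid = np.linspace(-3, 3, 60001)
        xc = x - x.mean()
        lls = [cox_partial_loglik(b, times, events, xc) for b in grid]
        assert res["beta"][0] == pytest.approx(grid[int(np.argmax(lls))],
                                               abs=1e-4)

    def test_cox_direction_later_events_protective(self):
        times = np.array([1, 2, 3, 10, 11, 12], float)
        events = np.ones(6, bool)
        group = np.array([0, 0, 0, 1, 1, 1], float)
        assert cox_lrt(times, events, group)["hazard_ratio"] < 1.0

    def test_cox_type_one_error(self):
        rejections = 0
        master = np.random.default_rng(7)
        for _ in range(100):
            rng = np.random.default_rng(master.integers(2**31))
            t = rng.exponential(5, 200)
            e = np.ones(200, bool)
            x = rng.normal(size=200)
            rejections += cox_lrt(t, e, x)["p_value"] < 0.05
        assert rejections <= 10

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_lrt([1, 2, 3], [1, 1, 1], [1.0, 1.0, 1.0])


class TestTablePercentages:
    def test_printed_percentages_reproduced(self):
        tabs = load_printed_tables()
        egfr = table_percentages(tabs["egfr_smoking"], decimals=1)
        assert egfr.loc["never", "EGFR+"] == 53.3
        assert egfr.loc["never", "WT"] == 5.8
        kras = table_percentages(tabs["kras_smoking"], decimals=1)
        assert kras.loc["never", "KRAS+"] == 2.1
        assert kras.loc["never", "WT"] == 18.3

    def test_columns_sum_to_100(self):
        pct = table_percentages(load_printed_tables()["kras_prognosis"])
        assert np.allclose(pct.sum(axis=0), 100.0)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            table_percentages(np.array([[0, 1], [0, 2]]))
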