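"""Survival oracles, test routing, regression recovery, missingness audit."""

import numpy as np
import pandas as pd
import pytest

from pdprog import (RankDeficiencyError, compare_progression_slopes,
                    fit_progression_model, group_difference_test, km_fit,
                    logrank_test, missingness_audit, stratified_score_summary)


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_product_limit(times, observed):
    """Textbook product-limit estimator evaluated at each distinct event time."""
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    out = {}
    s = 1.0
    for t in sorted(set(times[observed])):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & observed)
        s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


def permutation_logrank_p(ta, oa, tb, ob, n_perm=4000, seed=0):
    """Monte-Carlo permutation null of the log-rank statistic."""
    stat0, _ = logrank_test(ta, oa, tb, ob)
    times = np.concatenate([ta, tb])
    obs = np.concatenate([oa, ob]).astype(bool)
    na = len(ta)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(times))
        s, _ = logrank_test(times[idx[:na]], obs[idx[:na]],
                            times[idx[na:]], obs[idx[na:]])
        hits += s >= stat0 - 1e-12
    return hits / n_perm


class TestKaplanMeier:
    def test_uncensored_closed_form(self):
        c = km_fit([1, 2, 3])
        lookup = dict(zip(c.times, c.survival))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)
        assert c.median == 2.0

    def test_censored_hand_product_limit(self):
        c = km_fit([1, 2, 3], [True, False, True])
        lookup = dict(zip(c.times, c.survival))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[3.0] == pytest.approx(0.0)
        assert c.median == 3.0

    def test_all_censored_median_not_reached(self):
        c = km_fit([2, 4, 6], [False, False, False])
        assert np.all(c.survival == 1.0)
        assert c.median is None
        assert c.median_label == "not reached (> 6)"

    def test_survival_non_increasing_from_one(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(3, 40)
        o = rng.random(40) < 0.6
        c = km_fit(t, o)
        assert c.survival[0] <= 1.0 + 1e-12
        assert np.all(np.diff(c.survival) <= 1e-12)

    def test_empty_and_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            km_fit([])
        with pytest.raises(ValueError):
            km_fit([-1.0])

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for trial in range(25):
            n = int(rng.integers(1, 51))
            t = np.round(rng.exponential(5, n), 1)  # ties on purpose
            o = rng.random(n) < 0.7
            if not o.any():
                continue
            c = km_fit(t, o)
            lookup = dict(zip(c.times, c.survival))
            for te, se in brute_force_product_limit(t, o).items():
                assert lookup[te] == pytest.approx(se), trial


class TestLogrank:
    def test_identical_groups_null(self):
        stat, p = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_hand_computed_four_risk_sets(self):
        # A events {1,2}, B events {3,4}: O_A=2, E_A=5/6, V=17/36
        stat, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert stat == pytest.approx((2 - 5 / 6) ** 2 / (17 / 36), rel=1e-6)
        assert stat == pytest.approx(2.88, abs=0.01)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_p_value_within_monte_carlo_error_of_permutation_null(self, seed):
        rng = np.random.default_rng(seed)
        ta = rng.exponential(2, 4)
        tb = rng.exponential(4, 4)
        oa = np.ones(4)
        ob = rng.random(4) < 0.8
        _, p = logrank_test(ta, oa, tb, ob)
        p_perm = permutation_logrank_p(ta, oa, tb, ob, n_perm=800, seed=seed)
        se = np.sqrt(p_perm * (1 - p_perm) / 800)
        # chi-square approximation vs exact permutation: allow 3 MC SEs + gap
        assert abs(p - p_perm) < 3 * se + 0.12


class TestGroupDifferenceRouting:
    def test_normal_unequal_variance_routes_to_welch(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        y = rng.normal(0.3, 3, 200)
        rec = group_difference_test(x, y)
        assert rec.route == "welch_t"
        assert rec.levene_p < 0.05

    def test_normal_equal_variance_routes_to_pooled_t(self):
        rng = np.random.default_rng(6)
        rec = group_difference_test(rng.normal(0, 1, 150),
                                    rng.normal(0.1, 1, 150))
        assert rec.route == "pooled_t"

    def test_lognormal_routes_to_mann_whitney(self):
        rng = np.random.default_rng(2)
        rec = group_difference_test(rng.lognormal(0, 1, 200),
                                    rng.lognormal(0.2, 1, 200))
        assert rec.route == "mann_whitney"
        assert min(rec.shapiro_p) < 0.05

    def test_identical_normal_samples_give_null_t(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5, 1, 100)
        rec = group_difference_test(x, x.copy())
        assert rec.route == "pooled_t"
        assert rec.statistic == pytest.approx(0.0, abs=1e-12)
        assert rec.p_value == pytest.approx(1.0)

    def test_routing_is_function_of_subtest_pvalues(self):
        """The route is reproducible from the recorded diagnostics alone."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(0, 1, 60) if rng.random() < 0.5 else rng.lognormal(0, 1, 60)
            y = rng.normal(0, rng.choice([1, 4]), 60)
            rec = group_difference_test(x, y)
            if min(rec.shapiro_p) < 0.05:
                assert rec.route == "mann_whitney"
            elif rec.levene_p < 0.05:
                assert rec.route == "welch_t"
            else:
                assert rec.route == "pooled_t"


class TestStratifiedSummary:
    def test_constant_scores(self):
        df = pd.DataFrame({"t": [0.2, 0.7, 1.3, 1.9], "value": [2.0] * 4})
        out = stratified_score_summary(df)
        assert (out["mean"] == 2.0).all()
        assert (out["ci_high"] - out["ci_low"] == 0).all()

    def test_empty_bins_omitted(self):
        df = pd.DataFrame({"t": [0.5, 5.5], "value": [1.0, 2.0]})
        out = stratified_score_summary(df)
        assert list(out["year_bin"]) == [0, 5]

    def test_linear_scores_have_bin_midpoint_means(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(0, 5, 20000)
        df = pd.DataFrame({"t": t, "value": t})  # slope 1, intercept 0
        out = stratified_score_summary(df, horizon_years=5)
        for row in out.itertuples(index=False):
            assert row.mean == pytest.approx(row.year_bin + 0.5, abs=0.03)

    def test_singleton_bin_has_no_ci(self):
        df = pd.DataFrame({"t": [0.5], "value": [3.0]})
        out = stratified_score_summary(df)
        assert np.isnan(out["ci_low"]).all()


class TestProgressionModel:
    def test_four_point_hand_table(self):
        df = pd.DataFrame({"t": [0, 1, 2, 3], "value": [1, 3, 5, 7]})
        fit = fit_progression_model(df, "updrs_total", covariates=())
        assert fit.slope_per_year == pytest.approx(2.0)
        assert fit.intercept_at_dx == pytest.approx(1.0)

    def test_noiseless_covariate_recovery(self):
        rng = np.random.default_rng(6)
        n = 400
        t = rng.uniform(0, 8, n)
        age = rng.normal(60.4, 10, n)
        sex = rng.choice(["M", "F"], n)
        df = pd.DataFrame({"t": t, "age_at_dx": age, "sex": sex,
                           "value": 28.7 - 0.11 * t})
        fit = fit_progression_model(df, "mmse")
        assert fit.slope_per_year == pytest.approx(-0.11, abs=1e-9)
        assert fit.intercept_at_dx == pytest.approx(28.7, abs=1e-9)
        assert fit.coefficients["age_at_dx"] == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_covariate_raises_named_error(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"t": rng.uniform(0, 5, 50),
                           "age_at_dx": rng.normal(60, 10, 50)})
        df["age_copy"] = df["age_at_dx"]
        df["value"] = 2 + df["t"]
        with pytest.raises(RankDeficiencyError) as ei:
            fit_progression_model(df, "updrs_total",
                                  covariates=("age_at_dx", "age_copy"))
        assert "age_at_dx" in str(ei.value) and "age_copy" in str(ei.value)

    def test_vif_flag_activates_on_near_collinearity(self):
        rng = np.random.default_rng(8)
        n = 300
        age = rng.normal(60, 10, n)
        near_copy = age + rng.normal(0, 0.5, n)  # VIF >> 10, full rank
        df = pd.DataFrame({"t": rng.uniform(0, 5, n), "age_at_dx": age,
                           "age2": near_copy})
        df["value"] = 20 + 2 * df["t"] + rng.normal(0, 1, n)
        fit = fit_progression_model(df, "updrs_total",
                                    covariates=("age_at_dx", "age2"))
        assert fit.vif["age_at_dx"] >= 10
        assert fit.vif_flag

    def test_low_vif_not_flagged(self):
        rng = np.random.default_rng(9)
        n = 300
        df = pd.DataFrame({"t": rng.uniform(0, 5, n),
                           "age_at_dx": rng.normal(60, 10, n),
                           "sex": rng.choice(["M", "F"], n)})
        df["value"] = 20 + 2 * df["t"] + rng.normal(0, 1, n)
        fit = fit_progression_model(df, "updrs_total")
        assert not fit.vif_flag
        assert all(v < 2 for v in fit.vif.values())

    def test_cluster_robust_errors_widen_with_repeated_measures(self):
        rng = np.random.default_rng(10)
        pid = np.repeat(np.arange(80), 6)
        re = np.repeat(rng.normal(0, 4, 80), 6)
        t = rng.uniform(0, 5, 480)
        df = pd.DataFrame({"patient_id": pid, "t": t,
                           "value": 20 + 2 * t + re + rng.normal(0, 1, 480)})
        plain = fit_progression_model(df, "updrs_total", covariates=())
        clustered = fit_progression_model(df, "updrs_total", covariates=(),
                                          cluster_col="patient_id")
        # shared random intercepts inflate the uncertainty of the mean level
        assert clustered.std_errors["const"] > plain.std_errors["const"]


class TestSlopeComparison:
    def _table(self, slope, n, seed, source, noise=1.0):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 6, n)
        return pd.DataFrame({
            "t": t, "value": 20 + slope * t + rng.normal(0, noise, n),
            "age_at_dx": rng.normal(65, 10, n),
            "sex": rng.choice(["M", "F"], n), "source": source})

    def test_identical_sources_give_zero_difference(self):
        a = self._table(2.0, 300, 1, "a")
        b = a.copy()
        b["source"] = "b"
        comp = compare_progression_slopes(pd.concat([a, b]))
        assert comp.difference == pytest.approx(0.0, abs=1e-10)
        assert comp.p_value == pytest.approx(1.0)

    def test_recovers_true_slope_contrast(self):
        a = self._table(1.54, 2000, 2, "a", noise=4.0)
        b = self._table(3.87, 2000, 3, "b", noise=4.0)
        comp = compare_progression_slopes(pd.concat([a, b]))
        assert abs(comp.difference - 2.33) < 2 * comp.std_error
        assert comp.p_value < 0.001

    def test_interaction_equals_separate_fit_delta(self):
        a = self._table(1.0, 500, 4, "a")
        b = self._table(2.5, 500, 5, "b")
        comp = compare_progression_slopes(pd.concat([a, b]), covariates=())
        assert comp.difference == pytest.approx(comp.separate_fit_difference,
                                                abs=1e-9)


class TestMissingnessAudit:
    def test_independent_labels_give_chance_auc(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(2000, 4)),
                         columns=list("abcd"))
        y = rng.integers(0, 2, 2000)
        out = missingness_audit(X, y, seed=0)
        assert out["auc"] == pytest.approx(0.5, abs=0.05)

    def test_separable_feature_gives_high_auc(self):
        rng = np.random.default_rng(12)
        y = rng.integers(0, 2, 500)
        X = pd.DataFrame({"f": y * 10.0 + rng.normal(0, 0.1, 500)})
        out = missingness_audit(X, y, seed=0)
        assert out["auc"] > 0.99

    def test_constant_labels_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            missingness_audit(X, [1, 1, 1])

    def test_weak_specialist_signal_gives_weak_auc(self, rwd_small):
        """Recording driven by a specialist flag at a mild odds ratio is only
        marginally predictable, mirroring the weak real-data signal."""
        from pdprog import CohortConfig, build_cohort
        from pdprog.pipeline import _missingness_table
        ds, truth = rwd_small
        cohort = build_cohort(ds, CohortConfig(mode="encounter"))
        feats, y = _missingness_table(ds, cohort, truth)
        out = missingness_audit(feats, y, seed=1)
        assert 0.4 < out["auc"] < 0.75
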