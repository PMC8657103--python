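import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lesionkinetics import (
    TransformSpec,
    apply_transform,
    choose_transform,
    gee_logistic,
    km_logrank,
    multivariable_model,
    roc_auc,
    univariate_screen,
)
from lesionkinetics.stats import build_transform_pool


def simulate_clustered(n_clusters, cluster_size, beta1, icc_sd, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_clusters * cluster_size)
    u = np.repeat(rng.normal(0, icc_sd, n_clusters), cluster_size)
    p = 1 / (1 + np.exp(-(-0.5 + beta1 * x + u)))
    y = (rng.random(x.size) < p).astype(int)
    cluster = np.repeat(np.arange(n_clusters), cluster_size)
    return y, x, cluster


class TestChooseTransform:
    def test_symmetric_sample_identity(self):
        rng = np.random.default_rng(0)
        spec = choose_transform(rng.normal(50, 5, 500), "f")
        assert spec.transform == "identity"

    def test_lognormal_sample_log_brute_force(self):
        rng = np.random.default_rng(1)
        v = np.exp(rng.normal(0, 1, 500))
        spec = choose_transform(v, "f")
        assert spec.transform == "log"
        # brute-force: log must minimize |skewness| among all candidates
        skews = {}
        for t, pre in (("identity", 1.0), ("log", 1.0), ("sqrt", 1.0), ("cbrt", 1.0)):
            skews[t] = abs(sps.skew(apply_transform(v, TransformSpec("f", t, pre))))
        assert skews["log"] == min(skews.values())

    def test_negative_values_force_cube(self):
        spec = choose_transform([1.0, -3.0, 2.0, 5.0], "f")
        assert spec.transform == "cube"

    def test_unit_interval_feature_prescaled_before_log(self):
        rng = np.random.default_rng(2)
        v = np.exp(rng.normal(-3, 1, 500))
        v = v / (v.max() * 1.01)  # bounded in (0, 1)
        spec = choose_transform(v, "uniformity")
        if spec.transform == "log":
            assert spec.pre_scale == 1000.0
            assert "1000" in spec.label

    def test_constant_feature_identity_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            spec = choose_transform([2.0, 2.0, 2.0, 2.0], "f")
        assert spec.transform == "identity"

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            choose_transform([1.0, 2.0], "f")

    def test_log_on_nonpositive_errors(self):
        with pytest.raises(ValueError):
            apply_transform([1.0, 0.0], TransformSpec("f", "log"))

    def test_build_pool_adds_transformed_variants(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": np.exp(rng.normal(0, 1, 300)), "b": rng.normal(0, 1, 300)})
        pool, prov = build_transform_pool(df)
        assert set(df.columns) <= set(pool.columns)
        assert all(lbl in pool.columns for lbl in prov)


class TestGEE:
    def test_cluster_size_one_equals_logistic_mle(self):
        import statsmodels.api as sm

        y, x, _ = simulate_clustered(300, 1, 1.0, 0.0, 0)
        fit = gee_logistic(y, x[:, None], np.arange(300), names=["x"])
        mle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert np.allclose(fit.params.to_numpy(), mle.params, atol=1e-6)

    def test_independence_reduces_to_logistic(self):
        import statsmodels.api as sm

        y, x, cluster = simulate_clustered(100, 4, 0.8, 0.8, 1)
        fit = gee_logistic(y, x[:, None], cluster, names=["x"], cov_struct="independence")
        mle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert np.allclose(fit.params.to_numpy(), mle.params, atol=1e-5)

    def test_ci_brackets_or(self):
        y, x, cluster = simulate_clustered(100, 3, 0.8, 0.5, 2)
        fit = gee_logistic(y, x[:, None], cluster, names=["x"])
        assert fit.converged
        for term in fit.params.index:
            assert fit.or_ci.loc[term, "lower"] <= fit.odds_ratios[term] <= fit.or_ci.loc[term, "upper"]
            assert 0 <= fit.p_values[term] <= 1

    def test_positive_working_correlation_recovered(self):
        y, x, cluster = simulate_clustered(300, 4, 0.0, 1.5, 3)
        fit = gee_logistic(y, x[:, None], cluster, names=["x"])
        assert fit.working_correlation > 0.05

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError, match="clusters"):
            gee_logistic([0, 1], [[1.0], [2.0]], ["a", "a"], names=["x"])

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="constant"):
            gee_logistic([0, 1, 0, 1], [[1.0]] * 4, [0, 0, 1, 1], names=["x"])

    def test_separation_flagged_not_raised(self):
        x = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        y = (x > 0).astype(int)
        fit = gee_logistic(y, x[:, None], np.arange(6), names=["x"])
        # either flagged as non-converged or yields a finite (huge-SE) fit
        assert isinstance(fit.converged, bool)


class TestUnivariateScreen:
    def test_generating_score_selected_noise_mostly_not(self):
        y, x, cluster = simulate_clustered(150, 3, 1.5, 0.5, 4)
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"signal": x, "noise": rng.standard_normal(x.size)})
        selected = univariate_screen(df, y, cluster, alpha=0.1)
        assert "signal" in selected

    def test_threshold_is_strict(self):
        y, x, cluster = simulate_clustered(100, 3, 0.3, 0.5, 6)
        df = pd.DataFrame({"x": x})
        fit = gee_logistic(y, x[:, None], cluster, names=["x"])
        p = fit.term_p("x")
        # with alpha exactly equal to the feature's p-value it must NOT pass
        assert univariate_screen(df, y, cluster, alpha=p) == []
        assert univariate_screen(df, y, cluster, alpha=np.nextafter(p, 1)) == ["x"]

    def test_all_missing_feature_skipped_with_warning(self):
        y, x, cluster = simulate_clustered(50, 2, 1.0, 0.0, 7)
        df = pd.DataFrame({"x": x, "empty": np.nan})
        with pytest.warns(UserWarning, match="empty"):
            selected = univariate_screen(df, y, cluster)
        assert "empty" not in selected


class TestMultivariableModel:
    def test_strong_feature_survives_with_auc(self):
        y, x, cluster = simulate_clustered(200, 3, 1.5, 0.5, 8)
        df = pd.DataFrame({"x": x})
        fit, roc = multivariable_model(df, y, cluster)
        assert "x" in fit.params.index
        assert roc.auc > 0.6

    def test_redundant_duplicate_eliminated(self):
        y, x, cluster = simulate_clustered(200, 3, 1.5, 0.5, 9)
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"x1": x, "x2": x + 0.01 * rng.standard_normal(x.size)})
        fit, _ = multivariable_model(df, y, cluster)
        terms = [t for t in fit.params.index if t != "intercept"]
        assert len(terms) == 1

    def test_pure_noise_gives_intercept_only(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 300)
        df = pd.DataFrame({"n1": rng.standard_normal(300), "n2": rng.standard_normal(300)})
        fit, roc = multivariable_model(df, y, np.arange(300))
        terms = [t for t in fit.params.index if t != "intercept"]
        if not terms:
            assert roc.auc == 0.5


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_concordant_pair_counting(self):
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_all_ties(self):
        r = roc_auc([5.0] * 8, [0, 1] * 4)
        assert r.auc == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 1 / (1 + np.exp(-scores))).astype(int)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores), labels)
        assert a.auc == pytest.approx(b.auc)

    def test_one_class_absent_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_delong_ci_sane(self):
        rng = np.random.default_rng(13)
        scores = np.concatenate([rng.normal(0, 1, 100), rng.normal(1, 1, 100)])
        labels = np.array([0] * 100 + [1] * 100)
        r = roc_auc(scores, labels)
        assert 0 <= r.ci_95[0] <= r.auc <= r.ci_95[1] <= 1
        assert r.n_pos == r.n_neg == 100


def naive_km(times, events):
    """Brute-force risk-set tabulation of the product-limit estimator."""
    out = []
    s = 1.0
    for t in sorted(set(times)):
        at_risk = sum(1 for ti in times if ti >= t)
        deaths = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        if deaths:
            s *= 1 - deaths / at_risk
        out.append((t, s))
    return out


def naive_logrank(times, events, groups):
    """Direct observed-minus-expected tabulation, 1 df."""
    o_minus_e = 0.0
    var = 0.0
    labels = sorted(set(groups))
    for t in sorted({ti for ti, ei in zip(times, events) if ei == 1}):
        n = sum(1 for ti in times if ti >= t)
        n1 = sum(1 for ti, g in zip(times, groups) if ti >= t and g == labels[0])
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        d1 = sum(
            1 for ti, ei, g in zip(times, events, groups)
            if ti == t and ei == 1 and g == labels[0]
        )
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, float(sps.chi2.sf(chi2, 1))


class TestSurvival:
    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(14)
        times = np.concatenate([rng.exponential(100, 40), rng.exponential(200, 40)])
        groups = ["a"] * 40 + ["b"] * 40
        curves, _ = km_logrank(times, np.ones(80, dtype=int), groups)
        for lab, sel in (("a", slice(0, 40)), ("b", slice(40, 80))):
            sub = np.sort(times[sel])
            curve = curves[lab]
            for t, s in zip(curve.times[1:], curve.survival[1:]):
                emp = np.mean(sub > t)
                assert s == pytest.approx(emp, abs=1e-12)

    def test_identical_groups_chi2_zero(self):
        times = [50, 80, 120, 200, 310, 400]
        events = [1, 1, 0, 1, 1, 0]
        _, lr = km_logrank(times + times, events + events, ["a"] * 6 + ["b"] * 6)
        assert lr.chi_square == pytest.approx(0.0, abs=1e-10)
        assert lr.p_value == pytest.approx(1.0)

    def test_six_subject_hand_oracle(self):
        times = [30.0, 60.0, 60.0, 90.0, 150.0, 200.0]
        events = [1, 1, 0, 1, 0, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        curves, lr = km_logrank(times, events, groups)
        for lab in ("a", "b"):
            sel = [i for i, g in enumerate(groups) if g == lab]
            oracle = naive_km([times[i] for i in sel], [events[i] for i in sel])
            curve = curves[lab]
            for t, s in oracle:
                assert curve.survival_at(t) == pytest.approx(s, abs=1e-12)
        chi2, p = naive_logrank(times, events, groups)
        assert lr.chi_square == pytest.approx(chi2, rel=1e-9)
        assert lr.p_value == pytest.approx(p, rel=1e-9)

    def test_curves_are_nonincreasing_in_unit_interval(self):
        rng = np.random.default_rng(15)
        times = rng.exponential(100, 60)
        events = (rng.random(60) < 0.7).astype(int)
        groups = ["a"] * 30 + ["b"] * 30
        curves, _ = km_logrank(times, events, groups)
        for curve in curves.values():
            assert curve.survival_at(0) == 1.0
            assert np.all(np.diff(curve.survival) <= 1e-12)
            assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_zero_events_errors(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])

    def test_one_group_errors(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3], [1, 1, 1], ["a", "a", "a"])
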