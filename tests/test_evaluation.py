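"""PSIS, generalized Pareto tail fitting, ROC/PRC curves, model comparison."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabwork.evaluation import (
    LooResult,
    ModelEvaluation,
    compare_models,
    fit_gpd_tail,
    loo_predictive,
    pr_curve,
    psis_smooth,
    roc_curve,
)


class TestGpdTail:
    def test_recovers_known_shape(self):
        from scipy.stats import genpareto

        x = genpareto.rvs(0.3, scale=1.0, size=10_000, random_state=1)
        k, sigma = fit_gpd_tail(x)
        assert abs(k - 0.3) < 0.05
        assert sigma > 0

    def test_exponential_is_near_zero_shape(self):
        x = np.random.default_rng(2).exponential(size=10_000)
        k, _ = fit_gpd_tail(x)
        assert abs(k) < 0.05

    def test_constant_exceedances_hit_boundary_without_crash(self):
        k, sigma = fit_gpd_tail(np.full(100, 2.5))
        assert np.isfinite(k)

    def test_too_few_values_is_not_applicable(self):
        k, sigma = fit_gpd_tail(np.array([1.0, 2.0, 3.0]))
        assert np.isnan(k) and np.isnan(sigma)


class TestPsisSmooth:
    def test_equal_weights_pass_through(self):
        w, khat = psis_smooth(np.zeros(1000))
        np.testing.assert_allclose(w, 1.0 / 1000)

    def test_matches_reference_implementation(self):
        import arviz as az

        rng = np.random.default_rng(3)
        for scale in (0.3, 1.0, 3.0):
            lw = rng.normal(0.0, scale, size=2000)
            w, khat = psis_smooth(lw)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lw_ref, k_ref = az.psislw(lw.copy())
            np.testing.assert_allclose(w, np.exp(lw_ref), atol=1e-12)
            assert khat == pytest.approx(float(k_ref), abs=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(0.1, 4.0))
    def test_contract_normalized_and_capped(self, seed, scale):
        lw = np.random.default_rng(seed).normal(0.0, scale, size=400)
        w, _ = psis_smooth(lw)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        raw = np.exp(lw - lw.max())
        assert w.max() <= raw.max() / raw.sum() * w.sum() * (raw.sum()) + 1e-12
        assert (w >= 0).all()

    def test_small_sample_falls_back_to_truncation(self):
        with pytest.warns(UserWarning, match="truncated"):
            w, khat = psis_smooth(np.random.default_rng(0).normal(size=10))
        assert np.isnan(khat)
        assert w.sum() == pytest.approx(1.0)

    def test_smoothing_reduces_estimator_variance_on_heavy_tails(self):
        """Importance-sampling self-normalized mean of a test function under
        heavy-tailed weights: smoothed beats raw in replicate variance."""
        rng = np.random.default_rng(4)
        raw_est, smooth_est = [], []
        for _ in range(200):
            lw = rng.standard_t(df=2, size=800)  # heavy-tailed log-weights
            h = rng.normal(size=800)
            w_raw = np.exp(lw - lw.max())
            w_raw /= w_raw.sum()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w_s, _ = psis_smooth(lw)
            raw_est.append(w_raw @ h)
            smooth_est.append(w_s @ h)
        assert np.var(smooth_est) < np.var(raw_est)

    def test_nonfinite_weights_rejected(self):
        lw = np.zeros(100)
        lw[3] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            psis_smooth(lw)


class TestLooPredictive:
    def test_single_draw_degenerates_to_that_draw(self):
        loglik = np.log(np.array([[0.2, 0.7, 0.9]]))
        pred = np.array([[0.8, 0.7, 0.9]])
        res = loo_predictive(loglik, pred)
        np.testing.assert_allclose(res.p_hat, pred[0])
        np.testing.assert_allclose(res.elpd_i, loglik[0])

    def test_pointwise_elpd_is_nonpositive_for_probabilities(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.95, size=(600, 40))
        y = rng.binomial(1, 0.3, size=40)
        loglik = np.where(y[None, :] == 1, np.log(p), np.log1p(-p))
        res = loo_predictive(loglik, p)
        assert (res.elpd_i <= 0).all()
        assert ((res.p_hat > 0) & (res.p_hat < 1)).all()
        assert res.se >= 0

    def test_shape_mismatch_and_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            loo_predictive(np.zeros((10, 4)), np.zeros((10, 5)))
        ll = np.zeros((30, 4))
        ll[0, 0] = -np.inf
        with pytest.raises(ValueError, match="non-finite"):
            loo_predictive(ll, np.full((30, 4), 0.5))


class TestRocCurve:
    def test_perfect_separation_gives_unit_area(self):
        y = np.array([0, 0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        curve = roc_curve(p, y)
        assert curve.auc == pytest.approx(1.0)
        assert tuple(curve.points[0]) == (0.0, 0.0)
        assert tuple(curve.points[-1]) == (1.0, 1.0)

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(6)
        y = rng.binomial(1, 0.3, size=4000)
        p = rng.uniform(size=4000)
        assert abs(roc_curve(p, y).auc - 0.5) < 0.03

    def test_equals_mann_whitney_exactly(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(10, 60)
            y = rng.binomial(1, 0.4, size=n)
            if y.sum() in (0, n):
                continue
            # coarse scores to force ties
            p = rng.integers(0, 6, size=n) / 5.0
            ranks = rankdata(p)
            n1, n0 = y.sum(), n - y.sum()
            u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
            assert roc_curve(p, y).auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        for _ in range(20):
            y = rng.binomial(1, 0.35, size=200)
            p = rng.uniform(size=200)
            assert roc_curve(p, y).auc == pytest.approx(
                roc_auc_score(y, p), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.binomial(1, 0.4, size=300)
        p = rng.uniform(size=300)
        a = roc_curve(p, y).auc
        assert roc_curve(np.exp(3 * p), y).auc == pytest.approx(a, abs=1e-12)
        assert roc_curve(np.log(p + 1e-9), y).auc == pytest.approx(a, abs=1e-12)

    def test_points_monotone_nondecreasing(self):
        rng = np.random.default_rng(10)
        y = rng.binomial(1, 0.4, size=150)
        p = rng.integers(0, 10, size=150) / 10.0
        curve = roc_curve(p, y)
        assert (np.diff(curve.points[:, 0]) >= -1e-12).all()
        assert (np.diff(curve.points[:, 1]) >= -1e-12).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.array([0.4, 0.6]), np.array([1, 1]))


class TestPrCurve:
    def test_perfect_classifier_unit_area(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        assert pr_curve(p, y).auc == pytest.approx(1.0)

    def test_uninformative_scores_near_prevalence(self):
        rng = np.random.default_rng(11)
        y = rng.binomial(1, 0.25, size=5000)
        p = rng.uniform(size=5000)
        curve = pr_curve(p, y)
        assert curve.baseline == pytest.approx(y.mean())
        assert abs(curve.auc - y.mean()) < 0.04

    def test_five_point_hand_example(self):
        # scores descending: y = 1, 0, 1, 1, 0
        y = np.array([1, 0, 1, 1, 0])
        p = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        curve = pr_curve(p, y)
        np.testing.assert_allclose(curve.points[:, 0], [1 / 3, 1 / 3, 2 / 3, 1.0, 1.0])
        np.testing.assert_allclose(curve.points[:, 1], [1.0, 0.5, 2 / 3, 0.75, 0.6])
        expected_auc = (1 / 3) * 1.0 + (1 / 3) * (2 / 3) + (1 / 3) * 0.75
        assert curve.auc == pytest.approx(expected_auc)

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(12)
        for _ in range(20):
            y = rng.binomial(1, 0.3, size=150)
            if y.sum() == 0:
                continue
            p = rng.uniform(size=150)
            assert pr_curve(p, y).auc == pytest.approx(
                average_precision_score(y, p), abs=1e-12
            )

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve(np.array([0.4, 0.6]), np.array([0, 0]))


def _fake_eval(name, y, p_hat, covariate_set="full"):
    loo = LooResult(
        elpd_i=np.log(np.where(y == 1, p_hat, 1 - p_hat)),
        p_hat=p_hat,
        khat=np.zeros(len(y)),
        elpd_loo=float(np.log(np.where(y == 1, p_hat, 1 - p_hat)).sum()),
        se=1.0,
        n_high_khat=0,
    )
    return ModelEvaluation(
        name=name,
        covariate_set=covariate_set,
        loo=loo,
        roc=roc_curve(p_hat, y),
        prc=pr_curve(p_hat, y),
        y=y,
    )


class TestCompareModels:
    def test_identical_predictions_identical_rows(self):
        rng = np.random.default_rng(13)
        y = rng.binomial(1, 0.4, size=100)
        p = np.clip(rng.uniform(size=100), 0.05, 0.95)
        table = compare_models([_fake_eval("a", y, p), _fake_eval("b", y, p)])
        metrics = table[["elpd_loo", "auroc", "auprc"]]
        assert (metrics.iloc[0] == metrics.iloc[1]).all()

    def test_ranked_by_auroc(self):
        rng = np.random.default_rng(14)
        y = rng.binomial(1, 0.4, size=400)
        good = np.clip(0.6 * y + 0.2 + 0.1 * rng.uniform(size=400), 0.01, 0.99)
        bad = np.clip(rng.uniform(size=400), 0.01, 0.99)
        table = compare_models([_fake_eval("bad", y, bad), _fake_eval("good", y, good)])
        assert table.iloc[0]["model"] == "good"

    def test_mismatched_observations_rejected(self):
        rng = np.random.default_rng(15)
        y1 = rng.binomial(1, 0.4, size=100)
        y2 = rng.binomial(1, 0.4, size=101)
        p1 = np.full(100, 0.4)
        p2 = np.full(101, 0.4)
        y1[0], y2[0] = 0, 1  # ensure both classes
        y1[1], y2[1] = 1, 0
        with pytest.raises(ValueError, match="different observation set"):
            compare_models([_fake_eval("a", y1, p1), _fake_eval("b", y2, p2)])

    def test_curve_save_roundtrip(self, tmp_path):
        rng = np.random.default_rng(16)
        y = rng.binomial(1, 0.4, size=60)
        p = np.clip(rng.uniform(size=60), 0.05, 0.95)
        ev = _fake_eval("m", y, p)
        ev.save(tmp_path / "eval")
        import json
        import pandas as pd

        summary = json.loads((tmp_path / "eval" / "summary.json").read_text())
        assert summary["auroc"] == pytest.approx(ev.roc.auc)
        roc_df = pd.read_csv(tmp_path / "eval" / "roc.csv")
        np.testing.assert_allclose(roc_df.to_numpy(), ev.roc.points)
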