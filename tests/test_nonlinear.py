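"""Piecewise GLM (additive decomposition) and Bayesian neural network."""

import warnings

import numpy as np
import pytest
from scipy.special import expit

from conftest import make_design
from fabwork.models.bnn import BayesianNeuralNet, BnnSpec, width_scan
from fabwork.models.logistic import (
    LogisticModelSpec,
    Posterior,
    SteadyWorkLogistic,
    _GlmDensity,
)
from fabwork.models.piecewise import (
    PartitionSpec,
    PiecewiseLogistic,
    PiecewiseModelSpec,
    PiecewiseResults,
    _PiecewiseDensity,
    effective_coefficients,
)

QUIET_PW = PiecewiseModelSpec(
    draws=150, warmup=150, chains=1, year_intercepts=False, fixed_shrinkage=1.5
)


def toy_piecewise(design, partition, draws_dict, spec=QUIET_PW):
    model = PiecewiseLogistic(design, partition, spec)
    posterior = Posterior(
        draws=draws_dict,
        chains=1,
        seed=0,
        diagnostics={"algorithm": "manual", "converged": True},
        column_names=design.column_names,
        imp_col_names=[],
    )
    return PiecewiseResults(model, posterior)


class TestPiecewiseDegenerateLimits:
    def test_zero_deviation_scale_is_exactly_the_logistic_density(self, small_design):
        """With the deviation prior scale fixed at 0 the decomposition drops
        out and the joint density equals the plain logistic density."""
        spec = PiecewiseModelSpec(
            draws=100, warmup=100, chains=1, deviation_scale=0.0
        )
        part = PartitionSpec(covariates=("baseline_working",))
        pw = _PiecewiseDensity(small_design, part, spec)
        glm = _GlmDensity(small_design, LogisticModelSpec(**{
            k: v for k, v in spec.model_dump().items()
            if k in LogisticModelSpec.model_fields
        }))
        assert pw.layout.dim == glm.layout.dim
        rng = np.random.default_rng(0)
        for _ in range(5):
            theta = pw.initial_point() + 0.2 * rng.normal(size=pw.layout.dim)
            v1, g1 = pw(theta)
            v2, g2 = glm(theta)
            assert v1 == pytest.approx(v2, rel=1e-12)
            np.testing.assert_allclose(g1, g2, rtol=1e-10)

    def test_single_cell_partition_is_exactly_the_logistic_density(self, small_design):
        """A partition covariate with one level contributes no deviations."""
        from dataclasses import replace

        Z = small_design.Z.copy()
        j = small_design.column_index("vehicle_access")
        Z[:, j] = 1.0  # constant column -> single level
        design = replace(small_design, Z=Z)
        spec = PiecewiseModelSpec(draws=100, warmup=100, chains=1)
        pw = _PiecewiseDensity(design, PartitionSpec(covariates=("vehicle_access",)), spec)
        assert not pw.dims  # no active partition dimensions
        glm = _GlmDensity(design, LogisticModelSpec(**{
            k: v for k, v in spec.model_dump().items()
            if k in LogisticModelSpec.model_fields
        }))
        theta = pw.initial_point() + 0.1 * np.random.default_rng(1).normal(
            size=pw.layout.dim
        )
        assert pw(theta)[0] == pytest.approx(glm(theta)[0], rel=1e-12)

    def test_masked_partition_covariate_rejected(self, small_design):
        masked_col = next(
            c.name
            for j, c in enumerate(small_design.columns)
            if not small_design.mask[:, j].all()
        )
        with pytest.raises(ValueError, match="fully observed"):
            PiecewiseLogistic(
                small_design, PartitionSpec(covariates=(masked_col,)), QUIET_PW
            )


class TestPiecewiseGradientAndFit:
    def test_gradient_matches_finite_differences(self, small_design):
        spec = PiecewiseModelSpec(draws=100, warmup=100, chains=1)
        part = PartitionSpec(covariates=("baseline_working", "fab_comm_cog_baseline"))
        dens = _PiecewiseDensity(small_design, part, spec)
        rng = np.random.default_rng(4)
        theta = dens.initial_point() + 0.1 * rng.normal(size=dens.layout.dim)
        _, grad = dens(theta)
        for i in rng.choice(dens.layout.dim, 40, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += 1e-6
            tm[i] -= 1e-6
            fd = (dens(tp)[0] - dens(tm)[0]) / 2e-6
            assert abs(fd - grad[i]) / (1 + abs(fd)) < 1e-5

    def test_slope_change_sign_recovery(self):
        """A slope flip across a binary region is recovered with the right
        sign in most replicates."""
        hits = 0
        reps = 6
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            n = 500
            g = rng.binomial(1, 0.5, size=n).astype(float)
            x = rng.normal(size=n)
            eta = -1.0 + np.where(g == 1, 1.2, -1.2) * x
            y = rng.binomial(1, expit(eta))
            design = make_design(np.column_stack([g, x]), y)
            part = PartitionSpec(covariates=("x0",))
            spec = PiecewiseModelSpec(
                draws=150, warmup=150, chains=1, year_intercepts=False,
                fixed_shrinkage=1.5,
            )
            res = PiecewiseLogistic(design, part, spec).fit(seed=rep)
            delta = res.posterior.draws["delta_0"]  # (S, 2 levels, p+1)
            # slope deviation on x (column index 2 = 1 + design col 1)
            gap = delta[:, 1, 2].mean() - delta[:, 0, 2].mean()
            hits += gap > 0
        assert hits >= reps - 1

    def test_fit_reduces_to_logistic_predictions_when_deviations_off(self, small_design):
        spec_off = PiecewiseModelSpec(
            draws=150, warmup=150, chains=2, deviation_scale=0.0
        )
        part = PartitionSpec(covariates=("baseline_working",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pw = PiecewiseLogistic(small_design, part, spec_off).fit(seed=2)
            glm = SteadyWorkLogistic(
                small_design, LogisticModelSpec(draws=150, warmup=150, chains=2)
            ).fit(seed=2)
        p1, p2 = pw.predict_prob(), glm.predict_prob()
        assert np.corrcoef(p1, p2)[0, 1] > 0.98
        assert np.abs(p1 - p2).max() < 0.06


class TestEffectiveCoefficients:
    def _design_two_cells(self):
        rng = np.random.default_rng(3)
        n = 40
        g = np.repeat([0.0, 1.0], n // 2)
        x = rng.normal(size=n)
        y = rng.binomial(1, 0.4, size=n)
        return make_design(np.column_stack([g, x]), y)

    def test_zero_deltas_equal_global(self):
        design = self._design_two_cells()
        part = PartitionSpec(covariates=("x0",))
        S = 60
        rng = np.random.default_rng(0)
        beta = rng.normal(size=(S, 2))
        draws = {
            "alpha": np.zeros(S),
            "beta": beta,
            "delta_0": np.zeros((S, 2, 3)),
        }
        res = toy_piecewise(design, part, draws)
        eff = effective_coefficients(res)
        assert set(eff) == {(0,), (1,)}
        for table in (eff[(0,)].table, eff[(1,)].table):
            global_or = np.exp(beta).mean(axis=0)
            by_name = table.set_index("name").or_mean
            assert by_name["x0"] == pytest.approx(global_or[0])
            assert by_name["x1"] == pytest.approx(global_or[1])

    def test_two_cell_hand_arithmetic(self):
        design = self._design_two_cells()
        part = PartitionSpec(covariates=("x0",))
        S = 2
        beta = np.array([[0.0, np.log(2.0)], [0.0, np.log(2.0)]])
        delta = np.zeros((S, 2, 3))
        delta[:, 1, 2] = np.log(3.0)  # slope deviation on x1 in cell 1
        res = toy_piecewise(
            design, part, {"alpha": np.zeros(S), "beta": beta, "delta_0": delta}
        )
        eff = effective_coefficients(res)
        or0 = eff[(0,)].table.set_index("name").or_mean
        or1 = eff[(1,)].table.set_index("name").or_mean
        assert or0["x1"] == pytest.approx(2.0)
        assert or1["x1"] == pytest.approx(6.0)  # exp(log2 + log3)
        assert or0["x0"] == or1["x0"] == pytest.approx(1.0)


class TestBnn:
    def test_gradient_matches_finite_differences(self, small_design):
        from fabwork.models.bnn import _BnnDensity

        dens = _BnnDensity(small_design, BnnSpec(hidden=3))
        rng = np.random.default_rng(6)
        theta = 0.2 * rng.normal(size=dens.layout.dim)
        _, grad = dens(theta)
        for i in rng.choice(dens.layout.dim, 40, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += 1e-6
            tm[i] -= 1e-6
            fd = (dens(tp)[0] - dens(tm)[0]) / 2e-6
            assert abs(fd - grad[i]) / (1 + abs(fd)) < 1e-5

    def test_zero_weight_draws_predict_half(self):
        n = 12
        design = make_design(np.random.default_rng(0).normal(size=(n, 2)),
                             np.tile([0, 1], 6))
        model = BayesianNeuralNet(design, BnnSpec(hidden=2, draws=100))
        from fabwork.models.logistic import Posterior

        S, H, p = 100, 2, 2
        posterior = Posterior(
            draws={
                "W1": np.zeros((S, H, p)),
                "b1": np.zeros((S, H)),
                "w2": np.zeros((S, H)),
                "b2": np.zeros(S),
                "alpha": np.zeros(S),
            },
            chains=1, seed=0, diagnostics={}, column_names=design.column_names,
            imp_col_names=[],
        )
        from fabwork.models.bnn import BnnResults

        res = BnnResults(model, posterior)
        np.testing.assert_allclose(res.predict_prob(), 0.5)

    def test_width_one_approximates_logistic_on_linear_data(self):
        from fabwork.evaluation import roc_curve

        rng = np.random.default_rng(7)
        n, p = 600, 4
        Z = rng.normal(size=(n, p))
        beta = np.array([1.0, -0.7, 0.5, 0.0])
        y = rng.binomial(1, expit(Z @ beta - 1.0))
        design = make_design(Z, y)
        glm = SteadyWorkLogistic(
            design,
            LogisticModelSpec(
                draws=200, warmup=200, chains=2, year_intercepts=False
            ),
        ).fit(seed=1)
        bnn = BayesianNeuralNet(
            design, BnnSpec(hidden=1, vi_steps=4000, restarts=3, draws=200)
        ).fit(seed=1)
        a_glm = roc_curve(glm.predict_prob(), y).auc
        a_bnn = roc_curve(bnn.predict_prob(), y).auc
        assert abs(a_glm - a_bnn) < 0.02

    def test_bnn_beats_logistic_on_xor_structure(self):
        from fabwork.evaluation import roc_curve

        rng = np.random.default_rng(1)
        n = 600
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = rng.binomial(1, expit(2.0 * np.sign(x1 * x2)))
        design = make_design(np.column_stack([x1, x2]), y)
        bnn = BayesianNeuralNet(
            design, BnnSpec(hidden=8, vi_steps=3000, restarts=3, draws=200)
        ).fit(seed=2)
        glm = SteadyWorkLogistic(
            design,
            LogisticModelSpec(
                draws=200, warmup=200, chains=2, year_intercepts=False
            ),
        ).fit(seed=2)
        auroc_bnn = roc_curve(bnn.loo().p_hat, y).auc
        auroc_glm = roc_curve(glm.loo().p_hat, y).auc
        assert auroc_bnn > auroc_glm + 0.1

    def test_fit_is_seed_deterministic(self, small_design):
        spec = BnnSpec(hidden=2, vi_steps=300, restarts=1, draws=100)
        a = BayesianNeuralNet(small_design, spec).fit(seed=5)
        b = BayesianNeuralNet(small_design, spec).fit(seed=5)
        np.testing.assert_array_equal(
            a.posterior.draws["W1"], b.posterior.draws["W1"]
        )


class TestWidthScan:
    def test_single_width_single_row(self, small_design):
        spec = BnnSpec(hidden=4, vi_steps=300, restarts=1, draws=100)
        table = width_scan(small_design, spec, seed=0, widths=[4])
        assert len(table) == 1
        assert table.attrs["selected"] == 4

    def test_linear_truth_shows_no_width_gain(self):
        rng = np.random.default_rng(9)
        n = 400
        Z = rng.normal(size=(n, 3))
        y = rng.binomial(1, expit(Z @ np.array([0.8, -0.6, 0.0]) - 0.8))
        design = make_design(Z, y)
        spec = BnnSpec(vi_steps=1500, restarts=2, draws=150)
        table = width_scan(design, spec, seed=3, widths=[2, 12])
        table = table.set_index("hidden")
        gain = table.loc[12, "elpd_loo"] - table.loc[2, "elpd_loo"]
        assert gain < 2 * table.loc[2, "elpd_se"]
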