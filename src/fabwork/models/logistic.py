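"""Bayesian hierarchical logistic regression with marginalized imputation.

The model for post-baseline person-year observations (i, t):

    y_it ~ Bernoulli(logit^-1(alpha + u_t + z_it' beta))
    beta_j ~ Normal(0, lambda),        lambda ~ HalfNormal(s_lambda)
    u_t    ~ Normal(0, tau),           tau    ~ HalfNormal(s_tau)
    alpha  ~ Normal(0, s_alpha)

Missing standardized covariate cells are latent, z_miss ~ Normal(mu_col,
sigma_col), with the per-column hyperparameters learned from the observed
cells of the same column; the latents are marginalized exactly during
inference (see :mod:`fabwork.models.likelihood`) and reconstructed per draw
for pointwise log-likelihoods and predictions.

Usage follows the model/results convention::

    model = SteadyWorkLogistic(design, spec)
    res = model.fit(seed=7)
    res.summary(); res.odds_ratios().top(32); res.loo()
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from ..prep import DesignMatrix
from .hmc import find_map, fit_vi, hmc_sample
from .likelihood import (
    bernoulli_gh,
    gauss_hermite,
    half_normal_logpdf_via_log,
    log_sigmoid,
    sample_delta_conditional,
)


class LogisticModelSpec(BaseModel):
    """Priors, hierarchy switches and inference settings."""

    model_config = ConfigDict(frozen=True)

    intercept_scale: float = Field(default=2.5, gt=0)
    shrinkage_scale: float = Field(default=1.0, gt=0)
    fixed_shrinkage: Optional[float] = None  # fixes lambda; None = learned
    year_intercepts: bool = True
    tau_scale: float = Field(default=1.0, gt=0)
    imputation: Literal["learned", "fixed"] = "learned"
    fixed_imputation: tuple[float, float] = (0.0, 1.0)
    mu_prior_scale: float = Field(default=1.0, gt=0)
    sigma_prior_scale: float = Field(default=2.0, gt=0)
    algorithm: Literal["hmc", "vi"] = "hmc"
    draws: int = Field(default=1000, ge=25)
    warmup: int = Field(default=1000, ge=10)
    chains: int = Field(default=4, ge=1)
    max_leapfrog: int = Field(default=20, ge=1)
    target_accept: float = Field(default=0.8, gt=0, lt=1)
    gh_points: int = Field(default=15, ge=3)
    vi_steps: int = Field(default=4000, ge=100)

    @model_validator(mode="after")
    def _enough_draws(self):
        if self.draws * self.chains < 100:
            raise ValueError("draws x chains must be >= 100 for reporting")
        return self


class _Layout:
    """Flat parameter-vector bookkeeping."""

    def __init__(self):
        self.slices: dict[str, slice] = {}
        self.dim = 0

    def add(self, name: str, size: int) -> None:
        self.slices[name] = slice(self.dim, self.dim + size)
        self.dim += size

    def get(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[self.slices[name]]

    def __contains__(self, name: str) -> bool:
        return name in self.slices


class _GlmDensity:
    """Joint log-density and gradient of the marginalized logistic model."""

    def __init__(self, design: DesignMatrix, spec: LogisticModelSpec):
        self.spec = spec
        self.y = design.y.astype(float)
        self.Z0 = np.where(design.mask, design.Z, 0.0)
        self.N, self.p = self.Z0.shape
        self.years = np.unique(design.year)
        self.T = len(self.years)
        self.year_idx = np.searchsorted(self.years, design.year)

        missing = ~design.mask
        self.imp_cols = np.flatnonzero(missing.any(axis=0))
        self.M = len(self.imp_cols)
        self.miss_r = missing[:, self.imp_cols].astype(float)
        # observed-cell sufficient statistics for the covariate model
        self.obs_n = np.empty(self.M)
        self.obs_sum = np.empty(self.M)
        self.obs_ssq = np.empty(self.M)
        for k, j in enumerate(self.imp_cols):
            z = design.Z[design.mask[:, j], j]
            self.obs_n[k] = len(z)
            self.obs_sum[k] = z.sum()
            self.obs_ssq[k] = (z**2).sum()

        self.gh_x, self.gh_w = gauss_hermite(spec.gh_points)

        lay = _Layout()
        lay.add("alpha", 1)
        lay.add("beta", self.p)
        if spec.year_intercepts:
            lay.add("u", self.T)
            lay.add("log_tau", 1)
        if spec.fixed_shrinkage is None:
            lay.add("log_lam", 1)
        self.learn_imputation = spec.imputation == "learned" and self.M > 0
        if self.learn_imputation:
            lay.add("mu", self.M)
            lay.add("log_sig", self.M)
        self.layout = lay

    def initial_point(self) -> np.ndarray:
        theta = np.zeros(self.layout.dim)
        if "log_lam" in self.layout:
            theta[self.layout.slices["log_lam"]] = np.log(0.5)
        if "log_tau" in self.layout:
            theta[self.layout.slices["log_tau"]] = np.log(0.3)
        if self.learn_imputation:
            theta[self.layout.slices["log_sig"]] = 0.0
        return theta

    def frozen_map_indices(self) -> np.ndarray:
        """Log-scale hyperparameter coordinates to hold fixed during MAP
        initialization (their joint mode sits at the hierarchical funnel)."""
        idx: list[int] = []
        for name, sl in self.layout.slices.items():
            if name.startswith("log_"):
                idx.extend(range(sl.start, sl.stop))
        return np.asarray(idx, dtype=int)

    def mu_sigma(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.learn_imputation:
            mu = self.layout.get(theta, "mu")
            sig = np.exp(self.layout.get(theta, "log_sig"))
        else:
            mu0, sig0 = self.spec.fixed_imputation
            mu = np.full(self.M, mu0)
            sig = np.full(self.M, sig0)
        return mu, sig

    def _lam(self, theta: np.ndarray) -> float:
        if self.spec.fixed_shrinkage is not None:
            return float(self.spec.fixed_shrinkage)
        return float(np.exp(self.layout.get(theta, "log_lam")[0]))

    def coefficients(self, theta: np.ndarray) -> np.ndarray:
        """Coefficients on the data scale (beta = lambda * beta_raw)."""
        return self._lam(theta) * self.layout.get(theta, "beta")

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        # non-centered parameterization throughout: beta = lam * beta_raw,
        # u = tau * u_raw, with standard-normal priors on the raw scales
        # (avoids the hierarchical funnel).
        if not np.all(np.isfinite(theta)) or np.abs(theta).max() > 100.0:
            return -np.inf, np.zeros_like(theta)  # diverged trajectory
        lay, spec = self.layout, self.spec
        grad = np.zeros_like(theta)
        alpha = lay.get(theta, "alpha")[0]
        beta_raw = lay.get(theta, "beta")
        lam = self._lam(theta)
        beta = lam * beta_raw

        eta = alpha + self.Z0 @ beta
        if spec.year_intercepts:
            u_raw = lay.get(theta, "u")
            tau = float(np.exp(lay.get(theta, "log_tau")[0]))
            u = tau * u_raw
            eta = eta + u[self.year_idx]

        mu, sig = self.mu_sigma(theta)
        beta_imp = beta[self.imp_cols]
        if self.M:
            m = self.miss_r @ (beta_imp * mu)
            v = self.miss_r @ (beta_imp**2 * sig**2)
        else:
            m = np.zeros(self.N)
            v = np.zeros(self.N)

        loglik, G1, G2 = bernoulli_gh(self.y, eta, m, v, self.gh_x, self.gh_w)
        logp = float(loglik.sum())

        grad[lay.slices["alpha"]] = G1.sum()
        g_beta = self.Z0.T @ G1  # d loglik / d beta (data scale)
        if self.M:
            mtG1 = self.miss_r.T @ G1
            mtG2 = self.miss_r.T @ G2
            g_beta[self.imp_cols] += mu * mtG1 + 2.0 * beta_imp * sig**2 * mtG2

        # intercept prior
        logp += -(alpha**2) / (2 * spec.intercept_scale**2)
        grad[lay.slices["alpha"]] += -alpha / spec.intercept_scale**2

        # raw-coefficient prior + shrinkage-scale hyperprior
        logp += -float(beta_raw @ beta_raw) / 2.0
        grad[lay.slices["beta"]] = lam * g_beta - beta_raw
        if "log_lam" in lay:
            lp, g = half_normal_logpdf_via_log(
                lay.get(theta, "log_lam")[0], spec.shrinkage_scale
            )
            logp += lp
            grad[lay.slices["log_lam"]] = g + float(g_beta @ beta)

        if spec.year_intercepts:
            g_u = np.bincount(self.year_idx, weights=G1, minlength=self.T)
            logp += -float(u_raw @ u_raw) / 2.0
            grad[lay.slices["u"]] = tau * g_u - u_raw
            lp, g = half_normal_logpdf_via_log(
                lay.get(theta, "log_tau")[0], spec.tau_scale
            )
            logp += lp
            grad[lay.slices["log_tau"]] = g + float(g_u @ u)

        if self.learn_imputation:
            g_mu = beta_imp * mtG1 if self.M else np.zeros(0)
            g_sig = 2.0 * beta_imp**2 * sig * mtG2 if self.M else np.zeros(0)
            # observed cells of imputable columns inform (mu, sigma)
            quad = self.obs_ssq - 2 * mu * self.obs_sum + self.obs_n * mu**2
            logp += float(np.sum(-self.obs_n * np.log(sig) - quad / (2 * sig**2)))
            g_mu = g_mu + (self.obs_sum - self.obs_n * mu) / sig**2
            g_sig = g_sig + (-self.obs_n / sig + quad / sig**3)
            # hyperpriors
            logp += float(np.sum(-(mu**2) / (2 * spec.mu_prior_scale**2)))
            g_mu = g_mu - mu / spec.mu_prior_scale**2
            log_sig = lay.get(theta, "log_sig")
            lp, g = half_normal_logpdf_via_log(log_sig, spec.sigma_prior_scale)
            logp += float(np.sum(lp))
            grad[lay.slices["mu"]] = g_mu
            grad[lay.slices["log_sig"]] = g_sig * sig + g
        return logp, grad


@dataclass
class Posterior:
    """Joint posterior draws, pooled over chains."""

    draws: dict[str, np.ndarray]
    chains: int
    seed: int
    diagnostics: dict
    column_names: list[str]
    imp_col_names: list[str]

    @property
    def n_draws(self) -> int:
        return len(self.draws["alpha"])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        flat = {}
        for key, arr in self.draws.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                flat[key] = arr
            else:
                arr2 = arr.reshape(arr.shape[0], -1)
                for j in range(arr2.shape[1]):
                    flat[f"{key}_{j}"] = arr2[:, j]
        pd.DataFrame(flat).to_parquet(directory / "draws.parquet", index=False)
        meta = {
            "chains": self.chains,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
            "column_names": self.column_names,
            "imp_col_names": self.imp_col_names,
            "shapes": {k: list(np.asarray(v).shape) for k, v in self.draws.items()},
        }
        (directory / "posterior.json").write_text(json.dumps(meta, indent=2))


@dataclass
class OddsRatioSummary:
    """Per-column posterior odds ratios with 95% credible intervals,
    sorted by |posterior mean log OR| for top-k reporting."""

    table: pd.DataFrame

    def top(self, k: int = 32) -> pd.DataFrame:
        return self.table.head(k)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return repr(self.table)


def summarize_odds_ratios(
    beta_draws: np.ndarray, columns: list, extra: Optional[dict] = None
) -> OddsRatioSummary:
    """exp-transform coefficient draws; mean and central 95% interval."""
    ors = np.exp(beta_draws)
    log_mean = beta_draws.mean(axis=0)
    rows = {
        "name": [c.name for c in columns],
        "var_class": [c.var_class for c in columns],
        "kind": [c.kind for c in columns],
        "or_mean": ors.mean(axis=0),
        "or_2.5%": np.quantile(ors, 0.025, axis=0),
        "or_97.5%": np.quantile(ors, 0.975, axis=0),
        "log_or_mean": log_mean,
    }
    if extra:
        rows.update(extra)
    table = (
        pd.DataFrame(rows)
        .sort_values("log_or_mean", key=np.abs, ascending=False)
        .reset_index(drop=True)
    )
    return OddsRatioSummary(table=table)


class _MarginalizedResults:
    """Shared machinery for models whose latents collapse to (eta, m, v)."""

    design: DesignMatrix
    posterior: Posterior

    def _eta_m_v(self, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        raise NotImplementedError

    def _check_design(self, design: Optional[DesignMatrix]) -> DesignMatrix:
        if design is None:
            return self.design
        if design.column_names != self.design.column_names:
            raise ValueError("design columns do not match the fitted design")
        fitted_imp = set(self.posterior.imp_col_names)
        missing = ~design.mask
        for j in np.flatnonzero(missing.any(axis=0)):
            if design.columns[j].name not in fitted_imp:
                raise ValueError(
                    f"column {design.columns[j].name!r} has masked cells but no "
                    "imputation hyperparameters from the fit"
                )
        return design

    def linear_predictor_draws(
        self, design: Optional[DesignMatrix] = None, conditional: Optional[bool] = None
    ) -> np.ndarray:
        """(S, N) draws of the linear predictor, masked cells integrated via
        each draw's imputed values (conditional on y for the fitted design,
        prior draws for new data)."""
        target = self._check_design(design)
        if conditional is None:
            conditional = target is self.design
        eta, m, v = self._eta_m_v(target)  # each (S, N)
        rng = np.random.default_rng(self.posterior.seed + 777_001)
        if conditional:
            delta = sample_delta_conditional(
                target.y[None, :], eta, m, v, rng
            )
        else:
            delta = m + np.sqrt(v) * rng.normal(size=v.shape)
        return eta + delta

    def pointwise_loglik(self, design: Optional[DesignMatrix] = None) -> np.ndarray:
        """(S, N): log Bernoulli(y_i | p_i^(s)) with draw s's imputations."""
        target = self._check_design(design)
        etas = self.linear_predictor_draws(design)
        s = 2.0 * target.y[None, :] - 1.0
        return log_sigmoid(s * etas)

    def predictive_draws(self, design: Optional[DesignMatrix] = None) -> np.ndarray:
        return expit(self.linear_predictor_draws(design))

    def predict_prob(self, design: Optional[DesignMatrix] = None) -> np.ndarray:
        """Posterior-mean event probability per row."""
        return self.predictive_draws(design).mean(axis=0)

    def loo(self, thin_to: Optional[int] = None):
        """PSIS-LOO evaluation of this fit (see fabwork.evaluation)."""
        from ..evaluation import loo_predictive

        loglik = self.pointwise_loglik()
        pred = self.predictive_draws()
        if thin_to is not None and thin_to < loglik.shape[0]:
            idx = np.linspace(0, loglik.shape[0] - 1, thin_to).astype(int)
            loglik, pred = loglik[idx], pred[idx]
        return loo_predictive(loglik, pred)


class LogisticResults(_MarginalizedResults):
    """Posterior summaries, predictions and diagnostics for the logistic fit."""

    def __init__(self, model: "SteadyWorkLogistic", posterior: Posterior):
        self.model = model
        self.design = model.design
        self.spec = model.spec
        self.posterior = posterior

    @property
    def converged(self) -> bool:
        return self.posterior.diagnostics.get("converged", True)

    def _eta_m_v(self, design: DesignMatrix):
        post = self.posterior.draws
        dens = self.model._density
        Z0 = np.where(design.mask, design.Z, 0.0)
        beta = post["beta"]  # (S, p)
        eta = post["alpha"][:, None] + beta @ Z0.T  # (S, N)
        if "u" in post:
            year_idx = np.searchsorted(dens.years, design.year)
            eta = eta + post["u"][:, year_idx]
        if dens.M:
            miss_r = (~design.mask)[:, dens.imp_cols].astype(float)
            beta_imp = beta[:, dens.imp_cols]
            m = (beta_imp * post["mu"]) @ miss_r.T
            v = (beta_imp**2 * post["sigma"] ** 2) @ miss_r.T
        else:
            m = np.zeros_like(eta)
            v = np.zeros_like(eta)
        return eta, m, v

    def odds_ratios(self) -> OddsRatioSummary:
        return summarize_odds_ratios(self.posterior.draws["beta"], self.design.columns)

    def sample_imputations(self, seed: int = 0) -> dict[tuple[int, int], np.ndarray]:
        """Per-draw latent values for every masked design cell.

        Returns {(row, col): (S,) draws}; exact conditional sampling given
        each draw's parameters and the row's outcome.
        """
        dens = self.model._density
        post = self.posterior.draws
        rng = np.random.default_rng(self.posterior.seed + 777_002)
        eta, m, v = self._eta_m_v(self.design)
        delta = sample_delta_conditional(self.design.y[None, :], eta, m, v, rng)
        out: dict[tuple[int, int], np.ndarray] = {}
        beta_imp = post["beta"][:, dens.imp_cols]  # (S, M)
        mu, sig = post["mu"], post["sigma"]
        for i in range(self.design.n_rows):
            cols = np.flatnonzero(~self.design.mask[i])
            if len(cols) == 0:
                continue
            kidx = np.searchsorted(dens.imp_cols, cols)
            b = beta_imp[:, kidx]  # (S, c)
            z0 = mu[:, kidx] + sig[:, kidx] * rng.normal(size=b.shape)
            denom = v[:, i]
            adj = np.where(
                denom > 0, (delta[:, i] - (b * z0).sum(axis=1)) / np.where(denom > 0, denom, 1.0), 0.0
            )
            z = z0 + (sig[:, kidx] ** 2) * b * adj[:, None]
            for c_pos, j in enumerate(cols):
                out[(i, int(j))] = z[:, c_pos]
        return out

    def summary(self) -> pd.DataFrame:
        post = self.posterior.draws
        names = ["intercept"] + self.design.column_names
        draws = np.column_stack([post["alpha"], post["beta"]])
        if "u" in post:
            for t in range(post["u"].shape[1]):
                names.append(f"year_{self.model._density.years[t]}_intercept")
            draws = np.column_stack([draws, post["u"]])
        df = pd.DataFrame(
            {
                "mean": draws.mean(axis=0),
                "sd": draws.std(axis=0, ddof=1),
                "2.5%": np.quantile(draws, 0.025, axis=0),
                "97.5%": np.quantile(draws, 0.975, axis=0),
            },
            index=names,
        )
        return df


class SteadyWorkLogistic:
    """Bayesian hierarchical logistic regression for annual steady work."""

    def __init__(self, design: DesignMatrix, spec: Optional[LogisticModelSpec] = None):
        if design.n_rows == 0:
            raise ValueError("empty design")
        if design.mask.shape != design.Z.shape:
            raise ValueError("design mask inconsistent with Z")
        self.design = design
        self.spec = spec or LogisticModelSpec()
        self._density = _GlmDensity(design, self.spec)

    @classmethod
    def from_panel(
        cls,
        panel,
        tolerance: int = 14,
        covariate_set: str = "full",
        spec: Optional[LogisticModelSpec] = None,
    ) -> "SteadyWorkLogistic":
        from ..prep import prepare_design

        design, _ = prepare_design(panel, tolerance, covariate_set)
        return cls(design, spec)

    def fit(self, seed: int = 0) -> LogisticResults:
        dens = self._density
        spec = self.spec
        theta0 = find_map(
            dens, dens.initial_point(), frozen=dens.frozen_map_indices()
        )
        if spec.algorithm == "hmc":
            res = hmc_sample(
                dens,
                theta0,
                draws=spec.draws,
                warmup=spec.warmup,
                chains=spec.chains,
                seed=seed,
                max_leapfrog=spec.max_leapfrog,
                target_accept=spec.target_accept,
            )
            flat = res.flat()
            diagnostics = {
                "algorithm": "hmc",
                "accept_rate": res.diagnostics.accept_rate,
                "divergences": res.diagnostics.divergences,
                "rhat_max": res.diagnostics.rhat_max,
                "ess_min": res.diagnostics.ess_min,
                "converged": res.diagnostics.converged,
            }
            if not res.diagnostics.converged:
                warnings.warn(
                    "HMC convergence diagnostics flagged this fit "
                    f"(rhat_max={res.diagnostics.rhat_max}, "
                    f"accept_rate={res.diagnostics.accept_rate:.2f})"
                )
            chains = spec.chains
        else:
            vi = fit_vi(
                dens,
                theta0,
                steps=spec.vi_steps,
                seed=seed,
            )
            rng = np.random.default_rng(seed + 1)
            flat = vi.sample(spec.draws * spec.chains, rng)
            diagnostics = {"algorithm": "vi", "elbo": vi.elbo, "converged": True}
            chains = 1

        lay = dens.layout
        if spec.fixed_shrinkage is None:
            lam = np.exp(flat[:, lay.slices["log_lam"]][:, 0])
        else:
            lam = np.full(flat.shape[0], spec.fixed_shrinkage)
        draws: dict[str, np.ndarray] = {
            "alpha": flat[:, lay.slices["alpha"]][:, 0],
            "beta": lam[:, None] * flat[:, lay.slices["beta"]],
        }
        if spec.year_intercepts:
            tau = np.exp(flat[:, lay.slices["log_tau"]][:, 0])
            draws["u"] = tau[:, None] * flat[:, lay.slices["u"]]
            draws["tau"] = tau
        if spec.fixed_shrinkage is None:
            draws["lam"] = lam
        if dens.M:
            if dens.learn_imputation:
                draws["mu"] = flat[:, lay.slices["mu"]]
                draws["sigma"] = np.exp(flat[:, lay.slices["log_sig"]])
            else:
                S = flat.shape[0]
                mu0, sig0 = spec.fixed_imputation
                draws["mu"] = np.full((S, dens.M), mu0)
                draws["sigma"] = np.full((S, dens.M), sig0)
        if not np.all([np.isfinite(a).all() for a in draws.values()]):
            raise FloatingPointError("non-finite posterior draws")

        posterior = Posterior(
            draws=draws,
            chains=chains,
            seed=seed,
            diagnostics=diagnostics,
            column_names=self.design.column_names,
            imp_col_names=[self.design.columns[j].name for j in dens.imp_cols],
        )
        return LogisticResults(self, posterior)


def fit_logistic(
    design: DesignMatrix, spec: Optional[LogisticModelSpec] = None, seed: int = 0
) -> LogisticResults:
    """Functional wrapper around SteadyWorkLogistic(...).fit(...)."""
    return SteadyWorkLogistic(design, spec).fit(seed=seed)
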